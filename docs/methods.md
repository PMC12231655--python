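# Methods

This note documents the models, conventions and design choices behind the
package. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Analysis pipeline

### EEG preprocessing

Deterministic, ICA-free: zero-phase 4th-order Butterworth band-pass
(1–49 Hz, forward–backward via `sosfiltfilt` with odd-extension padding of
min(3 low-cut periods, n−1) samples), polyphase resampling to 1000 Hz, and
average re-referencing. Epochs are cut at strong-beat events over
[−800, +800] ms — deliberately wider than any analysis window so that
wavelet edge effects fall outside the region used. Channel/epoch rejection,
ICA-based artifact removal and channel interpolation are out of scope:
synthetic inputs are artifact-free by construction, and those stages are
established external tools rather than part of this pipeline's computation.
Filtering is applied to the (continuous or epoched) data before epoch-level
analysis; for synthetic epoched input it runs per trial along the sample
axis.

### Time–frequency decomposition

Complex Morlet wavelets on a linear 6–48 Hz grid (1 Hz steps) with a
**fixed 500 ms window** at every frequency: the cycle count is 0.5·f
(3 cycles at 6 Hz, 24 at 48 Hz) and the Gaussian envelope is identical at
all frequencies. Conventions the method itself leaves open are fixed as:

- envelope SD = window/6 (taper ≈ 1% of max at the truncated edges);
- unit-energy normalization (ITC is normalization-invariant and ERSP is
  baseline-relative, so the choice is free but must be fixed);
- output grid every 10 ms, restricted so the full window fits in the epoch
  (±550 ms for the default ±800 ms epochs);
- ERSP(f,t) = 10·log₁₀(trial-mean power) − 10·log₁₀(mean baseline power
  over [−500, −200] ms), per frequency, with a 1e−20 µV² floor before the
  log. Trial-mean-then-log, not mean of single-trial dB;
- ITC(f,t) = |n⁻¹ Σₖ cₖ/|cₖ||; zero-magnitude coefficients carry no phase
  and are excluded at that point with a log record.

An FFT-based and a direct time-domain convolution path compute the same
coefficients; the suite holds them to 1e−8 agreement.

### ITC features

Alpha (8–14 Hz) ITC maps are computed per channel, averaged over the
left-motor channels C5/C3/C1, then averaged over in-band frequency bins
(closed intervals, 7 bins on the 1 Hz grid). The trough is the deepest
interior local minimum in [−222, −99] ms; the peak the highest interior
local maximum in [0, 101] ms. Local extrema use strict neighbor comparison;
a plateau counts once at its center sample (earlier of two middles), ties
between equal extrema resolve to the earlier time, and a window with no
interior extremum falls back to its global extremum. The slope is
(peak − trough ITC)/(Δt in s); the bare ITC difference is reported
alongside, since "rise" admits both readings.

### MEP quantification

Fixed chain order: baseline correction (subtract the trial mean over
[−20, −5] ms) → RMS rejection → biphasic check → outlier rejection →
peak-to-peak (max − min over 18–50 ms). Each trial gets exactly one
rejection reason. Choices the verbal protocol leaves open:

- RMS rejection is **one-sided high** (block mean + 2.5·SD, strict
  inequality, block statistics over all trials): low-RMS trials are
  physiologically unremarkable.
- The biphasic criterion is operationalized as opposite-sign excursions in
  [15, 40] ms each exceeding k·σ of the trial's pre-stimulus noise
  ([−200, −20] ms), k = 3 by default and configurable; the qualitative
  criterion gives no threshold, so k is flagged for sensitivity analysis.
- Outlier removal is a single pass (no iteration), computed on trials that
  survived the earlier stages, strict inequality at mean + 5·SD.
- Pre-pulse EMG (mean |signal| over [−20, −5] ms of kept trials) is
  reported per condition for parity checks but never gated on.

Condition comparisons report the paired t-test on per-participant means,
the percent change of group means, and the mean and median of
per-participant percent changes (the skew-robust summary).

### Group statistics

Paired and pooled-variance independent t-tests and simple OLS (R², F(1,
n−2), two-sided p) are implemented from closed forms with `scipy.stats`
distributions, and cross-checked in the suite against
`scipy.stats.ttest_rel`/`ttest_ind` and `statsmodels` OLS to 1e−10.
Degenerate inputs (zero-variance differences, single-participant cohorts)
raise or are flagged rather than silently producing 0/0.

## Stimulus scheduling

Beats lie at k·60/tempo; in duple meter strong beats are the even indices
(strong-beat period ≈ 1 s at 120 BPM). Metronome tones are 262 Hz, 60 ms,
with 10 ms **linear** rise/fall ramps (the simplest dialect of "rise and
fall"); weak beats at 1/10 the strong amplitude. Pulses are assigned to
every k-th strong beat with k drawn per gap from the smallest three values
satisfying the ≥ 3 s ISI floor ({3, 4, 5} at 120 BPM) — the protocol states
only the floor and that ISIs vary, so this seeded rule is a documented
choice. The standard condition copies the entrained plan's ISI sequence
verbatim (the strongest reading of "matched"). ISIs are computed from the
un-offset host beats so the constant −200 ms offset cannot introduce float
rounding below the floor. Music excerpts are represented by beat grids
only (tempo + meter); the analysis consumes beat times, not audio.

## Synthetic EEG: the phase-mixture model

Each trial's alpha component is

    sₖ(t) = A·[ w(t)·sin(2πf t + φ₀) + (1 − w(t))·sin(2πf t + θₖ) ],

a mixture of a beat-locked and a trial-random phase; the beta component is
identical with constant mixing. The mapping from mixing level w to
asymptotic ITC has no convenient closed form at finite n, so it is
tabulated once by Monte-Carlo (10⁴ trials per grid point, fixed seed) and
inverted by monotone (PCHIP) interpolation. At w = ½ the mixture phase is
θ/2, giving the closed-form check R = 2/π.

**Stratified trial phases.** θₖ are drawn one per bin of a 2π/n partition
(uniform jitter inside the bin, order shuffled), so each θₖ is marginally
uniform but the incoherent component's resultant is O(1/n) rather than the
O(1/√n) Rayleigh floor of i.i.d. draws. This matters: at n = 100 trials the
i.i.d. floor E|R| ≈ 0.0886 *exceeds* the trough ITC level (0.06) the
generator must realize, so i.i.d. phases cannot reproduce the calibrated
group values at the study's trial counts. With stratified phases the
measured ITC tracks the asymptotic calibration to ~0.003 at n = 100.

**Band-averaged forward model.** The analysis does not observe w(t)
directly. At an analysis bin offset Δf from the participant's alpha
frequency, the fixed-window Morlet transform smooths the mixing profile
with the *complex* kernel g(τ)e^(−2πiΔf·τ); relative to the attenuated
carrier this amplifies the profile's modulation, so off-center bins see an
exaggerated trough/peak, and the 8–14 Hz band average is sharper than the
envelope-smoothed profile. The generator therefore *inverts the full
forward model*: it builds a smooth target ITC series (two Gaussian bumps,
σ = 90 ms, on a flat baseline at the trough/peak midpoint, with bump
centers nudged so the extrema sit exactly at the requested times), then
iterates w ← w + ½·(map⁻¹(target) − map⁻¹(model)) where the model evaluates
the band-averaged mixture ITC of the candidate profile (512 stratified
phases, 4 ms subgrid), stopping below 1e−3 ITC error. The damped step
converges because the modulation amplification is bounded (≈ 1.5–2 for
these profiles).

Signals are placed on C5/C3/C1 within a 12-channel montage whose remaining
channels carry noise only, so average re-referencing attenuates but cannot
cancel the signal (a pure-signal montage would be annihilated by the
reference). Background noise is white Gaussian (default 3 µV vs. 15 µV
alpha / 8 µV beta amplitude — large wavelet-domain SNR, so noise-induced
phase jitter perturbs ITC by ≪ 0.01); an optional 1/f amplitude-shaping
filter exercises baseline removal.

## Synthetic EMG

Clean trials: a biphasic MEP template (positive then negative Gaussian
lobe, 5 ms SD, 10 ms apart, first lobe centered 7.5 ms after the
configured onset latency, normalized to unit peak-to-peak inside 18–50 ms)
with lognormal per-trial amplitudes (default CV 0.5 — MEP amplitudes are
right-skewed; at ~100 trials this puts the SE of a participant's mean near
0.15 mV at the 2–3 mV scale) on 0.008 mV background noise (absolute mean
≈ 0.0064 mV, matching the resting pre-pulse EMG level being emulated).
Artifact classes, with ground-truth labels recorded per trial and never
read downstream:

- **pre-activation** (default 5%): added tonic noise at 10–20× background
  across the trial — far above the block RMS threshold;
- **outliers** (default 1%): MEP amplitude at 10× the condition mean;
- **absent responses** (default 15%): background only, removed by the
  biphasic check.

The default fractions total ≈ 21% expected rejection, emulating the ~23%
exclusion rate typical of such experiments. The apportionment is
deliberate: a two-point RMS mixture defeats the one-sided mean + 2.5·SD
rule once the contaminated fraction p satisfies p + 2.5·√(p(1−p)) ≥ 1
(p ≳ 0.13), so most of the rejection budget is carried by non-biphasic
trials, which do not enter the block RMS statistics.

## Cohorts

Per-participant parameters sit at deterministic stratified normal quantiles
(participant i of N at probability (i−0.5)/N), so the realized cohort mean
equals the configured group mean exactly and group-recovery tests are
low-variance. Amplitude-like parameters use lognormal quantiles affinely
rescaled to the exact mean (plain normal quantiles would go negative at the
configured SD/mean ratios). Paired fields share the participant's rank —
trough/peak times, trough/peak ITC, and the three condition amplitudes —
so that within-participant orderings (trough before peak, trough ITC below
peak ITC) hold across the whole range and the paired condition design is
actually paired; unrelated fields get independent seeded rank
permutations. Exactly `n_inverted_slope` participants (default 1 in the
27-participant EEG cohort) have their trough/peak ITC values swapped; the
inverted participants are chosen as those whose trough/peak times lie
nearest the detection-window centers, so the negative rise is visible to
the window-limited detector regardless of seed (the swap perturbs cohort
mean trough/peak ITC by ≲ 0.003). All randomness derives from one master
seed via `SeedSequence` spawning; identical seeds give bit-identical data.

Default group calibration: trough time −156.48 ms (SD 40.62), peak time
46.41 ms (SD 39.02), trough ITC 0.06 (SD 0.02), peak ITC 0.11 (SD 0.03),
alpha frequency 10.5 Hz (SD 1), beta ITC 0.12; MEP condition means
3.08/2.44/2.38 mV (SDs 1.68/1.65/1.56) for seTMS/standard/auditory
control, latency 23 ms (SD 2), 100 EEG trials and 125 EMG trials per
condition — the study conditions this package emulates. Trough/peak times
are stratified over the normal *truncated to the detection windows* (5 ms
safety margin, recentred to the exact group mean): the detector only sees
extrema inside [−222, −99]/[0, 101] ms, and at the configured ~40 ms SDs
an untruncated draw would place roughly one participant in seven outside
the detectable regime, where a trough just beyond the window edge can even
masquerade as a negative slope. The realized across-participant time SD is
consequently ~29 ms; the group *means* are exact and are what the recovery
tests check.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: beat-locked
alpha coherence dynamics with controlled trough/peak, constant beta
coherence, amplitude-independent phase measures, lognormal MEP amplitudes,
and separable artifact classes. It does **not** model scalp geometry or
volume conduction, TMS pulse artifacts in EEG, auditory evoked potentials,
oscillatory power changes co-occurring with phase changes, non-stationary
background spectra, or trial-to-trial latency jitter of the MEP. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to every failure mode of real recordings.

## Problem sizes and runtime

The default replication — 27 EEG participants × 100 trials × 3 analyzed
channels (12 simulated), 43 frequencies, plus 19 MEP participants × 3
conditions × 125 trials — completes in well under a minute on one CPU;
the full test suite runs in about half a minute. Cohort-level fixtures are
computed once per test session and shared across the recovery tests.
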