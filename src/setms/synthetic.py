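"""Ground-truth-known synthetic EEG and EMG generators.

No public recordings exist for the beat-listening / beat-locked TMS design
this package analyzes, so every downstream stage is exercised on simulated
data whose generating parameters are known exactly.

EEG epochs emulate the statistical structure the intertrial-coherence (ITC)
analysis assumes: a sensorimotor alpha component whose phase locking to the
strong beat dips to a trough before the beat and rises to a peak after it,
a beta component with constant phase locking, and Gaussian background noise
(optionally 1/f-shaped).  Phase locking is controlled by a phase-locked /
random-phase mixture

    s_k(t) = A [ w(t) sin(2 pi f t + phi0) + (1 - w(t)) sin(2 pi f t + theta_k) ]

whose mixing level w(t) is mapped from target ITC values through a
Monte-Carlo calibration table (no convenient closed form exists for the
mixture's resultant length).  Two refinements make finite-trial recovery
sharp enough for cohort-level parameter-recovery tests:

* per-trial random phases ``theta_k`` are drawn by stratified jitter
  (marginally uniform on [0, 2 pi), but with an O(1/n) resultant instead of
  the O(1/sqrt(n)) Rayleigh floor of i.i.d. draws, which at n = 100 trials
  would exceed the trough ITC levels being emulated);
* the raw mixing profile is pre-compensated for the temporal smoothing of
  the fixed-window Morlet transform, so the *analyzed* ITC trough/peak hit
  the requested values at the requested times.

EMG trial sets contain biphasic motor-evoked-potential (MEP) waveforms with
lognormal per-trial amplitudes on low-level background EMG, plus seeded
artifact classes (tonic pre-activation, amplitude outliers, absent
responses) that the downstream rejection chain must recover.  Ground-truth
labels are recorded for every trial; no analysis stage reads them.

Cohorts place per-participant parameters at deterministic stratified
quantiles so that the realized cohort mean of every generated parameter
equals the configured group mean exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm

from .preprocess import EEGEpochs
from .mep import EMGTrialSet
from .scheduling import BeatSchedule, StimulusPlan, CONDITIONS

# Morlet smoothing constants mirrored from the analysis (fixed 500 ms
# window; Gaussian envelope sigma = window / 6).
_WAVELET_WINDOW_MS = 500.0
_SMOOTH_SIGMA_MS = _WAVELET_WINDOW_MS / 6.0

DEFAULT_CHANNELS = ["Fp1", "Fz", "F3", "F4", "C5", "C3", "C1",
                    "Cz", "C4", "P3", "Pz", "P4"]
SIGNAL_CHANNELS = ["C5", "C3", "C1"]


# ---------------------------------------------------------------------------
# ITC <-> mixing-level calibration oracle

_CAL_SEED = 20240101
_CAL_N_TRIALS = 10_000


def _stratified_phases(n: int, rng: np.random.Generator) -> np.ndarray:
    """Marginally uniform phases with an O(1/n) incoherent resultant.

    One phase is drawn uniformly inside each of n equal bins of [0, 2 pi)
    and the bin order is shuffled, so any subset statistic sees uniform
    phases while the full-set resultant nearly cancels.
    """
    u = rng.uniform(size=n)
    theta = 2.0 * np.pi * (np.arange(n) + u) / n
    return rng.permutation(theta)


@lru_cache(maxsize=1)
def _calibration_table() -> tuple[np.ndarray, np.ndarray]:
    """Tabulate mixing level w -> asymptotic ITC of the mixture model.

    Monte-Carlo with 10^4 stratified-phase trials per grid point and a fixed
    seed; the stratified draw removes nearly all sampling noise, so the
    tabulated curve is the asymptotic resultant length to ~1e-4.
    """
    rng = np.random.default_rng(_CAL_SEED)
    theta = _stratified_phases(_CAL_N_TRIALS, rng)
    grid = np.linspace(0.0, 1.0, 101)
    itc = np.empty_like(grid)
    for i, w in enumerate(grid):
        z = w + (1.0 - w) * np.exp(1j * theta)
        itc[i] = np.abs(np.mean(z / np.abs(z)))
    itc[0], itc[-1] = 0.0, 1.0  # exact limits of the mixture
    # enforce strict monotonicity for the inverse interpolator
    itc = np.maximum.accumulate(itc)
    return grid, itc


def itc_from_mix(w) -> np.ndarray:
    """Asymptotic ITC produced by mixing level(s) w in [0, 1]."""
    grid, itc = _calibration_table()
    return PchipInterpolator(grid, itc)(np.clip(w, 0.0, 1.0))


def mix_for_itc(target) -> np.ndarray:
    """Inverse calibration: mixing level w achieving a target ITC."""
    grid, itc = _calibration_table()
    keep = np.concatenate([[True], np.diff(itc) > 0])
    return PchipInterpolator(itc[keep], grid[keep])(np.clip(target, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Participant parameter sets


@dataclass(frozen=True)
class ParticipantEEGParams:
    """Ground truth for one participant's beat-locked alpha/beta dynamics.

    Times are beat-relative milliseconds (negative = before the strong
    beat); ITC values are the asymptotic coherence levels the analysis
    should recover at the trough/peak of the alpha mixing profile.
    """

    trough_time_ms: float = -156.48
    peak_time_ms: float = 46.41
    trough_itc: float = 0.06
    peak_itc: float = 0.11
    alpha_freq_hz: float = 10.5
    beta_itc: float = 0.12
    beta_freq_hz: float = 23.0
    n_trials: int = 100
    noise_sd_uV: float = 3.0
    alpha_amp_uV: float = 15.0
    beta_amp_uV: float = 8.0
    pink_noise: bool = False
    inverted: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        if self.noise_sd_uV < 0:
            raise ValueError("noise_sd_uV must be >= 0")
        for name in ("trough_itc", "peak_itc", "beta_itc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.trough_itc > self.peak_itc and not self.inverted:
            raise ValueError("trough_itc > peak_itc requires inverted=True")
        if self.trough_time_ms >= self.peak_time_ms:
            raise ValueError("trough must precede peak")


@dataclass(frozen=True)
class ParticipantEMGParams:
    """Ground truth for one participant's MEP amplitudes per condition."""

    mean_amp_mV: dict = field(default_factory=lambda: {
        "setms": 3.08, "standard": 2.44, "auditory_control": 2.38})
    amp_cv: float = 0.5
    mep_latency_ms: float = 23.0
    n_trials: int = 125
    artifact_fraction: float = 0.05
    outlier_fraction: float = 0.01
    absent_fraction: float = 0.15
    artifact_scale_range: tuple = (10.0, 20.0)
    outlier_factor: float = 10.0
    background_sd_mV: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        if not 15.0 <= self.mep_latency_ms <= 40.0:
            raise ValueError("mep_latency_ms must lie in [15, 40] ms")
        for cond, amp in self.mean_amp_mV.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            if amp <= 0:
                raise ValueError("mean amplitudes must be positive")
        for name in ("artifact_fraction", "outlier_fraction", "absent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Mixing profile with smoothing pre-compensation


def _raised_cosine_profile(t_ms: np.ndarray, knot_t: np.ndarray,
                           knot_w: np.ndarray) -> np.ndarray:
    """Piecewise raised-cosine interpolation through (knot_t, knot_w)."""
    w = np.full_like(t_ms, knot_w[0], dtype=float)
    w[t_ms >= knot_t[-1]] = knot_w[-1]
    for (ta, tb, wa, wb) in zip(knot_t[:-1], knot_t[1:], knot_w[:-1], knot_w[1:]):
        sel = (t_ms >= ta) & (t_ms < tb)
        x = (t_ms[sel] - ta) / (tb - ta)
        w[sel] = wa + (wb - wa) * 0.5 * (1.0 - np.cos(np.pi * x))
    return w


def _gauss_kernel(fs: float) -> np.ndarray:
    sigma = _SMOOTH_SIGMA_MS / 1000.0 * fs
    half = int(np.ceil(4 * sigma))
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _smooth(profile: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    half = kernel.size // 2
    padded = np.pad(profile, half, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


_DESIGN_MC_SEED = 777
_DESIGN_MC_PHASES = 512
_TARGET_BUMP_SIGMA_MS = 90.0


@lru_cache(maxsize=1)
def _design_phases() -> np.ndarray:
    rng = np.random.default_rng(_DESIGN_MC_SEED)
    return np.exp(1j * _stratified_phases(_DESIGN_MC_PHASES, rng))


def _mixture_itc_complex(u: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Resultant length of the mixture for (possibly complex) weights u."""
    z = u[..., None] + (1.0 - u[..., None]) * e
    return np.abs((z / np.abs(z)).mean(axis=-1))


def _band_kernels(fs: float, alpha_freq_hz: float,
                  band_freqs: np.ndarray) -> list[np.ndarray]:
    """Effective analysis kernels per band bin, relative to the alpha carrier.

    At a bin offset ``df`` from the participant's alpha frequency the Morlet
    transform smooths the mixing profile with the *complex* kernel
    g(tau) exp(-2 pi i df tau); relative to the attenuated carrier this
    amplifies the profile's modulation, which is why the generator inverts
    the band-averaged forward model rather than the plain envelope.
    """
    g = _gauss_kernel(fs)
    tau = (np.arange(g.size) - g.size // 2) / fs
    return [g * np.exp(-2j * np.pi * (f - alpha_freq_hz) * tau)
            for f in band_freqs]


def _band_itc_forward(w: np.ndarray, kernels: list[np.ndarray],
                      e: np.ndarray, sub: np.ndarray) -> np.ndarray:
    """Model the band-averaged ITC the analysis measures for profile w."""
    half = kernels[0].size // 2
    wp = np.pad(w, half, mode="edge")
    acc = 0.0
    for gf in kernels:
        u = np.convolve(wp, gf, mode="valid")[sub] / gf.sum()
        acc = acc + _mixture_itc_complex(u, e)
    return acc / len(kernels)


def _design_target_series(t_ms: np.ndarray, trough_time_ms: float,
                          peak_time_ms: float, trough_itc: float,
                          peak_itc: float, base_itc: float) -> np.ndarray:
    """Smooth ITC target: two Gaussian bumps on a flat baseline.

    Bump amplitudes are solved so the series equals the trough/peak ITC at
    the nominal times, and the bump centers are nudged by a short fixed
    point so the series' extrema sit exactly there despite the pull of the
    neighboring bump's tail.
    """
    s = _TARGET_BUMP_SIGMA_MS
    c1, c2 = trough_time_ms, peak_time_ms
    series = np.full_like(t_ms, base_itc, dtype=float)
    for _ in range(8):
        A = np.array([
            [np.exp(-0.5 * ((trough_time_ms - c1) / s) ** 2),
             np.exp(-0.5 * ((trough_time_ms - c2) / s) ** 2)],
            [np.exp(-0.5 * ((peak_time_ms - c1) / s) ** 2),
             np.exp(-0.5 * ((peak_time_ms - c2) / s) ** 2)]])
        a1, a2 = np.linalg.solve(A, [trough_itc - base_itc,
                                     peak_itc - base_itc])
        series = (base_itc
                  + a1 * np.exp(-0.5 * ((t_ms - c1) / s) ** 2)
                  + a2 * np.exp(-0.5 * ((t_ms - c2) / s) ** 2))

        def _extremum(nominal, amp):
            sel = (t_ms >= nominal - 120.0) & (t_ms <= nominal + 120.0)
            i = np.argmin(series[sel]) if amp < 0 else np.argmax(series[sel])
            return t_ms[sel][i]

        e1 = _extremum(trough_time_ms, a1)
        e2 = _extremum(peak_time_ms, a2)
        if abs(e1 - trough_time_ms) < 0.5 and abs(e2 - peak_time_ms) < 0.5:
            break
        c1 += trough_time_ms - e1
        c2 += peak_time_ms - e2
    return np.clip(series, 0.002, 0.995)


def _design_mix_profile(t_ms: np.ndarray, fs: float, trough_time_ms: float,
                        peak_time_ms: float, trough_itc: float,
                        peak_itc: float, base_itc: float,
                        alpha_freq_hz: float,
                        band_freqs: np.ndarray) -> np.ndarray:
    """Raw mixing profile whose *analyzed* band ITC hits the targets.

    Inverts the band-averaged forward model by damped fixed-point
    iteration in mixing-level space (Newton-like step through the inverse
    calibration map).  The forward model is evaluated on a 4 ms subgrid
    and the update interpolated back to the sample grid; iteration stops
    when the modeled series matches the target to < 1e-3 ITC everywhere.
    """
    target = _design_target_series(t_ms, trough_time_ms, peak_time_ms,
                                   trough_itc, peak_itc, base_itc)
    kernels = _band_kernels(fs, alpha_freq_hz, band_freqs)
    e = _design_phases()
    step = max(1, int(round(0.004 * fs)))
    sub = np.arange(0, t_ms.size, step)
    w = np.clip(mix_for_itc(target), 0.0, 1.0)
    target_sub = target[sub]
    for _ in range(40):
        model = _band_itc_forward(w, kernels, e, sub)
        if np.max(np.abs(target_sub - model)) < 1e-3:
            break
        dw = (mix_for_itc(np.clip(target_sub, 0.0, 1.0))
              - mix_for_itc(np.clip(model, 0.0, 1.0)))
        w = np.clip(w + 0.5 * np.interp(t_ms, t_ms[sub], dw), 0.0, 1.0)
    return w


# ---------------------------------------------------------------------------
# EEG epoch generation


def _pink_filter(noise: np.ndarray, fs: float, axis: int = 1) -> np.ndarray:
    """Shape white noise to a 1/f amplitude spectrum (variance preserved)."""
    n = noise.shape[axis]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = np.fft.rfft(noise, axis=axis)
    shape = [1] * noise.ndim
    shape[axis] = gain.size
    shaped = np.fft.irfft(spec * gain.reshape(shape), n=n, axis=axis)
    sd_in = noise.std()
    sd_out = shaped.std()
    return shaped * (sd_in / sd_out if sd_out > 0 else 1.0)


def gen_eeg_epochs(params: ParticipantEEGParams,
                   schedule: BeatSchedule | None = None,
                   fs: float = 1000.0,
                   channels: list[str] | None = None,
                   window_ms: tuple[float, float] = (-800.0, 800.0),
                   ) -> EEGEpochs:
    """Generate beat-locked EEG epochs for one participant.

    The alpha and beta components are placed on the left-motor channels
    (C5, C3, C1); the remaining montage channels carry noise only, so that
    average re-referencing attenuates but does not cancel the signal.
    Identical seeds produce bit-identical epochs.
    """
    if fs < 250.0:
        raise ValueError("fs must be >= 250 Hz")
    if window_ms[0] > -500.0 or window_ms[1] < 500.0:
        raise ValueError("epoch window must span at least [-500, +500] ms")
    channels = list(DEFAULT_CHANNELS if channels is None else channels)

    n_samp = int(round((window_ms[1] - window_ms[0]) / 1000.0 * fs)) + 1
    t_ms = window_ms[0] + np.arange(n_samp) * 1000.0 / fs
    t_s = t_ms / 1000.0
    n = params.n_trials
    rng = np.random.default_rng(params.seed)

    # mixing profile pre-compensated for the analysis' band-averaged
    # Morlet smoothing (see _design_mix_profile)
    from .tfr import ALPHA_BAND_HZ, FREQ_STEP_HZ
    band_freqs = np.arange(ALPHA_BAND_HZ[0],
                           ALPHA_BAND_HZ[1] + 0.5 * FREQ_STEP_HZ,
                           FREQ_STEP_HZ)
    base_itc = 0.5 * (params.trough_itc + params.peak_itc)
    w = _design_mix_profile(t_ms, fs, params.trough_time_ms,
                            params.peak_time_ms, params.trough_itc,
                            params.peak_itc, base_itc,
                            params.alpha_freq_hz, band_freqs)

    phi0_a = rng.uniform(0.0, 2.0 * np.pi)
    phi0_b = rng.uniform(0.0, 2.0 * np.pi)
    theta_a = _stratified_phases(n, rng)
    theta_b = _stratified_phases(n, rng)

    om_a = 2.0 * np.pi * params.alpha_freq_hz
    om_b = 2.0 * np.pi * params.beta_freq_hz
    # (samples, trials) alpha mixture with time-varying locking
    alpha = params.alpha_amp_uV * (
        w[:, None] * np.sin(om_a * t_s + phi0_a)[:, None]
        + (1.0 - w)[:, None] * np.sin(om_a * t_s[:, None] + theta_a[None, :]))
    w_beta = float(mix_for_itc(params.beta_itc))
    beta = params.beta_amp_uV * (
        w_beta * np.sin(om_b * t_s + phi0_b)[:, None]
        + (1.0 - w_beta) * np.sin(om_b * t_s[:, None] + theta_b[None, :]))
    sig = alpha + beta

    data = rng.normal(0.0, 1.0, size=(len(channels), n_samp, n))
    if params.pink_noise:
        data = _pink_filter(data, fs, axis=1)
    data *= params.noise_sd_uV
    for name in SIGNAL_CHANNELS:
        if name in channels:
            data[channels.index(name)] += sig
    return EEGEpochs(data, fs, t_ms, channels)


# ---------------------------------------------------------------------------
# EMG trial generation

_MEP_SIGMA_MS = 5.0    # per-lobe Gaussian SD
_MEP_LOBE_GAP_MS = 10.0
P2P_WINDOW_MS = (18.0, 50.0)


def mep_template(time_ms: np.ndarray, latency_ms: float) -> np.ndarray:
    """Biphasic MEP shape: positive then negative Gaussian lobe.

    Lobes of 5 ms SD, 10 ms apart, first lobe centered 7.5 ms after onset;
    normalized so the peak-to-peak amplitude inside the 18-50 ms
    quantification window is exactly 1.
    """
    c1 = latency_ms + 7.5
    c2 = c1 + _MEP_LOBE_GAP_MS
    shape = (np.exp(-0.5 * ((time_ms - c1) / _MEP_SIGMA_MS) ** 2)
             - np.exp(-0.5 * ((time_ms - c2) / _MEP_SIGMA_MS) ** 2))
    win = (time_ms >= P2P_WINDOW_MS[0]) & (time_ms <= P2P_WINDOW_MS[1])
    p2p = shape[win].max() - shape[win].min()
    return shape / p2p


def gen_emg_trials(params: ParticipantEMGParams, plan: StimulusPlan,
                   fs: float = 5000.0,
                   window_ms: tuple[float, float] = (-200.0, 60.0),
                   ) -> tuple[EMGTrialSet, pd.DataFrame]:
    """Generate pulse-locked EMG trials for one condition.

    Clean trials carry a biphasic MEP with a lognormal amplitude on
    background EMG noise; artifact trials add tonic activity scaled well
    above the block RMS rejection threshold; outlier trials carry an MEP
    amplitude far above the clean mean; absent-response trials carry noise
    only.  Returns the trial set and a ground-truth table (trial, label,
    true amplitude) that downstream analysis must not read.
    """
    if window_ms[0] > -200.0 or window_ms[1] < 60.0:
        raise ValueError("trial window must cover [-200, +60] ms")
    cond = plan.condition
    if cond not in params.mean_amp_mV:
        raise ValueError(f"no mean amplitude configured for {cond!r}")
    mean_amp = params.mean_amp_mV[cond]

    n = params.n_trials
    n_art = int(round(params.artifact_fraction * n))
    n_out = int(round(params.outlier_fraction * n))
    n_abs = int(round(params.absent_fraction * n))
    if n_art + n_out + n_abs > n:
        raise ValueError("artifact fractions exceed the trial count")
    labels = np.array(["clean"] * n, dtype=object)
    labels[:n_art] = "artifact"
    labels[n_art:n_art + n_out] = "outlier"
    labels[n_art + n_out:n_art + n_out + n_abs] = "absent"
    rng = np.random.default_rng(params.seed)
    rng.shuffle(labels)

    n_samp = int(round((window_ms[1] - window_ms[0]) / 1000.0 * fs)) + 1
    time_ms = window_ms[0] + np.arange(n_samp) * 1000.0 / fs
    template = mep_template(time_ms, params.mep_latency_ms)

    sigma_log = float(np.sqrt(np.log1p(params.amp_cv ** 2)))
    mu_log = float(np.log(mean_amp)) - 0.5 * sigma_log ** 2

    data = rng.normal(0.0, params.background_sd_mV, size=(n, n_samp))
    amp = np.full(n, np.nan)
    for i, lab in enumerate(labels):
        if lab == "absent":
            continue
        if lab == "outlier":
            amp[i] = params.outlier_factor * mean_amp
        else:
            amp[i] = rng.lognormal(mu_log, sigma_log)
        data[i] += amp[i] * template
        if lab == "artifact":
            scale = rng.uniform(*params.artifact_scale_range)
            data[i] += rng.normal(0.0, scale * params.background_sd_mV,
                                  size=n_samp)
    trials = EMGTrialSet(data=data, fs=fs, time_ms=time_ms, condition=cond)
    truth = pd.DataFrame({"trial": np.arange(n), "label": labels,
                          "true_amp_mV": amp})
    return trials, truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Group-level generative spec with stratified per-participant draws.

    ``eeg_mean``/``eeg_sd`` and ``emg_mean``/``emg_sd`` configure the
    across-participant distribution of the stratified parameters; fields
    not listed there are held at the single-participant defaults.  Defaults
    reproduce the study conditions this package emulates: a 27-participant
    listening cohort (one inverted-slope participant) and a 19-participant
    MEP cohort.
    """

    n_participants_eeg: int = 27
    n_participants_emg: int = 19
    n_inverted_slope: int = 1
    master_seed: int = 0
    eeg_mean: dict = field(default_factory=lambda: {
        "trough_time_ms": -156.48, "peak_time_ms": 46.41,
        "trough_itc": 0.06, "peak_itc": 0.11,
        "alpha_freq_hz": 10.5, "beta_itc": 0.12, "beta_freq_hz": 23.0})
    eeg_sd: dict = field(default_factory=lambda: {
        "trough_time_ms": 40.62, "peak_time_ms": 39.02,
        "trough_itc": 0.02, "peak_itc": 0.03,
        "alpha_freq_hz": 1.0, "beta_itc": 0.03, "beta_freq_hz": 1.5})
    emg_mean: dict = field(default_factory=lambda: {
        "setms": 3.08, "standard": 2.44, "auditory_control": 2.38,
        "mep_latency_ms": 23.0})
    emg_sd: dict = field(default_factory=lambda: {
        "setms": 1.68, "standard": 1.65, "auditory_control": 1.56,
        "mep_latency_ms": 2.0})
    eeg_defaults: ParticipantEEGParams = field(
        default_factory=ParticipantEEGParams)
    emg_defaults: ParticipantEMGParams = field(
        default_factory=ParticipantEMGParams)

    def __post_init__(self) -> None:
        if self.n_inverted_slope > self.n_participants_eeg:
            raise ValueError("n_inverted_slope exceeds cohort size")
        for d in (self.eeg_sd, self.emg_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("group SDs must be >= 0")


def _stratified_normal(n: int, mean: float, sd: float) -> np.ndarray:
    """Deterministic stratified normal quantiles (mean exact by symmetry)."""
    q = (np.arange(1, n + 1) - 0.5) / n
    return mean + sd * norm.ppf(q)


def _stratified_truncnorm(n: int, mean: float, sd: float, lo: float,
                          hi: float, margin: float = 5.0) -> np.ndarray:
    """Stratified quantiles of a window-truncated normal, exact mean.

    Used for the trough/peak times: the feature detector only sees extrema
    inside its analysis window, so cohort ground truth is confined to the
    detectable regime (with a safety margin for smoothing-induced shifts).
    The truncated quantiles are recentred to the exact group mean; the
    recentring shift is smaller than the margin, so values stay inside.
    """
    if sd == 0 or n == 1:
        return np.full(n, mean)
    a, b = lo + margin, hi - margin
    # shift the pre-truncation location so the truncated stratified mean
    # equals the requested mean exactly (contraction: converges fast) while
    # every quantile stays strictly inside the window
    shift = 0.0
    v = np.full(n, mean)
    for _ in range(50):
        loc = mean + shift
        p_lo, p_hi = norm.cdf((a - loc) / sd), norm.cdf((b - loc) / sd)
        q = p_lo + (np.arange(1, n + 1) - 0.5) / n * (p_hi - p_lo)
        v = loc + sd * norm.ppf(q)
        err = v.mean() - mean
        if abs(err) < 1e-10:
            break
        shift -= err
    return v


def _stratified_lognormal(n: int, mean: float, sd: float) -> np.ndarray:
    """Positive stratified draws rescaled to the exact group mean.

    Lognormal quantiles matched to (mean, sd) are affinely rescaled so the
    realized mean equals ``mean`` exactly and the realized SD equals ``sd``;
    positivity holds for the coefficient-of-variation range used here.
    """
    if sd == 0 or n == 1:
        return np.full(n, mean)
    cv = sd / mean
    s2 = np.log1p(cv ** 2)
    mu = np.log(mean) - 0.5 * s2
    q = (np.arange(1, n + 1) - 0.5) / n
    v = np.exp(norm.ppf(q, loc=mu, scale=np.sqrt(s2)))
    v = mean + (v - v.mean()) * (sd / v.std(ddof=0))
    if np.any(v <= 0):
        raise ValueError("stratified amplitudes not positive; reduce group SD")
    return v


class Cohort:
    """Per-participant ground-truth parameters plus lazy dataset access.

    ``eeg_truth`` / ``emg_truth`` are the ground-truth parameter tables;
    ``participant_eeg(i)`` and ``participant_emg(i, plan)`` generate the
    corresponding datasets on demand (generation is deterministic in
    ``master_seed``, so repeated calls are bit-identical).
    """

    def __init__(self, spec: CohortSpec):
        self.spec = spec
        ss = np.random.SeedSequence(spec.master_seed)
        (self._perm_ss, self._eeg_seed_ss, self._emg_seed_ss) = ss.spawn(3)
        self.eeg_truth = self._build_eeg_truth()
        self.emg_truth = self._build_emg_truth()

    # -- parameter tables ---------------------------------------------------

    def _build_eeg_truth(self) -> pd.DataFrame:
        spec = self.spec
        n = spec.n_participants_eeg
        rng = np.random.default_rng(self._perm_ss)
        # paired fields share the participant's rank so that per-participant
        # orderings (trough before peak, trough ITC below peak ITC) are
        # preserved across the whole stratified range
        groups = [("trough_time_ms", "peak_time_ms"),
                  ("trough_itc", "peak_itc"),
                  ("alpha_freq_hz",), ("beta_itc",), ("beta_freq_hz",)]
        from .features import PEAK_WINDOW_MS, TROUGH_WINDOW_MS
        windows = {"trough_time_ms": TROUGH_WINDOW_MS,
                   "peak_time_ms": PEAK_WINDOW_MS}
        cols = {}
        for group in groups:
            perm = rng.permutation(n)
            for name in group:
                if name in windows:
                    vals = _stratified_truncnorm(n, spec.eeg_mean[name],
                                                 spec.eeg_sd[name],
                                                 *windows[name])
                else:
                    vals = _stratified_normal(n, spec.eeg_mean[name],
                                              spec.eeg_sd[name])
                cols[name] = vals[perm]
        df = pd.DataFrame(cols)
        df.insert(0, "participant", np.arange(n))
        # physical clamps (defaults are chosen so these never bind)
        df["alpha_freq_hz"] = df["alpha_freq_hz"].clip(8.0, 14.0)
        df["beta_freq_hz"] = df["beta_freq_hz"].clip(20.0, 26.0)
        for c in ("trough_itc", "peak_itc", "beta_itc"):
            df[c] = df[c].clip(0.005, 0.98)
        # invert the participants whose trough/peak times sit nearest the
        # detection-window centers: swapping their trough/peak ITC values
        # produces a negative rise that the window-limited detector can
        # actually see, whatever the seed's rank assignment
        df["inverted"] = False
        if spec.n_inverted_slope:
            eccentricity = (np.abs(df["trough_time_ms"].to_numpy() + 160.5)
                            + np.abs(df["peak_time_ms"].to_numpy() - 50.5))
            order = np.argsort(eccentricity, kind="stable")
            for i in order[: spec.n_inverted_slope]:
                lo, hi = df.at[i, "trough_itc"], df.at[i, "peak_itc"]
                df.at[i, "trough_itc"], df.at[i, "peak_itc"] = hi, lo
                df.at[i, "inverted"] = True
        seeds = np.random.default_rng(self._eeg_seed_ss).integers(
            0, 2 ** 31, size=n)
        df["seed"] = seeds
        return df

    def _build_emg_truth(self) -> pd.DataFrame:
        spec = self.spec
        n = spec.n_participants_emg
        rng = np.random.default_rng(self._perm_ss)
        # one shared excitability rank per participant across conditions,
        # as the paired within-participant design requires
        perm = rng.permutation(n)
        cols = {}
        for cond in CONDITIONS:
            vals = _stratified_lognormal(n, spec.emg_mean[cond],
                                         spec.emg_sd[cond])
            cols[f"amp_{cond}"] = vals[perm]
        lat = _stratified_normal(n, spec.emg_mean["mep_latency_ms"],
                                 spec.emg_sd["mep_latency_ms"])
        cols["mep_latency_ms"] = np.clip(lat[rng.permutation(n)], 15.0, 40.0)
        df = pd.DataFrame(cols)
        df.insert(0, "participant", np.arange(n))
        seeds = np.random.default_rng(self._emg_seed_ss).integers(
            0, 2 ** 31, size=n)
        df["seed"] = seeds
        return df

    # -- dataset generation -------------------------------------------------

    def eeg_params(self, i: int) -> ParticipantEEGParams:
        row = self.eeg_truth.iloc[i]
        return replace(
            self.spec.eeg_defaults,
            trough_time_ms=float(row.trough_time_ms),
            peak_time_ms=float(row.peak_time_ms),
            trough_itc=float(row.trough_itc),
            peak_itc=float(row.peak_itc),
            alpha_freq_hz=float(row.alpha_freq_hz),
            beta_itc=float(row.beta_itc),
            beta_freq_hz=float(row.beta_freq_hz),
            inverted=bool(row.inverted),
            seed=int(row.seed))

    def emg_params(self, i: int) -> ParticipantEMGParams:
        row = self.emg_truth.iloc[i]
        return replace(
            self.spec.emg_defaults,
            mean_amp_mV={c: float(row[f"amp_{c}"]) for c in CONDITIONS},
            mep_latency_ms=float(row.mep_latency_ms),
            seed=int(row.seed))

    def participant_eeg(self, i: int, **kwargs) -> EEGEpochs:
        return gen_eeg_epochs(self.eeg_params(i), **kwargs)

    def participant_emg(self, i: int, plan: StimulusPlan, **kwargs):
        params = self.emg_params(i)
        # per-condition sub-seed so conditions are independent draws
        cond_offset = {c: k for k, c in enumerate(CONDITIONS)}[plan.condition]
        params = replace(params, seed=int((params.seed + cond_offset)
                                          % (2 ** 31)))
        return gen_emg_trials(params, plan, **kwargs)


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Build the cohort's ground-truth tables and dataset factory."""
    return Cohort(spec)


# ---------------------------------------------------------------------------
# Writers (delimited text formats with JSON sidecars)


def write_epochs_delimited(epochs: EEGEpochs, prefix) -> None:
    """Write epochs as a trial-major delimited matrix + JSON sidecar."""
    prefix = Path(prefix)
    n_ch, n_samp, n_tr = epochs.data.shape
    mat = epochs.data.transpose(2, 0, 1).reshape(n_tr * n_ch, n_samp)
    np.savetxt(prefix.with_suffix(".tsv"), mat, delimiter="\t", fmt="%.6g")
    hdr = {"fs": epochs.fs,
           "window_ms": [float(epochs.time_ms[0]), float(epochs.time_ms[-1])],
           "channel_names": list(epochs.channel_names),
           "n_trials": int(n_tr), "layout": "trial-major"}
    prefix.with_suffix(".json").write_text(json.dumps(hdr, indent=1))


def write_events_tsv(path, schedule: BeatSchedule,
                     plans: list[StimulusPlan] | None = None) -> None:
    """Write beat and pulse events: columns onset_s, kind, condition."""
    rows = [(float(t), "strong", "") for t in schedule.strong_beat_times_s]
    rows += [(float(t), "weak", "") for t in schedule.weak_beat_times_s]
    for plan in plans or []:
        rows += [(float(t), "pulse", plan.condition)
                 for t in plan.pulse_times_s]
    df = pd.DataFrame(rows, columns=["onset_s", "kind", "condition"])
    df.sort_values("onset_s", kind="stable").to_csv(path, sep="\t", index=False)


def write_emg_delimited(trials: EMGTrialSet, truth: pd.DataFrame,
                        prefix) -> None:
    """Write EMG trials (rows = trials) + JSON header + ground-truth TSV."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".tsv"), trials.data, delimiter="\t",
               fmt="%.6g")
    pulse_idx = int(np.argmin(np.abs(trials.time_ms)))
    hdr = {"fs": trials.fs, "pulse_sample_index": pulse_idx,
           "window_ms": [float(trials.time_ms[0]), float(trials.time_ms[-1])],
           "condition": trials.condition}
    prefix.with_suffix(".json").write_text(json.dumps(hdr, indent=1))
    truth.to_csv(prefix.parent / (prefix.stem + "_truth.tsv"), sep="\t",
                 index=False)
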