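# setms

Tools for **sensory-entrained TMS (seTMS)** experiments: delivering single
TMS pulses at a fixed offset before predictable auditory beats so that they
land in a high-excitability brain state, and quantifying the two
measurements such experiments rest on —

1. **Beat-locked EEG phase dynamics.** During passive listening, the
   sensorimotor mu rhythm (alpha band, 8–14 Hz) transiently *desynchronizes*
   before each strong beat and re-synchronizes after it. The package
   measures this with Morlet-wavelet intertrial coherence
   (ITC(f,t) = |n⁻¹ Σₖ cₖ(f,t)/|cₖ(f,t)||, 0 = no phase consistency across
   trials, 1 = perfect consistency), extracts the per-participant alpha-ITC
   **trough** in [−222, −99] ms and **peak** in [0, 101] ms, and the
   trough-to-peak **slope**.
2. **Motor-evoked potentials (MEPs).** EMG responses to TMS over motor
   cortex are cleaned by a fixed rejection chain (baseline correction →
   block-RMS pre-activation rejection at 2.5 SD → biphasic-waveform check in
   15–40 ms → 5 SD amplitude-outlier rejection) and quantified as the
   peak-to-peak voltage 18–50 ms post-pulse, compared across the seTMS
   (−200 ms), standard, and auditory-control (0 ms) conditions.

Because no public recordings exist for this design, the package ships
first-class **synthetic generators**: beat-locked EEG whose alpha ITC
trough/peak are controlled through a calibrated phase-mixture model, and EMG
trial sets with seeded artifact classes and known amplitudes. Every analysis
stage is validated end-to-end against this ground truth; the default
generator calibration reproduces the group-level quantities of the study
design it emulates (27-participant listening cohort, 19-participant MEP
cohort).

Audience: TMS/EEG methods researchers who want a tested, deterministic
reference implementation of the beat-locked ITC statistic and the MEP
preprocessing chain, or a simulator to power-test variants of either.

## Worked example

```python
from setms import (ParticipantEEGParams, gen_eeg_epochs, preprocess_epochs,
                   morlet_transform, alpha_itc_series, extract_features)
from setms.tfr import MOTOR_CHANNELS

# one synthetic participant: alpha-ITC trough 0.06 at -156.48 ms,
# peak 0.11 at +46.41 ms, 100 beat-locked trials
params = ParticipantEEGParams(seed=7)
epochs = gen_eeg_epochs(params)                       # 12-channel, ±800 ms
clean = preprocess_epochs(epochs)                     # 1-49 Hz, avg ref
tfr = morlet_transform(clean.pick(list(MOTOR_CHANNELS)))  # C5, C3, C1
times, series = alpha_itc_series(tfr)                 # 8-14 Hz band ITC
f = extract_features(times, series)
print(f"trough {f.trough_time_ms:.0f} ms (ITC {f.trough_itc:.3f}), "
      f"peak {f.peak_time_ms:.0f} ms (ITC {f.peak_itc:.3f}), "
      f"slope {f.slope:.3f}/s")
```

prints

```
trough -150 ms (ITC 0.058), peak 40 ms (ITC 0.115), slope 0.296/s
```

i.e. the pipeline recovers this participant's configured pre-beat
desynchronization trough and post-beat peak to within one 10 ms output
sample and ~0.005 ITC. The full replication — both cohorts, group
statistics, condition comparisons — runs from the command line:

```bash
setms replicate --seed 0 --out report.json
```

Other subcommands (`simulate`, `schedule`, `preprocess`, `tfr`,
`itc-features`, `mep`) expose the individual stages on delimited text
files; see `setms --help`.

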