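"""End-to-end orchestration: simulate, analyze, and report.

``run_eeg_study`` runs, per participant: epoch generation, band-pass /
resample / average-reference preprocessing, Morlet TFR over the motor
channels, alpha-band channel-averaged ITC, and trough/peak/slope feature
extraction; then group statistics (paired t of trough vs peak ITC,
positive-slope fraction).

``run_mep_study`` runs, per participant and condition: the EMG rejection
chain and peak-to-peak quantification; then paired condition comparisons
and percent-change summaries.

``run_default_replication`` executes both studies on the default synthetic
cohort calibrated to the group-level quantities this package emulates.
Reports are plain dicts (JSON-serializable) and fully determined by the
configuration and master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .features import extract_features, paired_t, positive_slope_fraction
from .mep import compare_conditions, quantify_meps
from .preprocess import preprocess_epochs
from .scheduling import CONDITIONS, make_beat_schedule, schedule_pulses
from .synthetic import Cohort, CohortSpec, gen_cohort
from .tfr import MOTOR_CHANNELS, alpha_itc_series, morlet_transform

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration: cohort spec plus analysis parameters.

    Every analysis threshold defaults to the value used throughout the
    package (filter band 1-49 Hz, wavelet grid 6-48 Hz / 500 ms window,
    trough window [-222, -99] ms, peak window [0, 101] ms, RMS criterion
    2.5 SD, outlier criterion 5 SD, condition offsets -200/0 ms).
    """

    cohort: CohortSpec = field(default_factory=CohortSpec)
    fs_eeg: float = 1000.0
    fs_emg: float = 5000.0
    tempo_bpm: float = 120.0
    min_isi_s: float = 3.0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        cohort_raw = raw.pop("cohort", {})
        eeg_defaults = cohort_raw.pop("eeg_defaults", {})
        emg_defaults = cohort_raw.pop("emg_defaults", {})
        from .synthetic import ParticipantEEGParams, ParticipantEMGParams
        if isinstance(emg_defaults, dict) and "artifact_scale_range" in emg_defaults:
            emg_defaults["artifact_scale_range"] = tuple(
                emg_defaults["artifact_scale_range"])
        cohort = CohortSpec(
            eeg_defaults=ParticipantEEGParams(**eeg_defaults),
            emg_defaults=ParticipantEMGParams(**emg_defaults),
            **cohort_raw)
        return cls(cohort=cohort, **raw)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _group_summary(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    out = {"n": int(values.size), "mean": float(values.mean())}
    if values.size > 1:
        out["sd"] = float(values.std(ddof=1))
        out["degenerate_n"] = False
    else:
        out["sd"] = None
        out["degenerate_n"] = True
    return out


def run_eeg_study(config: RunConfig) -> dict:
    """Listening-study section: per-participant ITC features + group stats."""
    spec = config.cohort
    if spec.n_participants_eeg < 1:
        raise ValueError("empty EEG cohort")
    cohort: Cohort = gen_cohort(spec)
    rows = []
    for i in range(spec.n_participants_eeg):
        epochs = cohort.participant_eeg(i, fs=config.fs_eeg)
        clean = preprocess_epochs(epochs)
        tfr = morlet_transform(clean.pick(list(MOTOR_CHANNELS)))
        times, series = alpha_itc_series(tfr)
        feats = extract_features(times, series)
        logger.info("participant %d: trough %.0f ms (%.3f), peak %.0f ms "
                    "(%.3f)", i, feats.trough_time_ms, feats.trough_itc,
                    feats.peak_time_ms, feats.peak_itc)
        rows.append(feats)
    section = {
        "n_participants": spec.n_participants_eeg,
        "features": [asdict(f) for f in rows],
        "trough_time_ms": _group_summary([f.trough_time_ms for f in rows]),
        "peak_time_ms": _group_summary([f.peak_time_ms for f in rows]),
        "trough_itc": _group_summary([f.trough_itc for f in rows]),
        "peak_itc": _group_summary([f.peak_itc for f in rows]),
        "slope_per_s": _group_summary([f.slope for f in rows]),
        "positive_slope_fraction": positive_slope_fraction(rows),
    }
    if len(rows) >= 2:
        st = paired_t([f.trough_itc for f in rows],
                      [f.peak_itc for f in rows])
        section["trough_vs_peak_itc_paired_t"] = vars(st)
    else:
        section["trough_vs_peak_itc_paired_t"] = None
    return section


def _build_plans(config: RunConfig, n_trials: int, seed: int) -> dict:
    """One beat schedule and matched pulse plans shared by the cohort."""
    # generous duration: worst case every 5th strong beat hosts a pulse
    duration = (n_trials + 2) * 5 * 2 * 60.0 / config.tempo_bpm
    schedule = make_beat_schedule(config.tempo_bpm, duration, "duple")
    setms_plan = schedule_pulses(schedule, "setms", config.min_isi_s,
                                 n_pulses=n_trials, seed=seed)
    control = schedule_pulses(schedule, "auditory_control", config.min_isi_s,
                              n_pulses=n_trials, seed=seed + 1)
    standard = schedule_pulses(schedule, "standard",
                               paired_setms=setms_plan)
    return {"setms": setms_plan, "auditory_control": control,
            "standard": standard}


def run_mep_study(config: RunConfig) -> dict:
    """TMS-study section: MEP quantification + paired condition comparisons."""
    spec = config.cohort
    if spec.n_participants_emg < 1:
        raise ValueError("empty MEP cohort")
    cohort: Cohort = gen_cohort(spec)
    plans = _build_plans(config, spec.emg_defaults.n_trials,
                         seed=spec.master_seed)
    cond_means = {c: [] for c in CONDITIONS}
    rejection = {c: [] for c in CONDITIONS}
    prepulse = {c: [] for c in CONDITIONS}
    for i in range(spec.n_participants_emg):
        for cond in CONDITIONS:
            trials, _truth = cohort.participant_emg(i, plans[cond],
                                                    fs=config.fs_emg)
            res = quantify_meps(trials)
            cond_means[cond].append(res.mean_p2p)
            rejection[cond].append(res.fraction_rejected)
            prepulse[cond].append(res.prepulse_abs_mean_mV)
        logger.info("participant %d MEP means: %s", i,
                    {c: round(cond_means[c][-1], 3) for c in CONDITIONS})
    section = {"n_participants": spec.n_participants_emg,
               "conditions": {}, "comparisons": {}}
    for cond in CONDITIONS:
        s = _group_summary(cond_means[cond])
        s["fraction_rejected_mean"] = float(np.mean(rejection[cond]))
        s["prepulse_abs_mean_mV"] = float(np.mean(prepulse[cond]))
        section["conditions"][cond] = s
    if spec.n_participants_emg >= 2:
        for other in ("standard", "auditory_control"):
            cmp_res = compare_conditions(cond_means["setms"],
                                         cond_means[other])
            section["comparisons"][f"setms_vs_{other}"] = {
                "percent_change_of_means": cmp_res.percent_change_of_means,
                "mean_percent_change": cmp_res.mean_percent_change,
                "median_percent_change": cmp_res.median_percent_change,
                "paired_t": vars(cmp_res.stats),
            }
    section["per_participant_means"] = {c: list(map(float, v))
                                        for c, v in cond_means.items()}
    return section


def run_default_replication(seed: int = 0,
                            config: RunConfig | None = None) -> dict:
    """Both studies on the default calibrated synthetic cohorts."""
    if config is None:
        config = RunConfig(cohort=CohortSpec(master_seed=seed))
    report = {
        "provenance": {
            "version": __version__,
            "master_seed": config.cohort.master_seed,
            "config_hash": config.content_hash(),
            "config": config.to_dict(),
        },
        "eeg": run_eeg_study(config),
        "mep": run_mep_study(config),
    }
    return report


def report_to_json(report: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return str(o)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=default)
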