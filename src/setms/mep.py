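"""MEP preprocessing chain, quantification and condition statistics.

The rejection chain runs in a fixed order on pulse-locked EMG trials:

1. baseline correction (subtract the mean over [-20, -5] ms pre-pulse),
2. RMS pre-activation rejection (trial RMS over [-200, +13] ms, omitting
   (-5, +5) ms around the pulse artifact, above block mean + 2.5 SD),
3. biphasic waveform check in [15, 40] ms,
4. amplitude outlier rejection (peak-to-peak above mean + 5 SD of the
   surviving trials),

after which the MEP is quantified as the min-to-max voltage in the
18-50 ms post-pulse window.  Each trial carries exactly one rejection
reason; block statistics for the RMS rule use all trials in the set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASELINE_WINDOW_MS = (-20.0, -5.0)
RMS_WINDOW_MS = (-200.0, 13.0)
RMS_OMIT_MS = (-5.0, 5.0)
RMS_SD_CRITERION = 2.5
BIPHASIC_WINDOW_MS = (15.0, 40.0)
BIPHASIC_NOISE_K = 3.0
NOISE_WINDOW_MS = (-200.0, -20.0)
OUTLIER_SD_CRITERION = 5.0
P2P_WINDOW_MS = (18.0, 50.0)
PREPULSE_EMG_WINDOW_MS = (-20.0, -5.0)


@dataclass
class EMGTrialSet:
    """Pulse-locked EMG trials (rows) in millivolts; time 0 = TMS pulse."""

    data: np.ndarray
    fs: float
    time_ms: np.ndarray
    condition: str
    participant_id: str | int | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.data.shape[1] != self.time_ms.size:
            raise ValueError("time_ms length mismatch")
        if self.time_ms[0] > -200.0 or self.time_ms[-1] < 60.0:
            raise ValueError("trial window must cover [-200, +60] ms")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def window(self, lo_ms: float, hi_ms: float,
               open_interval: bool = False) -> np.ndarray:
        if open_interval:
            return (self.time_ms > lo_ms) & (self.time_ms < hi_ms)
        return (self.time_ms >= lo_ms) & (self.time_ms <= hi_ms)


@dataclass
class MEPResult:
    """Per-trial audit and kept-trial summary for one condition block."""

    audit: pd.DataFrame          # trial, kept, reject_reason, p2p_mV
    mean_p2p: float
    sd_p2p: float
    n_kept: int
    n_rejected: int
    condition: str
    prepulse_abs_mean_mV: float

    @property
    def fraction_rejected(self) -> float:
        n = self.n_kept + self.n_rejected
        return self.n_rejected / n if n else float("nan")


@dataclass
class GroupStats:
    """t-based group summary (df = n - 1 for paired, pooled for independent)."""

    n: int
    mean: float
    sd: float
    ci95_low: float
    ci95_high: float
    t_stat: float
    df: int
    p_value: float


@dataclass
class ConditionComparison:
    percent_change_of_means: float
    mean_percent_change: float
    median_percent_change: float
    stats: GroupStats
    per_participant_percent_change: np.ndarray = field(repr=False,
                                                       default=None)


# ---------------------------------------------------------------------------
# Chain operations


def baseline_correct(trials: EMGTrialSet) -> EMGTrialSet:
    """Subtract each trial's mean over [-20, -5] ms from the whole trace."""
    win = trials.window(*BASELINE_WINDOW_MS)
    if not win.any():
        raise ValueError("baseline window [-20, -5] ms not present")
    data = trials.data - trials.data[:, win].mean(axis=1, keepdims=True)
    return EMGTrialSet(data, trials.fs, trials.time_ms, trials.condition,
                       trials.participant_id)


def rms_reject(trials: EMGTrialSet,
               sd_criterion: float = RMS_SD_CRITERION) -> np.ndarray:
    """Flag pre-activated trials by block-relative RMS.

    RMS is computed over [-200, +13] ms omitting the open interval
    (-5, +5) ms around the pulse artifact; trials whose RMS exceeds the
    block mean + 2.5 SD (one-sided, strict inequality, statistics over all
    trials in the set) are flagged.
    """
    if trials.n_trials < 3:
        raise ValueError("rms_reject needs >= 3 trials")
    win = trials.window(*RMS_WINDOW_MS) & ~trials.window(*RMS_OMIT_MS,
                                                         open_interval=True)
    if not win.any():
        raise ValueError("RMS window not present")
    rms = np.sqrt(np.mean(trials.data[:, win] ** 2, axis=1))
    thresh = rms.mean() + sd_criterion * rms.std(ddof=0)
    return rms > thresh


def biphasic_check(trials: EMGTrialSet,
                   noise_k: float = BIPHASIC_NOISE_K) -> np.ndarray:
    """True for trials with a biphasic deflection in [15, 40] ms.

    Operationalized as opposite-sign excursions each exceeding
    ``noise_k`` x the trial's pre-stimulus noise SD (over [-200, -20] ms),
    at distinct samples within the window.
    """
    win = trials.window(*BIPHASIC_WINDOW_MS)
    if not win.any():
        raise ValueError("biphasic window [15, 40] ms not present")
    noise_win = trials.window(*NOISE_WINDOW_MS)
    sigma = trials.data[:, noise_win].std(axis=1, ddof=0)
    sigma = np.maximum(sigma, 1e-12)
    seg = trials.data[:, win]
    return (seg.max(axis=1) > noise_k * sigma) & \
           (seg.min(axis=1) < -noise_k * sigma)


def peak_to_peak(trials: EMGTrialSet) -> np.ndarray:
    """Min-to-max voltage over the 18-50 ms post-pulse window (>= 0)."""
    win = trials.window(*P2P_WINDOW_MS)
    if not win.any():
        raise ValueError("peak-to-peak window [18, 50] ms not present")
    seg = trials.data[:, win]
    return seg.max(axis=1) - seg.min(axis=1)


def outlier_reject(p2p: np.ndarray,
                   sd_criterion: float = OUTLIER_SD_CRITERION) -> np.ndarray:
    """Flag amplitudes above mean + 5 SD of the surviving trials (one pass)."""
    p2p = np.asarray(p2p, dtype=float)
    if p2p.size < 3:
        raise ValueError("outlier_reject needs >= 3 surviving trials")
    return p2p > p2p.mean() + sd_criterion * p2p.std(ddof=0)


def quantify_meps(trials: EMGTrialSet,
                  rms_sd: float = RMS_SD_CRITERION,
                  biphasic_k: float = BIPHASIC_NOISE_K,
                  outlier_sd: float = OUTLIER_SD_CRITERION) -> MEPResult:
    """Run the full chain and summarize kept-trial peak-to-peak amplitudes."""
    corrected = baseline_correct(trials)
    n = corrected.n_trials
    reason = np.array(["none"] * n, dtype=object)

    rms_flag = rms_reject(corrected, rms_sd)
    reason[rms_flag] = "rms"

    biph_ok = biphasic_check(corrected, biphasic_k)
    reason[(reason == "none") & ~biph_ok] = "not_biphasic"

    p2p = peak_to_peak(corrected)
    surviving = reason == "none"
    if surviving.sum() >= 3:
        out_flag = outlier_reject(p2p[surviving], outlier_sd)
        idx = np.flatnonzero(surviving)[out_flag]
        reason[idx] = "outlier"
    kept = reason == "none"

    pre_win = corrected.window(*PREPULSE_EMG_WINDOW_MS)
    prepulse = float(np.abs(corrected.data[kept][:, pre_win]).mean()) \
        if kept.any() else float("nan")
    audit = pd.DataFrame({"trial": np.arange(n), "kept": kept,
                          "reject_reason": reason, "p2p_mV": p2p})
    kept_p2p = p2p[kept]
    return MEPResult(
        audit=audit,
        mean_p2p=float(kept_p2p.mean()) if kept.any() else float("nan"),
        sd_p2p=float(kept_p2p.std(ddof=1)) if kept.sum() > 1 else float("nan"),
        n_kept=int(kept.sum()), n_rejected=int(n - kept.sum()),
        condition=trials.condition, prepulse_abs_mean_mV=prepulse)


# ---------------------------------------------------------------------------
# Statistics


def percent_change(a_mean: float, b_mean: float) -> float:
    """100 * (a - b) / b."""
    if b_mean == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (a_mean - b_mean) / b_mean


def _t_summary(d: np.ndarray, df: int):
    mean = d.mean()
    sd = d.std(ddof=1)
    se = sd / np.sqrt(d.size)
    if se == 0:
        raise ValueError("zero-variance differences: t undefined")
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    return mean, sd, t, mean - tcrit * se, mean + tcrit * se, p


def paired_t(x, y) -> GroupStats:
    """Two-sided paired t-test on per-participant values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired_t needs equal-length arrays, n >= 2")
    d = x - y
    df = d.size - 1
    mean, sd, t, lo, hi, p = _t_summary(d, df)
    return GroupStats(n=d.size, mean=float(mean), sd=float(sd),
                      ci95_low=float(lo), ci95_high=float(hi),
                      t_stat=float(t), df=df, p_value=float(p))


def group_compare_independent(x, y) -> GroupStats:
    """Pooled-variance two-sample t-test, df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per group")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        raise ValueError("zero pooled variance: t undefined")
    diff = x.mean() - y.mean()
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    return GroupStats(n=n1 + n2, mean=float(diff),
                      sd=float(np.sqrt(sp2)),
                      ci95_low=float(diff - tcrit * se),
                      ci95_high=float(diff + tcrit * se),
                      t_stat=float(t), df=df, p_value=float(p))


def simple_linreg(x, y) -> dict:
    """Ordinary least squares y = a + b x with R^2, F(1, n-2) and p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("simple_linreg needs >= 3 paired observations")
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValueError("x has zero variance")
    b = np.sum((x - xm) * (y - ym)) / sxx
    a = ym - b * xm
    resid = y - (a + b * x)
    ss_res = np.sum(resid ** 2)
    ss_tot = np.sum((y - ym) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    df = n - 2
    if ss_res == 0:
        f = float("inf")
        p = 0.0
    else:
        f = (ss_tot - ss_res) / (ss_res / df)
        p = float(stats.f.sf(f, 1, df))
    return {"slope": float(b), "intercept": float(a), "r2": float(r2),
            "f_stat": float(f), "df": (1, df), "p_value": p}


def compare_conditions(a_means, b_means) -> ConditionComparison:
    """Paired comparison of per-participant condition means (a vs b).

    Reports the paired t-test on the means, the percent change of the group
    means, and the cohort mean and median of per-participant percent
    changes (the latter is the right-skew-robust summary).
    """
    a = np.asarray(a_means, dtype=float)
    b = np.asarray(b_means, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need paired data for n >= 2 participants")
    per = 100.0 * (a - b) / b
    if np.allclose(a, b):
        st = GroupStats(n=a.size, mean=0.0, sd=0.0, ci95_low=0.0,
                        ci95_high=0.0, t_stat=float("nan"), df=a.size - 1,
                        p_value=float("nan"))
    else:
        st = paired_t(a, b)
    return ConditionComparison(
        percent_change_of_means=percent_change(a.mean(), b.mean()),
        mean_percent_change=float(per.mean()),
        median_percent_change=float(np.median(per)),
        stats=st, per_participant_percent_change=per)
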