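"""Alpha-ITC trough/peak/slope features and group-level comparisons.

For each participant the beat-locked alpha-band ITC time series is reduced
to the local minimum in the pre-beat window [-222, -99] ms (the trough,
the moment of deepest phase desynchronization) and the local maximum in
the post-beat window [0, 101] ms (the peak).  The slope is the rise from
trough to peak per second; its sign says whether the participant shows the
desynchronization-then-synchronization profile.

Local extrema use strict neighbor comparison with plateau handling (a
plateau counts once, at its center sample, ties broken toward the earlier
time); when the window contains no interior extremum the global extremum
within the window is used as a documented fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mep import GroupStats, paired_t  # noqa: F401  (re-exported here)

TROUGH_WINDOW_MS = (-222.0, -99.0)
PEAK_WINDOW_MS = (0.0, 101.0)


@dataclass(frozen=True)
class ITCFeatures:
    trough_time_ms: float
    trough_itc: float
    peak_time_ms: float
    peak_itc: float
    slope: float          # ITC units per second
    rise: float           # bare ITC difference peak - trough
    slope_positive: bool


def _local_extrema(values: np.ndarray, mode: str) -> list[int]:
    """Indices of interior local extrema with plateau handling.

    Runs of equal values count once, at their center sample (the earlier
    of the two middles for even-length runs); a run is an extremum only if
    both neighbors exist and lie on the appropriate side.
    """
    v = values if mode == "min" else -values
    idx = []
    i = 0
    n = v.size
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if i > 0 and j < n - 1 and v[i - 1] > v[i] and v[j + 1] > v[i]:
            idx.append((i + j) // 2)
        i = j + 1
    return idx


def _find_extremum(times_ms: np.ndarray, values: np.ndarray,
                   window_ms: tuple[float, float],
                   mode: str) -> tuple[float, float]:
    times_ms = np.asarray(times_ms, dtype=float)
    values = np.asarray(values, dtype=float)
    if times_ms[0] > window_ms[0] or times_ms[-1] < window_ms[1]:
        raise ValueError(f"series does not cover window {window_ms}")
    sel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    t_win, v_win = times_ms[sel], values[sel]
    cand = _local_extrema(v_win, mode)
    if cand:
        vals = v_win[cand]
        best = vals.min() if mode == "min" else vals.max()
        # tie between equal-valued extrema -> earlier time
        i = cand[int(np.flatnonzero(vals == best)[0])]
    else:
        # no interior extremum: fall back to the window-global extremum
        i = int(np.argmin(v_win) if mode == "min" else np.argmax(v_win))
    return float(t_win[i]), float(v_win[i])


def find_trough(times_ms, alpha_itc,
                window_ms: tuple[float, float] = TROUGH_WINDOW_MS
                ) -> tuple[float, float]:
    """Deepest interior local minimum in the pre-beat window."""
    return _find_extremum(times_ms, alpha_itc, window_ms, "min")


def find_peak(times_ms, alpha_itc,
              window_ms: tuple[float, float] = PEAK_WINDOW_MS
              ) -> tuple[float, float]:
    """Highest interior local maximum in the post-beat window."""
    return _find_extremum(times_ms, alpha_itc, window_ms, "max")


def slope(trough: tuple[float, float], peak: tuple[float, float]) -> float:
    """Rise from trough to peak in ITC units per second."""
    (t_tr, v_tr), (t_pk, v_pk) = trough, peak
    if t_pk <= t_tr:
        raise ValueError("peak time must follow trough time")
    return (v_pk - v_tr) / ((t_pk - t_tr) / 1000.0)


def extract_features(times_ms, alpha_itc,
                     trough_window_ms=TROUGH_WINDOW_MS,
                     peak_window_ms=PEAK_WINDOW_MS) -> ITCFeatures:
    """Full trough/peak/slope feature set for one participant."""
    trough = find_trough(times_ms, alpha_itc, trough_window_ms)
    peak = find_peak(times_ms, alpha_itc, peak_window_ms)
    return ITCFeatures(
        trough_time_ms=trough[0], trough_itc=trough[1],
        peak_time_ms=peak[0], peak_itc=peak[1],
        slope=slope(trough, peak), rise=peak[1] - trough[1],
        slope_positive=peak[1] > trough[1])


def positive_slope_fraction(features: list[ITCFeatures]) -> float:
    """Fraction of participants with a positive trough-to-peak rise."""
    if not features:
        raise ValueError("empty feature list")
    return sum(f.slope_positive for f in features) / len(features)
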