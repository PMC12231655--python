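"""Minimal deterministic EEG preprocessing for beat-locked analyses.

Covers the non-ICA steps of a resting-state pipeline: 1-49 Hz zero-phase
4th-order Butterworth band-pass, polyphase downsampling to 1000 Hz, average
re-referencing, and epoching around strong-beat events.  Channel/epoch
rejection, ICA and interpolation are intentionally absent: synthetic inputs
are artifact-free by construction and those stages are published tools in
their own right, not part of this pipeline's computation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

BANDPASS_LOW_HZ = 1.0
BANDPASS_HIGH_HZ = 49.0
TARGET_FS_HZ = 1000.0
EPOCH_WINDOW_MS = (-800.0, 800.0)


@dataclass
class EEGEpochs:
    """Beat-locked EEG epochs: channels x samples x trials, in microvolts.

    ``time_ms`` is beat-relative (0 = strong-beat onset), uniform and
    strictly increasing.
    """

    data: np.ndarray
    fs: float
    time_ms: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x samples x trials")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length mismatch")
        if self.data.shape[1] != self.time_ms.size:
            raise ValueError("time_ms length mismatch")
        dt = np.diff(self.time_ms)
        if dt.size and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("time_ms must be uniform and increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epochs contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def pick(self, names: list[str]) -> "EEGEpochs":
        idx = [self.channel_names.index(n) for n in names]
        return EEGEpochs(self.data[idx], self.fs, self.time_ms, list(names))


def _butter_bandpass_sos(fs: float, low: float, high: float):
    if fs <= 2 * high:
        raise ValueError(f"fs={fs} too low for high cutoff {high} Hz")
    return signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(data: np.ndarray, fs: float, low: float = BANDPASS_LOW_HZ,
             high: float = BANDPASS_HIGH_HZ, axis: int = -1) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward).

    Odd-extension padding of min(3 low-cut periods, n-1) samples suppresses
    the filter transient at the segment edges; the forward-backward pass
    makes the net response phase-neutral and removes DC.
    """
    data = np.asarray(data, dtype=float)
    sos = _butter_bandpass_sos(fs, low, high)
    n = data.shape[axis]
    padlen = int(min(n - 1, 3 * fs / low))
    return signal.sosfiltfilt(sos, data, axis=axis, padlen=padlen)


def resample(data: np.ndarray, fs: float, target_fs: float = TARGET_FS_HZ,
             axis: int = -1) -> np.ndarray:
    """Anti-aliased polyphase downsampling; identity when target_fs == fs."""
    if target_fs > fs:
        raise ValueError("upsampling not supported")
    if target_fs == fs:
        return np.asarray(data, dtype=float)
    frac = Fraction(target_fs / fs).limit_denominator(10000)
    return signal.resample_poly(np.asarray(data, dtype=float),
                                frac.numerator, frac.denominator, axis=axis)


def rereference_average(epochs: EEGEpochs) -> EEGEpochs:
    """Subtract the instantaneous channel mean (channel mean becomes 0)."""
    if epochs.data.shape[0] < 2:
        raise ValueError("average reference needs >= 2 channels")
    data = epochs.data - epochs.data.mean(axis=0, keepdims=True)
    return EEGEpochs(data, epochs.fs, epochs.time_ms, list(epochs.channel_names))


def epoch(series: np.ndarray, fs: float, event_times_s: np.ndarray,
          channel_names: list[str],
          window_ms: tuple[float, float] = EPOCH_WINDOW_MS) -> EEGEpochs:
    """Cut beat-locked trials out of a continuous recording.

    Events whose window falls outside the recording are dropped and the
    count is logged.  Time 0 of the returned epochs is the event onset.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[None, :]
    n_samp = series.shape[1]
    i0 = int(np.round(window_ms[0] / 1000.0 * fs))
    i1 = int(np.round(window_ms[1] / 1000.0 * fs))
    trials, dropped = [], 0
    for t0 in np.asarray(event_times_s, dtype=float):
        c = int(np.round(t0 * fs))
        if c + i0 < 0 or c + i1 >= n_samp:
            dropped += 1
            continue
        trials.append(series[:, c + i0: c + i1 + 1])
    if dropped:
        logger.info("epoch: dropped %d out-of-bounds events", dropped)
    if not trials:
        raise ValueError("no events inside the recording")
    data = np.stack(trials, axis=2)
    time_ms = (np.arange(i0, i1 + 1) / fs) * 1000.0
    return EEGEpochs(data, fs, time_ms, list(channel_names))


def preprocess_epochs(epochs: EEGEpochs, low: float = BANDPASS_LOW_HZ,
                      high: float = BANDPASS_HIGH_HZ,
                      target_fs: float = TARGET_FS_HZ) -> EEGEpochs:
    """Band-pass, resample and average-reference already-epoched data.

    The filter runs per trial along the sample axis; the window midpoint is
    preserved by resampling because epoch lengths are chosen as integer
    multiples of the decimation factor.
    """
    data = bandpass(epochs.data, epochs.fs, low, high, axis=1)
    if target_fs != epochs.fs:
        data = resample(data, epochs.fs, target_fs, axis=1)
        time_ms = epochs.time_ms[0] + np.arange(data.shape[1]) * 1000.0 / target_fs
    else:
        time_ms = epochs.time_ms
    out = EEGEpochs(data, target_fs, time_ms, list(epochs.channel_names))
    return rereference_average(out)


# ---------------------------------------------------------------------------
# I/O: delimited epoch matrices (+ JSON sidecar), events TSV, EDF


def read_epochs_delimited(prefix) -> EEGEpochs:
    """Read the delimited epoch format written by the synthetic generator.

    ``<prefix>.tsv`` holds one row per (trial, channel) in trial-major order,
    columns are samples; ``<prefix>.json`` is the sidecar header with fs,
    window and channel names.
    """
    prefix = Path(prefix)
    with open(prefix.with_suffix(".json")) as fh:
        hdr = json.load(fh)
    mat = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    n_ch = len(hdr["channel_names"])
    n_tr = int(hdr["n_trials"])
    data = mat.reshape(n_tr, n_ch, -1).transpose(1, 2, 0)
    time_ms = hdr["window_ms"][0] + np.arange(data.shape[1]) * 1000.0 / hdr["fs"]
    return EEGEpochs(data, float(hdr["fs"]), time_ms, hdr["channel_names"])


def read_events_tsv(path) -> pd.DataFrame:
    """Events table with columns onset_s, kind (strong|weak|pulse), condition."""
    ev = pd.read_csv(path, sep="\t")
    missing = {"onset_s", "kind"} - set(ev.columns)
    if missing:
        raise ValueError(f"events file missing columns: {sorted(missing)}")
    return ev


def read_raw_edf(path):
    """Load a continuous EDF recording; returns (data_uV, fs, channel_names)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)
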