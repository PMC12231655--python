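"""Beat schedules, metronome audio and TMS pulse plans.

Experiments that pair rhythmic sound with TMS need three things before any
signal is recorded: the grid of strong/weak beat times for a stimulus block,
the metronome audio realizing that grid, and the pulse-time plan per
condition.  Pulses in the entrained condition precede each selected strong
beat by a fixed offset (default -200 ms, the pre-beat window of maximal mu
desynchronization); the auditory control fires on the beat (0 ms); the
standard condition has no audio but copies the entrained plan's
inter-stimulus-interval sequence so that pulse pacing is matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

TONE_FREQ_HZ = 262.0       # middle C
TONE_DUR_S = 0.060
TONE_RAMP_S = 0.010        # linear rise and fall
WEAK_AMP_RATIO = 0.1       # weak beat = 1/10 strong amplitude
SETMS_OFFSET_MS = -200.0
MIN_ISI_S = 3.0

CONDITIONS = ("setms", "standard", "auditory_control")


@dataclass(frozen=True)
class BeatSchedule:
    """Strong/weak auditory event times for one stimulus block."""

    tempo_bpm: float
    duration_s: float
    meter: str  # "duple" or "quadruple"
    strong_beat_times_s: np.ndarray
    weak_beat_times_s: np.ndarray

    @property
    def strong_period_s(self) -> float:
        group = 2 if self.meter == "duple" else 4
        return group * 60.0 / self.tempo_bpm


@dataclass(frozen=True)
class StimulusPlan:
    """TMS pulse times for one condition with ISI guarantees."""

    condition: str
    pulse_times_s: np.ndarray
    offset_ms: float
    isi_s: np.ndarray = field(default_factory=lambda: np.empty(0))


def make_beat_schedule(tempo_bpm: float, duration_s: float,
                       meter: str = "duple") -> BeatSchedule:
    """Lay beats at k*60/tempo from 0; strong beats at group boundaries.

    In duple meter strong and weak beats alternate, giving a strong-beat
    period of 2*(60/tempo) (~1 s at 120 BPM); quadruple meter accents every
    fourth beat.
    """
    if not (30.0 <= tempo_bpm <= 300.0):
        raise ValueError(f"tempo_bpm must be in [30, 300], got {tempo_bpm}")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if meter not in ("duple", "quadruple"):
        raise ValueError(f"meter must be duple or quadruple, got {meter!r}")
    period = 60.0 / tempo_bpm
    n_beats = int(np.floor(duration_s / period)) + 1
    beats = np.arange(n_beats) * period
    beats = beats[beats < duration_s]
    if beats.size == 0:
        beats = np.array([0.0])
    group = 2 if meter == "duple" else 4
    strong = beats[::group]
    weak = np.setdiff1d(beats, strong)
    return BeatSchedule(tempo_bpm, duration_s, meter, strong, weak)


def _tone(fs: int, amplitude: float) -> np.ndarray:
    n = int(round(TONE_DUR_S * fs))
    t = np.arange(n) / fs
    tone = amplitude * np.sin(2 * np.pi * TONE_FREQ_HZ * t)
    n_ramp = int(round(TONE_RAMP_S * fs))
    env = np.ones(n)
    env[:n_ramp] = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
    env[n - n_ramp:] = np.linspace(1.0, 0.0, n_ramp)
    return tone * env


def synth_metronome(schedule: BeatSchedule, fs_audio: int = 44100) -> np.ndarray:
    """Render the metronome: 262 Hz tones, 60 ms long, 10 ms linear ramps.

    Weak beats are attenuated to 1/10 of the strong-beat amplitude.  Peak
    amplitude is kept at <= 1 by construction (strong tones at 0.9).
    """
    if fs_audio < 8000:
        raise ValueError("fs_audio must be >= 8000 Hz")
    all_times = np.sort(np.concatenate([schedule.strong_beat_times_s,
                                        schedule.weak_beat_times_s]))
    if all_times.size > 1 and np.min(np.diff(all_times)) < TONE_DUR_S:
        raise ValueError("tempo too fast: 60 ms tones would overlap")
    n_total = int(np.ceil(schedule.duration_s * fs_audio))
    audio = np.zeros(n_total)
    for times, amp in ((schedule.strong_beat_times_s, 0.9),
                       (schedule.weak_beat_times_s, 0.9 * WEAK_AMP_RATIO)):
        tone = _tone(fs_audio, amp)
        for t0 in times:
            i0 = int(round(t0 * fs_audio))
            i1 = min(i0 + tone.size, n_total)
            audio[i0:i1] += tone[: i1 - i0]
    return audio


def write_wav(path, audio: np.ndarray, fs_audio: int = 44100) -> None:
    """Write PCM 16-bit WAV (deterministic for identical inputs)."""
    pcm = np.clip(audio, -1.0, 1.0)
    wavfile.write(path, fs_audio, (pcm * 32767).astype(np.int16))


def schedule_pulses(schedule: BeatSchedule, condition: str,
                    min_isi_s: float = MIN_ISI_S,
                    n_pulses: int | None = None,
                    seed: int = 0,
                    paired_setms: StimulusPlan | None = None) -> StimulusPlan:
    """Assign pulses to strong beats with all ISIs >= min_isi_s.

    Candidate pulse times are strong beats plus the condition offset
    (-200 ms for setms, 0 for auditory_control).  Hosting beats are chosen
    by stepping every k-th strong beat with k drawn per gap from the
    smallest set {k0, k0+1, k0+2} satisfying the ISI floor, so intervals
    vary yet stay reproducible under the seed.  The standard condition
    carries no audio and copies the ISI sequence of its paired setms plan
    verbatim.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if condition == "standard":
        if paired_setms is None:
            raise ValueError("standard condition requires paired_setms plan")
        isi = np.asarray(paired_setms.isi_s, dtype=float)
        pulses = np.concatenate([[paired_setms.pulse_times_s[0]],
                                 paired_setms.pulse_times_s[0] + np.cumsum(isi)])
        return StimulusPlan("standard", pulses, 0.0, isi)

    offset_s = (SETMS_OFFSET_MS / 1000.0) if condition == "setms" else 0.0
    strong = np.asarray(schedule.strong_beat_times_s, dtype=float)
    period = schedule.strong_period_s
    k0 = int(np.ceil(min_isi_s / period))
    rng = np.random.default_rng(seed)
    idx = [0]
    while True:
        k = int(rng.integers(k0, k0 + 3))
        nxt = idx[-1] + k
        if nxt >= strong.size:
            break
        idx.append(nxt)
    hosts = strong[np.asarray(idx)]
    if n_pulses is not None:
        if n_pulses > hosts.size:
            raise ValueError(
                f"cannot host {n_pulses} pulses with min ISI {min_isi_s} s "
                f"in {schedule.duration_s} s")
        hosts = hosts[:n_pulses]
    pulses = hosts + offset_s
    # ISIs from the un-offset host beats: the constant offset cancels, and
    # this avoids spurious sub-floor values from float rounding of -0.2 s
    isi = np.diff(hosts)
    if isi.size and isi.min() < min_isi_s - 1e-12:
        raise ValueError("internal error: ISI floor violated")
    return StimulusPlan(condition, pulses, offset_s * 1000.0, isi)
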