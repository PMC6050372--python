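"""Signal synthesis: colored background noise plus class-specific transients.

The background is a per-channel mixture of white and 1/f-shaped ("pink")
Gaussian noise with total variance ``noise_sd**2``.  Each movement adds a
raised-cosine evoked transient — the class's spatial pattern times a smooth
temporal envelope — to all channels.  The offline simulator plays out a cued
task schedule; the closed-loop simulator draws self-paced movements from a
thinned Poisson process.
"""

from __future__ import annotations

import numpy as np

from .recording import Recording, make_events
from .subject import CLASSES, SubjectModel, TaskSchedule

__all__ = [
    "simulate_offline_task",
    "simulate_closed_loop_segment",
    "simulate_rest",
    "draw_movement_times",
]

#: Default sampling rate (Hz).  1,000 Hz matches whole-head MEG acquisition;
#: 250 Hz is the desk-scale default — every downstream stage is rate-agnostic.
DEFAULT_FS = 250.0

#: Minimum spacing between self-paced movements = evoked support + margin.
REFRACTORY_MARGIN_MS = 1600.0


#: Knee of the 1/f spectrum (Hz): flat below, 1/f above.  Mirrors the
#: acquisition high-pass of a real recording chain; without it, slow drift
#: shared by neighbouring cues of a block would carry spurious class
#: information into the features.
PINK_KNEE_HZ = 0.5


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, knee_hz: float = PINK_KNEE_HZ) -> np.ndarray:
    """1/f-power-shaped Gaussian noise (flat below ``knee_hz``), unit sample
    variance per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, knee_hz))
    shaping[0] = 0.0  # no DC offset
    pink = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def make_noise(subject: SubjectModel, n_samples: int,
               rng: np.random.Generator, fs: float) -> np.ndarray:
    """Background noise, total per-channel variance ``noise_sd**2``."""
    p = subject.pink_fraction
    out = np.zeros((subject.n_channels, n_samples))
    if p < 1.0:
        out += np.sqrt(1.0 - p) * rng.standard_normal((subject.n_channels, n_samples))
    if p > 0.0:
        out += np.sqrt(p) * _pink_noise(rng, subject.n_channels, n_samples, fs)
    return subject.noise_sd * out


def evoked_envelope(subject: SubjectModel, fs: float) -> np.ndarray:
    """Raised-cosine bump sampled at ``fs`` over the evoked duration."""
    n = max(int(round(subject.evoked_duration_ms * fs / 1000.0)), 1)
    t = np.arange(n) / n
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def add_evoked(signal: np.ndarray, onset_sample: int, pattern: np.ndarray,
               envelope: np.ndarray) -> None:
    """Add ``pattern[:, None] * envelope`` in place, clipped to the signal."""
    stop = min(onset_sample + envelope.size, signal.shape[1])
    if stop <= onset_sample:
        return
    signal[:, onset_sample:stop] += pattern[:, None] * envelope[: stop - onset_sample]


def _rng_for(subject: SubjectModel, purpose: int, seed=None) -> np.random.Generator:
    entropy = [int(subject.rng_seed) if seed is None else int(seed), purpose]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def simulate_offline_task(
    subject: SubjectModel,
    schedule: TaskSchedule,
    *,
    sampling_rate: float = DEFAULT_FS,
    seed=None,
    tail_s: float = 2.0,
) -> Recording:
    """Play out a cued grasp/open task and return the recording.

    Each execution cue is followed, after the subject's reaction latency, by
    an evoked transient with the cue's class pattern; a ``subject_movement``
    event is logged at the transient onset.  The first
    ``schedule.baseline_duration_s`` seconds are movement-free baseline.
    """
    if schedule.cues and subject.common_pattern is None:
        raise ValueError("subject patterns not initialized; use make_subject()")
    fs = float(sampling_rate)
    duration_s = schedule.end_time_s + tail_s
    n_samples = int(round(duration_s * fs))
    rng = _rng_for(subject, 0xB10C, seed)
    signal = make_noise(subject, n_samples, rng, fs)
    env = evoked_envelope(subject, fs)

    rows = [(int(round(t * 1000)), "instruction", lab) for lab, t in schedule.blocks]
    for t_s, label in schedule.cues:
        cue_ms = int(round(t_s * 1000))
        onset_ms = cue_ms + int(round(subject.reaction_latency_ms))
        add_evoked(signal, int(round(onset_ms * fs / 1000.0)),
                   subject.pattern(label), env)
        rows.append((cue_ms, "cue", label))
        rows.append((onset_ms, "subject_movement", label))
    return Recording(sampling_rate=fs, signal=signal, events=make_events(rows))


def simulate_rest(
    subject: SubjectModel,
    duration_s: float,
    *,
    sampling_rate: float = DEFAULT_FS,
    seed=None,
) -> Recording:
    """Movement-free recording (background noise only)."""
    fs = float(sampling_rate)
    rng = _rng_for(subject, 0x4E57, seed)
    signal = make_noise(subject, int(round(duration_s * fs)), rng, fs)
    return Recording(sampling_rate=fs, signal=signal)


def draw_movement_times(
    rng: np.random.Generator,
    duration_ms: float,
    rate_per_min: float,
    min_spacing_ms: float,
) -> np.ndarray:
    """Thinned Poisson event times (ms): homogeneous arrivals at
    ``rate_per_min``, discarding any arrival within ``min_spacing_ms`` of the
    last kept one.  The kept process is renewal with mean gap
    ``min_spacing + 1/rate``."""
    if rate_per_min <= 0:
        raise ValueError("movement rate must be > 0")
    if min_spacing_ms >= 60000.0 / rate_per_min * 10:
        raise ValueError("movement rate infeasible under the spacing constraint")
    lam = rate_per_min / 60000.0  # events per ms
    times, t, last = [], 0.0, -np.inf
    while True:
        t += rng.exponential(1.0 / lam)
        if t >= duration_ms:
            break
        if t - last >= min_spacing_ms:
            times.append(t)
            last = t
    return np.asarray(times)


def simulate_closed_loop_segment(
    subject: SubjectModel,
    duration_s: float = 600.0,
    movement_rate_per_min: float = 5.0,
    seed=None,
    *,
    sampling_rate: float = DEFAULT_FS,
) -> Recording:
    """Free-movement segment with a *fixed* subject (no adaptation).

    Self-paced movements occur at thinned-Poisson times with random classes;
    each adds an evoked transient at its onset.  The adaptive closed-loop
    session (decoder in the loop, feedback updating ``s``) lives in
    :mod:`megbmi.session`.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    fs = float(sampling_rate)
    n_samples = int(round(duration_s * fs))
    rng = _rng_for(subject, 0xF4EE, seed)
    signal = make_noise(subject, n_samples, rng, fs)
    env = evoked_envelope(subject, fs)

    min_spacing = subject.evoked_duration_ms + REFRACTORY_MARGIN_MS
    times = draw_movement_times(rng, duration_s * 1000.0 - min_spacing,
                                movement_rate_per_min, min_spacing)
    rows = []
    for t_ms in times:
        label = CLASSES[rng.integers(2)]
        onset_ms = int(round(t_ms))
        add_evoked(signal, int(round(onset_ms * fs / 1000.0)),
                   subject.pattern(label), env)
        rows.append((onset_ms, "subject_movement", label))
    return Recording(sampling_rate=fs, signal=signal, events=make_events(rows))
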