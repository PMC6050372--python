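"""Windowed z-score features.

The decoder's feature representation: per-channel means over a causal 500-ms
window, emitted every 100 ms, z-scored against statistics estimated from the
initial 50 s of the offline task.  A frame's timestamp is its window END, so
the same arithmetic serves batch (offline) and streaming (online) use; the
epoch grid runs from -2,000 to +1,000 ms around each execution cue (31
offsets).

Baseline statistics are computed on the window means themselves (not raw
samples) so that baseline frames have zero mean and unit SD at the feature
level by construction; a ``mode="sample"`` switch computes them on raw
samples instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Recording

__all__ = [
    "BaselineStats",
    "FeatureFrameSeries",
    "EpochFeatures",
    "fit_baseline_stats",
    "sliding_features",
    "epoch_features",
    "EPOCH_OFFSETS_MS",
]

WINDOW_MS = 500
STEP_MS = 100

#: Epoch grid relative to the execution cue: -2,000..+1,000 ms, 31 offsets.
EPOCH_OFFSETS_MS = np.arange(-2000, 1001, STEP_MS, dtype=np.int64)


@dataclass(frozen=True)
class BaselineStats:
    mean: np.ndarray          # per channel
    sd: np.ndarray            # per channel, all > 0
    source_duration_s: float
    window_ms: int = WINDOW_MS
    mode: str = "window"

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            raise ValueError("baseline SDs must all be > 0")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "mean": self.mean.tolist(), "sd": self.sd.tolist(),
            "source_duration_s": self.source_duration_s,
            "window_ms": int(self.window_ms), "mode": self.mode,
        }, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "BaselineStats":
        d = json.loads(Path(path).read_text())
        return cls(mean=np.asarray(d["mean"]), sd=np.asarray(d["sd"]),
                   source_duration_s=d["source_duration_s"],
                   window_ms=d["window_ms"], mode=d["mode"])


@dataclass(frozen=True)
class FeatureFrameSeries:
    times_ms: np.ndarray      # int64 window-end times, spacing == step_ms
    frames: np.ndarray        # (n_frames, n_channels), z-scored
    window_ms: int = WINDOW_MS
    step_ms: int = STEP_MS

    def __post_init__(self) -> None:
        if len(self.times_ms) > 1 and np.any(np.diff(self.times_ms) != self.step_ms):
            raise ValueError("frame spacing must equal step_ms exactly")
        if not np.isfinite(self.frames).all():
            raise ValueError("frames must be finite")

    @property
    def n_channels(self) -> int:
        return self.frames.shape[1]

    def to_csv(self, path) -> None:
        """Long format: time_ms, channel, value."""
        n_t, n_c = self.frames.shape
        pd.DataFrame({
            "time_ms": np.repeat(self.times_ms, n_c),
            "channel": np.tile(np.arange(n_c), n_t),
            "value": self.frames.ravel(),
        }).to_csv(path, index=False)


@dataclass(frozen=True)
class EpochFeatures:
    data: np.ndarray          # (n_trials, n_offsets, n_channels)
    offsets_ms: np.ndarray
    labels: list
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.labels):
            raise ValueError("one label per trial required")
        if self.data.shape[1] != len(self.offsets_ms):
            raise ValueError("offset grid mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def offset_index(self, offset_ms: int) -> int:
        idx = np.nonzero(self.offsets_ms == offset_ms)[0]
        if idx.size == 0:
            raise KeyError(f"offset {offset_ms} ms not in epoch grid")
        return int(idx[0])

    def at_offsets(self, offsets_ms) -> np.ndarray:
        """Trials x (len(offsets) * channels) matrix, offsets concatenated."""
        cols = [self.data[:, self.offset_index(o), :] for o in offsets_ms]
        return np.concatenate(cols, axis=1)

    def save_npz(self, path) -> None:
        np.savez(path, data=self.data, offsets_ms=self.offsets_ms,
                 labels=np.asarray(self.labels, dtype=object),
                 n_dropped=self.n_dropped)

    @classmethod
    def load_npz(cls, path) -> "EpochFeatures":
        with np.load(path, allow_pickle=True) as f:
            return cls(data=f["data"], offsets_ms=f["offsets_ms"],
                       labels=list(f["labels"]), n_dropped=int(f["n_dropped"]))

    def to_csv(self, path) -> None:
        """Long format: trial, label, offset_ms, channel, value."""
        n_t, n_o, n_c = self.data.shape
        pd.DataFrame({
            "trial": np.repeat(np.arange(n_t), n_o * n_c),
            "label": np.repeat(self.labels, n_o * n_c),
            "offset_ms": np.tile(np.repeat(self.offsets_ms, n_c), n_t),
            "channel": np.tile(np.arange(n_c), n_t * n_o),
            "value": self.data.ravel(),
        }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Core window arithmetic
# ---------------------------------------------------------------------------

def _window_samples(fs: float, window_ms: int, step_ms: int) -> tuple:
    w = window_ms * fs / 1000.0
    d = step_ms * fs / 1000.0
    if w <= 0 or abs(w - round(w)) > 1e-9 or d <= 0 or abs(d - round(d)) > 1e-9:
        raise ValueError(
            "window and step must be positive multiples of the sample period"
        )
    return int(round(w)), int(round(d))


def window_means(signal: np.ndarray, fs: float,
                 window_ms: int = WINDOW_MS, step_ms: int = STEP_MS) -> tuple:
    """Raw (un-z-scored) causal window means.

    Returns ``(times_ms, means)`` where the frame at time t averages samples
    in (t - window, t].  Uses the same per-window reduction as a direct
    ``signal[:, a:b].mean()`` so streaming and batch paths agree bit-exactly.
    """
    w, d = _window_samples(fs, window_ms, step_ms)
    n = signal.shape[1]
    if n < w:
        raise ValueError("recording shorter than one window")
    view = np.lib.stride_tricks.sliding_window_view(signal, w, axis=1)
    means = view[:, ::d, :].mean(axis=-1).T  # (n_frames, n_channels)
    n_frames = means.shape[0]
    times = window_ms + step_ms * np.arange(n_frames, dtype=np.int64)
    return times, means


def single_window_mean(signal: np.ndarray, fs: float, end_sample: int,
                       window_ms: int = WINDOW_MS) -> np.ndarray:
    """One causal window mean ending at ``end_sample`` (exclusive)."""
    w, _ = _window_samples(fs, window_ms, window_ms)
    return signal[:, end_sample - w:end_sample].mean(axis=1)


def fit_baseline_stats(
    recording: Recording,
    baseline_duration_s: float = 50.0,
    *,
    window_ms: int = WINDOW_MS,
    step_ms: int = STEP_MS,
    mode: str = "window",
) -> BaselineStats:
    """Per-channel mean/SD from the initial baseline span.

    ``mode="window"`` (default) computes the statistics over the causal
    window means of the baseline so that z-scored baseline frames have unit
    scale by construction; ``mode="sample"`` uses raw samples.
    """
    n_base = int(round(baseline_duration_s * recording.sampling_rate))
    if recording.n_samples < n_base:
        raise ValueError("recording shorter than the baseline duration")
    base = recording.signal[:, :n_base]
    if mode == "window":
        _, means = window_means(base, recording.sampling_rate, window_ms, step_ms)
        mean = means.mean(axis=0)
        sd = means.std(axis=0, ddof=1)
    elif mode == "sample":
        mean = base.mean(axis=1)
        sd = base.std(axis=1, ddof=1)
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    if np.any(sd <= 0):
        raise ValueError("zero-variance channel in the baseline span")
    return BaselineStats(mean=mean, sd=sd, source_duration_s=baseline_duration_s,
                         window_ms=window_ms, mode=mode)


def sliding_features(
    recording: Recording,
    stats: BaselineStats,
    *,
    window_ms: int = WINDOW_MS,
    step_ms: int = STEP_MS,
) -> FeatureFrameSeries:
    """Causal z-scored window means at ``step_ms`` intervals.

    Purely causal: truncating the recording reproduces every frame whose
    window still fits, bit-exactly.
    """
    if stats.mean.shape[0] != recording.n_channels:
        raise ValueError("baseline stats channel count mismatch")
    times, means = window_means(recording.signal, recording.sampling_rate,
                                window_ms, step_ms)
    frames = (means - stats.mean) / stats.sd
    return FeatureFrameSeries(times_ms=times, frames=frames,
                              window_ms=window_ms, step_ms=step_ms)


def zscore_frame(raw_mean: np.ndarray, stats: BaselineStats) -> np.ndarray:
    return (raw_mean - stats.mean) / stats.sd


def epoch_features(
    series: FeatureFrameSeries,
    cue_times_ms,
    labels,
    offsets_ms: np.ndarray = EPOCH_OFFSETS_MS,
) -> EpochFeatures:
    """Cut per-cue epochs from the frame series.

    Trials whose grid extends beyond the available frames are dropped with a
    warning; label order of surviving trials is preserved.
    """
    cue_times_ms = np.asarray(cue_times_ms, dtype=np.int64)
    labels = list(labels)
    if len(cue_times_ms) != len(labels):
        raise ValueError("cue_times and labels must have equal length")
    offsets_ms = np.asarray(offsets_ms, dtype=np.int64)

    index = {int(t): i for i, t in enumerate(series.times_ms)}
    kept, kept_labels, dropped = [], [], 0
    for cue, lab in zip(cue_times_ms, labels):
        rows = [index.get(int(cue + off)) for off in offsets_ms]
        if any(r is None for r in rows):
            dropped += 1
            continue
        kept.append(series.frames[rows, :])
        kept_labels.append(lab)
    if not kept:
        raise ValueError("no trial survives epoching")
    if dropped:
        warnings.warn(f"dropped {dropped} trial(s) with incomplete epochs",
                      stacklevel=2)
    return EpochFeatures(data=np.stack(kept), offsets_ms=offsets_ms,
                         labels=kept_labels, n_dropped=dropped)
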