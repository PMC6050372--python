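"""Continuous multichannel recordings and their on-disk layout.

A :class:`Recording` is a channels x samples float matrix plus a time-stamped
event log (instructions, execution cues, subject movements).  Recordings are
written either as an ``.npy`` matrix or as a CSV with one header row of
channel labels; the event log is a plain CSV ``time_ms,kind,label``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["Recording", "save_recording", "load_recording"]

EVENT_KINDS = ("instruction", "cue", "subject_movement")


@dataclass
class Recording:
    sampling_rate: float
    signal: np.ndarray  # (n_channels, n_samples)
    events: pd.DataFrame = field(default_factory=lambda: _empty_events())

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        ev = self.events
        if len(ev):
            if (ev["time_ms"] < 0).any() or (ev["time_ms"] > self.duration_ms).any():
                raise ValueError("event times must lie within the recording")
            moves = ev[ev["kind"] == "subject_movement"]
            if moves["label"].isna().any():
                raise ValueError("subject_movement events must carry a class label")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.sampling_rate

    def events_of(self, kind: str) -> pd.DataFrame:
        return self.events[self.events["kind"] == kind].reset_index(drop=True)


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({"time_ms": pd.Series(dtype=np.int64),
                         "kind": pd.Series(dtype=object),
                         "label": pd.Series(dtype=object)})


def make_events(rows) -> pd.DataFrame:
    """Build an event frame from (time_ms, kind, label) triples, time-sorted."""
    if not rows:
        return _empty_events()
    df = pd.DataFrame(rows, columns=["time_ms", "kind", "label"])
    df["time_ms"] = df["time_ms"].astype(np.int64)
    return df.sort_values("time_ms", kind="stable").reset_index(drop=True)


def save_recording(rec: Recording, directory, *, signal_format: str = "npy") -> Path:
    """Write signal + events + metadata under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if signal_format == "npy":
        np.save(directory / "signal.npy", rec.signal)
    elif signal_format == "csv":
        labels = [f"ch{i:03d}" for i in range(rec.n_channels)]
        pd.DataFrame(rec.signal.T, columns=labels).to_csv(
            directory / "signal.csv", index=False
        )
    else:
        raise ValueError(f"unknown signal_format {signal_format!r}")
    rec.events.to_csv(directory / "events.csv", index=False)
    meta = {"sampling_rate": float(rec.sampling_rate),
            "n_channels": int(rec.n_channels),
            "n_samples": int(rec.n_samples),
            "signal_format": signal_format}
    (directory / "recording.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return directory


def load_recording(directory) -> Recording:
    directory = Path(directory)
    meta = yaml.safe_load((directory / "recording.yaml").read_text())
    if meta["signal_format"] == "npy":
        signal = np.load(directory / "signal.npy")
    else:
        signal = pd.read_csv(directory / "signal.csv").to_numpy().T
    events = pd.read_csv(directory / "events.csv")
    if len(events):
        events["time_ms"] = events["time_ms"].astype(np.int64)
        events["label"] = events["label"].where(pd.notna(events["label"]), None)
    else:
        events = _empty_events()
    return Recording(sampling_rate=meta["sampling_rate"], signal=signal, events=events)
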