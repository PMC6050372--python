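"""Closed-loop BMI training session.

The virtual subject's signal is streamed through the online decoder at
100-ms steps; detected movements drive a two-posture robotic hand whose
state persists until the next command.  After each self-paced subject
movement, the session judges — with the very same matching rule the offline
scorer uses — whether the robot entered the matching posture within the
1-s window, and feeds the outcome to the subject's adaptation rule, so a
decoder that tracks the subject's movements lets separability grow while an
uninformative (sham) decoder reinforces only at chance.

Causality: the signal is materialized incrementally — a movement's evoked
transient is injected (with the subject's separability *at that moment*)
only when the streaming clock reaches it — and every frame is the same
causal window mean the batch preprocessing computes, so batch re-processing
of the logged recording reproduces the streamed frames bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import json
import numpy as np
import pandas as pd

from .decoder import DecoderState, OnlineDecoder, decode_step
from .features import BaselineStats, zscore_frame, single_window_mean
from .recording import Recording, make_events, save_recording
from .simulate import (REFRACTORY_MARGIN_MS, add_evoked, draw_movement_times,
                       evoked_envelope, make_noise)
from .subject import CLASSES, SubjectModel, adaptation_update

__all__ = ["RobotTimeline", "SessionLog", "run_training_session",
           "replay_session", "greedy_match", "save_session_log"]


@dataclass(frozen=True)
class RobotTimeline:
    """Ordered posture command list; posture persists between commands."""
    commands: tuple  # ((time_ms, posture), ...)
    initial_posture: str = "open"

    def __post_init__(self) -> None:
        times = [t for t, _ in self.commands]
        if any(nxt <= prev for prev, nxt in zip(times, times[1:])):
            raise ValueError("command times must be strictly increasing")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.commands, columns=["time_ms", "posture"])


@dataclass
class SessionLog:
    recording: Recording
    robot: RobotTimeline
    score_times_ms: np.ndarray
    smoothed_scores: np.ndarray
    s_trajectory: list            # [(time_ms, s), ...]; non-decreasing s
    rewards: list                 # [(time_ms, reward), ...]
    duration_s: float
    feedback: bool
    seed: int = 0

    @property
    def movements(self) -> pd.DataFrame:
        return self.recording.events_of("subject_movement")


def greedy_match(movement_times_ms, movement_labels, commands, match_window_ms=1000.0):
    """Pair subject movements with robot commands, earliest-first.

    A movement at ``t`` is correct iff an unconsumed command with the same
    posture occurs in ``(t, t + match_window]``; each command can satisfy at
    most one movement, and movements are served in time order.  Returns a
    boolean array over movements.
    """
    consumed = np.zeros(len(commands), dtype=bool)
    matched = np.zeros(len(movement_times_ms), dtype=bool)
    for i, (t, lab) in enumerate(zip(movement_times_ms, movement_labels)):
        for j, (tc, posture) in enumerate(commands):
            if consumed[j] or posture != lab:
                continue
            if t < tc <= t + match_window_ms:
                matched[i] = True
                consumed[j] = True
                break
            if tc > t + match_window_ms:
                break
    return matched


def run_training_session(
    subject: SubjectModel,
    decoder: OnlineDecoder,
    stats: BaselineStats,
    duration_s: float = 600.0,
    feedback: bool = True,
    movement_rate_per_min: float = 5.0,
    seed: int = 0,
    *,
    sampling_rate: float = 250.0,
    match_window_ms: float = 1000.0,
    initial_posture: str = "open",
):
    """Run one closed-loop training session.

    Returns ``(SessionLog, updated SubjectModel)``.  With ``feedback=False``
    the adaptation rule is never invoked and ``s`` stays constant.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if subject.n_channels != decoder.n_channels:
        raise ValueError("decoder/subject channel mismatch")
    fs = float(sampling_rate)
    step_ms = decoder.step_ms
    window_ms = stats.window_ms
    n_samples = int(round(duration_s * fs))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E55]))

    # Movement times/classes are the subject's volition: independent of the
    # feedback loop, so they may be drawn upfront.  Amplitudes may not.
    min_spacing = subject.evoked_duration_ms + REFRACTORY_MARGIN_MS
    move_times = draw_movement_times(
        rng, duration_s * 1000.0 - (min_spacing + match_window_ms),
        movement_rate_per_min, min_spacing)
    move_times = np.asarray([int(round(t)) for t in move_times], dtype=np.int64)
    move_labels = [CLASSES[rng.integers(2)] for _ in move_times]

    signal = make_noise(subject, n_samples, rng, fs)
    env = evoked_envelope(subject, fs)

    state = DecoderState.fresh()
    commands, score_times, scores = [], [], []
    s_traj = [(0, subject.s)]
    rewards = []
    pending = list(zip(move_times.tolist(), move_labels))  # awaiting injection
    awaiting = []                                          # awaiting reward

    frame_times = np.arange(window_ms, int(duration_s * 1000) + 1, step_ms,
                            dtype=np.int64)
    for t in frame_times:
        # inject evoked transients for movements now in the past, using the
        # subject's *current* separability
        while pending and pending[0][0] < t:
            t_ev, lab = pending.pop(0)
            add_evoked(signal, int(round(t_ev * fs / 1000.0)),
                       subject.pattern(lab), env)
            awaiting.append((t_ev, lab))

        end_sample = int(round(t * fs / 1000.0))
        frame = zscore_frame(
            single_window_mean(signal, fs, end_sample, window_ms), stats)
        command, smoothed = decode_step(decoder, state, frame, float(t))
        score_times.append(t)
        scores.append(smoothed)
        if command is not None:
            commands.append((int(t), command))

        # settle rewards whose 1-s window has closed, oldest first
        while awaiting and t >= awaiting[0][0] + match_window_ms:
            t_ev, lab = awaiting.pop(0)
            done_times = [m for m, _ in zip(move_times, move_labels)
                          if m <= t_ev]
            done_labels = move_labels[: len(done_times)]
            matched = greedy_match(done_times, done_labels, commands,
                                   match_window_ms)
            reward = "correct" if matched[-1] else "incorrect"
            rewards.append((int(t_ev), reward))
            if feedback:
                new_subject = adaptation_update(subject, reward)
                if new_subject.s != subject.s:
                    s_traj.append((int(t), new_subject.s))
                subject = new_subject

    n_events = len(move_times)
    rows = [(t, "subject_movement", lab)
            for t, lab in zip(move_times.tolist(), move_labels)]
    recording = Recording(sampling_rate=fs, signal=signal,
                          events=make_events(rows))
    log = SessionLog(
        recording=recording,
        robot=RobotTimeline(commands=tuple(commands),
                            initial_posture=initial_posture),
        score_times_ms=np.asarray(score_times, dtype=np.int64),
        smoothed_scores=np.asarray(scores),
        s_trajectory=s_traj,
        rewards=rewards[:n_events],
        duration_s=duration_s,
        feedback=feedback,
        seed=int(seed),
    )
    return log, subject


def replay_session(log: SessionLog, decoder: OnlineDecoder,
                   stats: BaselineStats) -> RobotTimeline:
    """Re-decode the logged recording; must reproduce the logged commands."""
    rec = log.recording
    fs = rec.sampling_rate
    window_ms = stats.window_ms
    step_ms = decoder.step_ms
    if rec.n_channels != decoder.n_channels:
        raise ValueError("decoder/log channel mismatch")
    state = DecoderState.fresh()
    commands = []
    frame_times = np.arange(window_ms, int(log.duration_s * 1000) + 1, step_ms,
                            dtype=np.int64)
    for t in frame_times:
        end_sample = int(round(t * fs / 1000.0))
        frame = zscore_frame(
            single_window_mean(rec.signal, fs, end_sample, window_ms), stats)
        command, _ = decode_step(decoder, state, frame, float(t))
        if command is not None:
            commands.append((int(t), command))
    return RobotTimeline(commands=tuple(commands),
                         initial_posture=log.robot.initial_posture)


def save_session_log(log: SessionLog, directory, *, signal_format="npy") -> Path:
    """Session directory: recording files + commands/scores/trajectory CSVs
    plus a manifest with the seeds and settings."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_recording(log.recording, directory / "recording",
                   signal_format=signal_format)
    log.robot.as_frame().to_csv(directory / "commands.csv", index=False)
    pd.DataFrame({"time_ms": log.score_times_ms,
                  "smoothed_score": log.smoothed_scores}
                 ).to_csv(directory / "scores.csv", index=False)
    pd.DataFrame(log.s_trajectory, columns=["time_ms", "s"]
                 ).to_csv(directory / "s_trajectory.csv", index=False)
    pd.DataFrame(log.rewards, columns=["time_ms", "reward"]
                 ).to_csv(directory / "rewards.csv", index=False)
    manifest = {"duration_s": log.duration_s, "feedback": log.feedback,
                "seed": log.seed,
                "initial_posture": log.robot.initial_posture}
    (directory / "session.json").write_text(json.dumps(manifest, sort_keys=True))
    return directory
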