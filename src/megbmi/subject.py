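"""Parametric virtual subject for closed-loop MEG decoding simulations.

A :class:`SubjectModel` stands in for a human participant: it owns a pair of
class-specific evoked sensor patterns (grasp vs. open), a separability
parameter ``s`` scaling the distance between them, a colored-noise background,
and a reinforcement-style adaptation rule through which ``s`` can grow when
the subject receives correct feedback.  ``s`` is the model's operational
proxy for training-induced change in the cortical representation of the two
movements: the larger ``s``, the easier the movements are to tell apart from
the sensor signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SubjectModel",
    "TaskSchedule",
    "make_subject",
    "make_offline_schedule",
    "adaptation_update",
    "CLASSES",
]

#: Movement classes, in canonical order.
CLASSES = ("grasp", "open")

#: Reward tokens accepted by :func:`adaptation_update`.
REWARDS = ("correct", "incorrect", "none")


@dataclass(frozen=True)
class SubjectModel:
    """Generative parameters of a virtual subject.

    The evoked response to a movement of class *c* has the spatial pattern

    ``pattern_c = evoked_gain * u  +/-  (s / 2) * class_gain * v``

    where ``u`` (movement component, shared by both classes) and ``v``
    (class-difference direction, orthogonal to ``u``) are fixed unit-norm
    channel vectors drawn once per subject.  The between-class pattern
    distance is therefore exactly ``s * class_gain``: linear in ``s`` and
    zero at ``s = 0``.

    Amplitudes are in units of the per-channel background noise standard
    deviation (``noise_sd``).  The defaults place the untrained subject
    (s = 1) in the regime the study design needs: offline decoding clearly
    above chance but far from ceiling, and a movement-evoked response that
    the onset detector catches for only a minority of self-paced movements
    once its threshold is calibrated to 2 false positives/min, so reward
    events stay sparse enough for real and sham feedback to diverge.
    """

    n_channels: int = 84
    s: float = 1.0
    s_max: float = 3.0
    adaptation_rate: float = 0.1
    evoked_gain: float = 1.35
    class_gain: float = 2.5
    evoked_duration_ms: float = 400.0
    reaction_latency_ms: float = 100.0
    noise_sd: float = 1.0
    pink_fraction: float = 0.5
    rng_seed: int = 0
    common_pattern: np.ndarray = field(default=None, repr=False)
    diff_pattern: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError(f"n_channels must be >= 2, got {self.n_channels}")
        if self.s < 0:
            raise ValueError(f"separability s must be >= 0, got {self.s}")
        if self.adaptation_rate < 0:
            raise ValueError("adaptation_rate must be >= 0")
        if not (0.0 <= self.pink_fraction <= 1.0):
            raise ValueError("pink_fraction must lie in [0, 1]")
        if not np.isfinite([self.evoked_gain, self.class_gain, self.noise_sd]).all():
            raise ValueError("amplitudes must be finite")
        for name in ("common_pattern", "diff_pattern"):
            vec = getattr(self, name)
            if vec is not None and vec.shape != (self.n_channels,):
                raise ValueError(f"{name} must have length n_channels")

    # -- derived per-class patterns -------------------------------------
    def pattern(self, label: str) -> np.ndarray:
        """Evoked spatial pattern (peak amplitude per channel) for a class."""
        if label not in CLASSES:
            raise ValueError(f"unknown class {label!r}")
        sign = 1.0 if label == "grasp" else -1.0
        return (
            self.evoked_gain * self.common_pattern
            + sign * 0.5 * self.s * self.class_gain * self.diff_pattern
        )

    @property
    def pattern_grasp(self) -> np.ndarray:
        return self.pattern("grasp")

    @property
    def pattern_open(self) -> np.ndarray:
        return self.pattern("open")

    @property
    def evoked_span_ms(self) -> float:
        """Reaction latency plus evoked-envelope support, in ms."""
        return self.reaction_latency_ms + self.evoked_duration_ms


def make_subject(seed: int = 0, **params) -> SubjectModel:
    """Create a fully initialized :class:`SubjectModel`.

    Pattern directions are drawn once from the seeded generator and then
    fixed: the same ``(params, seed)`` always yields an identical subject.
    """
    model = SubjectModel(rng_seed=int(seed), **params)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0FFEE]))
    u = rng.standard_normal(model.n_channels)
    u /= np.linalg.norm(u)
    v = rng.standard_normal(model.n_channels)
    v -= (v @ u) * u  # orthogonalize so class difference is pure
    v /= np.linalg.norm(v)
    return dataclasses.replace(model, common_pattern=u, diff_pattern=v)


def adaptation_update(subject: SubjectModel, reward: str) -> SubjectModel:
    """Apply one reinforcement step to the subject's separability.

    ``correct`` feedback multiplies ``s`` by ``1 + adaptation_rate`` up to
    the cap ``s_max``; ``incorrect`` and ``none`` leave the subject
    unchanged.  All other fields are untouched.
    """
    if reward not in REWARDS:
        raise ValueError(f"unknown reward token {reward!r}")
    if reward != "correct":
        return subject
    new_s = min(subject.s * (1.0 + subject.adaptation_rate), subject.s_max)
    return dataclasses.replace(subject, s=new_s)


# ---------------------------------------------------------------------------
# Task schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskSchedule:
    """Cue timeline of one offline (open-loop) task.

    Movement instructions come in blocks; each block shows the movement word
    (grasp/open) and is followed by ``cues_per_block`` execution cues spaced
    ``cue_interval_s`` apart.  All times are seconds from recording start and
    lie on the 100-ms feature grid.
    """

    blocks: tuple  # ((label, instruction_time_s), ...)
    cues: tuple    # ((cue_time_s, label), ...)
    cues_per_class: int
    baseline_duration_s: float = 50.0

    def __post_init__(self) -> None:
        times = [t for t, _ in self.cues]
        if any(b >= a for a, b in zip(times[1:], times[:-1])):
            raise ValueError("cue times must be strictly increasing")
        if times and times[0] < self.baseline_duration_s:
            raise ValueError("all cues must follow the baseline period")
        for cls in CLASSES:
            n = sum(1 for _, lab in self.cues if lab == cls)
            if n != self.cues_per_class:
                raise ValueError(
                    f"class {cls!r} has {n} cues, expected {self.cues_per_class}"
                )

    @property
    def cue_times_ms(self) -> np.ndarray:
        return np.asarray([round(t * 1000) for t, _ in self.cues], dtype=np.int64)

    @property
    def labels(self) -> list:
        return [lab for _, lab in self.cues]

    @property
    def end_time_s(self) -> float:
        return self.cues[-1][0] if self.cues else self.baseline_duration_s


def make_offline_schedule(
    cues_per_class: int = 40,
    seed: int = 0,
    *,
    baseline_duration_s: float = 50.0,
    cue_interval_s: float = 5.5,
    cues_per_block: int = 4,
    instruction_lead_s: float = 2.0,
    inter_block_gap_s: float = 2.0,
) -> TaskSchedule:
    """Randomized block schedule: ``cues_per_class`` cues for each movement.

    Blocks of ``cues_per_block`` same-class cues (inter-cue interval 5.5 s)
    are ordered randomly; the instruction precedes the first cue of its
    block by ``instruction_lead_s``.
    """
    if cues_per_class < 1 or cues_per_class % cues_per_block:
        raise ValueError(
            f"cues_per_class must be a positive multiple of {cues_per_block}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5C4ED]))
    n_blocks = cues_per_class // cues_per_block
    order = [CLASSES[0]] * n_blocks + [CLASSES[1]] * n_blocks
    order = [order[i] for i in rng.permutation(2 * n_blocks)]

    blocks, cues = [], []
    t = baseline_duration_s
    for label in order:
        blocks.append((label, round(t, 1)))
        for j in range(cues_per_block):
            cues.append((round(t + instruction_lead_s + j * cue_interval_s, 1), label))
        t = cues[-1][0] + inter_block_gap_s
    return TaskSchedule(
        blocks=tuple(blocks),
        cues=tuple(cues),
        cues_per_class=cues_per_class,
        baseline_duration_s=baseline_duration_s,
    )
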