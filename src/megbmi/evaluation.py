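"""Scoring and statistics.

Four analyses mirror the study design:

* **Correct rate** — fraction of subject hand movements followed within 1 s
  by a robot command of the same posture, scored over 1-min segments at the
  start and end of training (greedy earliest pairing; one command satisfies
  at most one movement).
* **Nested 10-fold CV accuracy** — linear SVM on features concatenating the
  11 windows from -500 to +500 ms around the cue; the regularization
  strength is chosen by an inner 10-fold CV run on training folds only.
* **Per-channel discriminability** — one-way ANOVA F between classes of the
  0-500-ms window mean (the sensor-space analogue of a vertex-wise F map).
* **Crossover statistics** — paired t within each arm (pre vs. post), at
  Bonferroni-corrected alpha = 0.025 because two paired tests are run, and
  an unpaired t contrasting per-subject improvements between arms.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

from .cv import stratified_folds
from .decoder import C_GRID, _cv_accuracy, _fit_svc
from .features import EpochFeatures
from .session import SessionLog, greedy_match

__all__ = [
    "CorrectRateReport", "CVReport", "PairedTestResult", "ContrastResult",
    "correct_rate", "nested_cv_accuracy", "discriminability_map",
    "paired_comparison", "improvement_contrast", "CV_FEATURE_OFFSETS_MS",
]

#: Decoding-feature grid: 11 windows, -500..+500 ms around the cue.
CV_FEATURE_OFFSETS_MS = np.arange(-500, 501, 100, dtype=np.int64)

BONFERRONI_ALPHA = 0.025  # two paired t-tests (real arm, sham arm)


@dataclass(frozen=True)
class CorrectRateReport:
    segment_start_s: float
    segment_end_s: float
    n_movements: int
    n_correct: int
    rate: float | None  # None when no movements occurred (undefined)

    def __post_init__(self) -> None:
        if not (0 <= self.n_correct <= self.n_movements):
            raise ValueError("0 <= correct <= movements violated")


def correct_rate(log: SessionLog, segment_start_s: float, segment_end_s: float,
                 match_window_ms: float = 1000.0) -> CorrectRateReport:
    """Correct rate over ``[segment_start, segment_end)``.

    Pairing is computed over the whole session (identical to the online
    reward rule); the rate counts only movements inside the segment.  With
    zero movements the rate is undefined and reported as None.
    """
    if segment_end_s <= segment_start_s:
        raise ValueError("segment bounds inverted")
    moves = log.movements
    times = moves["time_ms"].to_numpy(dtype=np.int64)
    labels = moves["label"].tolist()
    matched = greedy_match(times, labels, list(log.robot.commands),
                           match_window_ms)
    lo, hi = segment_start_s * 1000.0, segment_end_s * 1000.0
    in_seg = (times >= lo) & (times < hi)
    n_mov = int(in_seg.sum())
    n_cor = int(matched[in_seg].sum())
    return CorrectRateReport(segment_start_s, segment_end_s, n_mov, n_cor,
                             rate=(n_cor / n_mov) if n_mov else None)


@dataclass(frozen=True)
class CVReport:
    fold_accuracies: tuple
    mean_accuracy_pct: float
    fold_C: tuple
    feature_dim: int
    n_per_class: dict

    def as_dict(self) -> dict:
        return asdict(self)


def nested_cv_accuracy(
    epochs: EpochFeatures,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
    *,
    C_grid=C_GRID,
    offsets_ms=CV_FEATURE_OFFSETS_MS,
) -> CVReport:
    """Nested stratified CV accuracy of the 11-window concatenated feature.

    For each outer fold the regularization strength is picked by an inner
    ``inner_folds``-fold CV on the training folds alone (ties toward the
    strongest regularization), the model is refit on the full training set,
    and the held-out fold is scored; the report averages outer accuracies.
    """
    X = epochs.at_offsets(offsets_ms)
    y = np.asarray(epochs.labels)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0CE4]))
    outer = stratified_folds(y, outer_folds, rng)
    accs, chosen = [], []
    for test_idx in outer:
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        X_tr, y_tr = X[mask], y[mask]
        inner = stratified_folds(y_tr, inner_folds, rng)
        inner_accs = [_cv_accuracy(X_tr, y_tr, C, inner) for C in C_grid]
        C = float(C_grid[int(np.argmax(inner_accs))])
        model = _fit_svc(X_tr, y_tr, C)
        accs.append(float(np.mean(model.predict(X[test_idx]) == y[test_idx])))
        chosen.append(C)
    classes, counts = np.unique(y, return_counts=True)
    return CVReport(
        fold_accuracies=tuple(accs),
        mean_accuracy_pct=float(np.mean(accs) * 100.0),
        fold_C=tuple(chosen),
        feature_dim=X.shape[1],
        n_per_class={str(c): int(n) for c, n in zip(classes, counts)},
    )


def discriminability_map(epochs: EpochFeatures, offset_ms: int = 500) -> dict:
    """Per-channel one-way ANOVA F between classes of the 0-500-ms feature.

    ``offset_ms=500`` selects the frame whose 500-ms window covers
    (0, 500] ms after the cue.  With two groups F equals the squared
    pooled-variance t statistic.
    """
    y = np.asarray(epochs.labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both movement classes required")
    X = epochs.data[:, epochs.offset_index(offset_ms), :]
    groups = [X[y == c] for c in classes]
    if any(len(g) == 0 for g in groups):
        raise ValueError("a class is empty")
    F, _ = sps.f_oneway(*groups, axis=0)
    return {
        "F": np.asarray(F),
        "group_sizes": {str(c): int((y == c).sum()) for c in classes},
        "offset_ms": int(offset_ms),
    }


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    significant: bool
    n: int
    mean_difference: float
    degenerate: bool = False


def paired_comparison(pre, post, alpha: float = BONFERRONI_ALPHA) -> PairedTestResult:
    """Two-sided paired Student's t-test on post - pre (df = n - 1)."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise ValueError("pre/post must be paired (equal length)")
    keep = np.isfinite(pre) & np.isfinite(post)
    pre, post = pre[keep], post[keep]
    n = pre.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = post - pre
    df = n - 1
    sd = d.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(d).max())):
        if d.mean() == 0:
            return PairedTestResult(0.0, df, 1.0, False, n, 0.0, degenerate=True)
        t = np.inf if d.mean() > 0 else -np.inf
        return PairedTestResult(float(t), df, 0.0, True, n,
                                float(d.mean()), degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return PairedTestResult(float(t), df, float(p), bool(p < alpha), n,
                            float(d.mean()))


@dataclass(frozen=True)
class ContrastResult:
    t: float
    df: int
    p: float
    mean_difference: float  # mean(real) - mean(sham)
    degenerate: bool = False


def improvement_contrast(real_improvements, sham_improvements) -> ContrastResult:
    """Unpaired two-sided Student's t-test on per-subject improvements."""
    a = np.asarray(real_improvements, float)
    b = np.asarray(sham_improvements, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each arm needs at least 2 subjects")
    diff = float(a.mean() - b.mean())
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    scale = max(1.0, float(np.abs(a).max()), float(np.abs(b).max()))
    if pooled <= (1e-12 * scale) ** 2:
        if diff == 0:
            return ContrastResult(0.0, df, 1.0, 0.0, degenerate=True)
        return ContrastResult(float(np.sign(diff) * np.inf), df, 0.0, diff,
                              degenerate=True)
    t = diff / np.sqrt(pooled * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    return ContrastResult(float(t), df, float(p), diff)
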