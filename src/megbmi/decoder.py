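"""The online decoder: movement-onset detector plus grasp/open classifier.

Two components, trained on the same offline task:

* :class:`PeakWindowClassifier` — a linear-margin (SVM) grasp/open
  classifier operating on a single feature frame.  Training scans every
  offset of the epoch grid, estimates cross-validated accuracy per offset,
  and refits at the accuracy peak (ties break toward the earliest offset).
* :class:`OnsetDetector` — a linear move-vs-rest scorer over one frame, a
  causal smoother (linear-kernel regression from the last ``k`` raw scores
  to the movement indicator), a threshold and a refractory period.

The sham decoder shares the onset stage (true movement timing) but trains
the class stage on permuted movement-type labels, so the posture feedback it
drives is uninformative about which movement was made.

Regularization for every linear trainer is chosen from a logarithmic grid by
internal cross-validation; ties break toward stronger regularization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Ridge
from sklearn.svm._liblinear import set_verbosity_wrap, train_wrap

set_verbosity_wrap(0)

from .cv import stratified_folds
from .features import (BaselineStats, EpochFeatures, sliding_features)
from .recording import Recording

__all__ = [
    "PeakWindowClassifier",
    "MoveRestScorer",
    "CausalScoreSmoother",
    "OnsetDetector",
    "OnlineDecoder",
    "DecoderState",
    "train_class_decoder",
    "train_onset_detector",
    "make_real_decoder",
    "make_sham_decoder",
    "calibrate_threshold",
    "decode_step",
    "count_detections",
    "decoder_to_json",
    "decoder_from_json",
]

#: Regularization grid (SVC ``C``), ascending: ties prefer stronger reg.
C_GRID = tuple(10.0 ** np.arange(-3, 4))

DEFAULT_REFRACTORY_MS = 1000.0


class _LinearSVM:
    """Minimal linear SVM (squared hinge, L2, balanced class weights).

    Solves exactly the problem :class:`sklearn.svm.LinearSVC` solves, through
    the same liblinear routine, but without the per-call validation overhead
    that dominates when thousands of small fits are made during the offset
    scan and the nested CV.
    """

    __slots__ = ("coef_", "intercept_", "classes_", "C")

    def __init__(self, C=1.0):
        self.C = C

    def fit(self, X, y):
        X = np.ascontiguousarray(X, dtype=np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError("binary classification only")
        yf = y_idx.astype(np.float64)
        counts = np.bincount(y_idx)
        balanced = (len(yf) / (2.0 * counts)).astype(np.float64)
        # dual coordinate descent when p >= n, primal Newton otherwise
        # (same rule as LinearSVC's dual="auto"); both solve the identical
        # L2-regularized squared-hinge problem
        solver = 1 if X.shape[0] <= X.shape[1] else 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            raw, _ = train_wrap(X, yf, False, solver, 1e-4, 1.0, self.C,
                                balanced, 5000, 0, 0.1,
                                np.ones(len(yf)))
        self.coef_ = np.ascontiguousarray(raw[:, :-1])
        self.intercept_ = np.ascontiguousarray(raw[:, -1])
        return self

    def decision_function(self, X):
        return np.asarray(X) @ self.coef_.ravel() + self.intercept_[0]

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def _fit_svc(X, y, C):
    return _LinearSVM(C=C).fit(X, y)


def _cv_accuracy(X, y, C, folds) -> float:
    accs = []
    for test_idx in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        svc = _fit_svc(X[mask], y[mask], C)
        accs.append(float(np.mean(svc.predict(X[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


class PeakWindowClassifier(BaseEstimator, ClassifierMixin):
    """Grasp/open linear SVM at the offset with peak training-CV accuracy.

    Parameters
    ----------
    cv_folds : stratified folds used for the per-offset accuracy scan.
    C_grid : candidate regularization strengths (ascending).
    random_state : seeds the fold shuffling.

    Fitted attributes
    -----------------
    offset_ms_ : selected epoch offset (ms relative to the cue).
    cv_accuracy_per_offset_ : training CV accuracy at each scanned offset.
    C_ : selected regularization strength.
    svc_ : the refit LinearSVC; classes_ its label order.
    """

    def __init__(self, cv_folds: int = 10, C_grid=C_GRID, random_state: int = 0,
                 scan_repeats: int = 3, scan_C_grid=None):
        self.cv_folds = cv_folds
        self.C_grid = C_grid
        self.random_state = random_state
        self.scan_repeats = scan_repeats
        self.scan_C_grid = scan_C_grid

    def fit(self, epochs: EpochFeatures, y=None) -> "PeakWindowClassifier":
        labels = np.asarray(epochs.labels if y is None else y)
        if np.unique(labels).size < 2:
            raise ValueError("class decoder needs both movement classes")
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.random_state), 0xC1A55]))
        # cap folds at the smallest class so tiny training sets still work
        classes, counts = np.unique(labels, return_counts=True)
        if counts.min() < 2:
            raise ValueError("class decoder needs >= 2 trials per class")
        # repeated splits: the arg-max over 31 offsets is only as good as the
        # per-offset accuracy estimates, so average them over a few splits
        fold_sets = [stratified_folds(labels,
                                      min(self.cv_folds, int(counts.min())),
                                      rng)
                     for _ in range(max(1, self.scan_repeats))]

        # coarse C grid while ranking offsets, full grid at the winner
        scan_grid = (self.scan_C_grid if self.scan_C_grid is not None
                     else tuple(self.C_grid[::3]) or self.C_grid)

        per_offset = []
        for k in range(len(epochs.offsets_ms)):
            X = epochs.data[:, k, :]
            accs = [float(np.mean([_cv_accuracy(X, labels, C, folds)
                                   for folds in fold_sets]))
                    for C in scan_grid]
            per_offset.append(max(accs))
        k_best = int(np.argmax(per_offset))  # first max -> earliest offset
        X = epochs.data[:, k_best, :]
        final_accs = [float(np.mean([_cv_accuracy(X, labels, C, folds)
                                     for folds in fold_sets]))
                      for C in self.C_grid]
        best = int(np.argmax(final_accs))  # first max -> strongest reg on ties
        self.offset_index_ = k_best
        self.offset_ms_ = int(epochs.offsets_ms[k_best])
        self.cv_accuracy_per_offset_ = np.asarray(per_offset)
        self.cv_accuracy_ = float(max(per_offset[k_best], final_accs[best]))
        self.C_ = float(self.C_grid[best])
        self.svc_ = _fit_svc(epochs.data[:, k_best, :], labels, self.C_)
        self.classes_ = self.svc_.classes_
        self.n_channels_ = epochs.n_channels
        return self

    def predict(self, frames: np.ndarray):
        frames = np.atleast_2d(frames)
        if frames.shape[1] != self.n_channels_:
            raise ValueError("frame channel count mismatch")
        return self.svc_.predict(frames)


class MoveRestScorer(BaseEstimator):
    """Linear margin scorer separating movement frames from rest frames."""

    def __init__(self, cv_folds: int = 5, C_grid=C_GRID, random_state: int = 0):
        self.cv_folds = cv_folds
        self.C_grid = C_grid
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MoveRestScorer":
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.random_state), 0x04537]))
        # C selection on a subsample keeps training fast on long recordings;
        # the final fit uses every frame
        if len(y) > 1200:
            sel = np.sort(np.concatenate(
                [rng.choice(np.nonzero(y == c)[0],
                            max(2, int(round(1200 * (y == c).mean()))),
                            replace=False)
                 for c in np.unique(y)]))
            X_sel, y_sel = X[sel], y[sel]
        else:
            X_sel, y_sel = X, y
        folds = stratified_folds(y_sel, self.cv_folds, rng)
        accs = [_cv_accuracy(X_sel, y_sel, C, folds) for C in self.C_grid]
        self.C_ = float(self.C_grid[int(np.argmax(accs))])
        self.svc_ = _fit_svc(X, y, self.C_)
        self.n_channels_ = X.shape[1]
        return self

    def score_frames(self, X: np.ndarray) -> np.ndarray:
        return self.svc_.decision_function(np.atleast_2d(X))


class CausalScoreSmoother(BaseEstimator):
    """Causal linear-kernel regression over the last ``n_lags`` raw scores.

    Fit maps lagged raw-score vectors to the {0,1} movement indicator by
    ridge regression (the posterior mean of a linear-kernel GP with
    observation noise ``alpha``).  Early frames are left-padded by edge
    replication, both offline and online.
    """

    def __init__(self, n_lags: int = 5, alpha: float = 1.0):
        self.n_lags = n_lags
        self.alpha = alpha

    @staticmethod
    def _lag_matrix(scores: np.ndarray, n_lags: int) -> np.ndarray:
        padded = np.concatenate([np.repeat(scores[:1], n_lags - 1), scores])
        return np.lib.stride_tricks.sliding_window_view(padded, n_lags)

    def fit(self, raw_scores: np.ndarray, indicator: np.ndarray,
            sample_mask=None) -> "CausalScoreSmoother":
        X = self._lag_matrix(np.asarray(raw_scores, float), self.n_lags)
        y = np.asarray(indicator, float)
        if sample_mask is not None:
            X, y = X[sample_mask], y[sample_mask]
        model = Ridge(alpha=self.alpha).fit(X, y)
        self.weights_ = model.coef_.copy()   # oldest-to-newest lag order
        self.intercept_ = float(model.intercept_)
        return self

    def transform(self, raw_scores: np.ndarray) -> np.ndarray:
        X = self._lag_matrix(np.asarray(raw_scores, float), self.n_lags)
        return X @ self.weights_ + self.intercept_

    def smooth_one(self, recent: list) -> float:
        """Smoothed score from the most recent raw scores (edge-replicated)."""
        k = self.n_lags
        vec = ([recent[0]] * (k - len(recent)) + list(recent))[-k:]
        return float(np.dot(self.weights_, vec) + self.intercept_)


@dataclass(frozen=True)
class OnsetDetector:
    scorer: MoveRestScorer
    smoother: CausalScoreSmoother
    threshold: float
    refractory_ms: float = DEFAULT_REFRACTORY_MS

    def __post_init__(self) -> None:
        if np.isnan(self.threshold):
            raise ValueError("threshold must be a number (+/-inf allowed)")
        if self.refractory_ms < 0:
            raise ValueError("refractory must be >= 0")

    def smoothed_scores(self, frames: np.ndarray) -> np.ndarray:
        return self.smoother.transform(self.scorer.score_frames(frames))


@dataclass(frozen=True)
class OnlineDecoder:
    onset: OnsetDetector
    classifier: PeakWindowClassifier
    step_ms: int = 100
    meta: dict = None

    @property
    def n_channels(self) -> int:
        return self.classifier.n_channels_


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_class_decoder(epochs: EpochFeatures, cv_folds: int = 10,
                        C_grid=C_GRID, seed: int = 0) -> PeakWindowClassifier:
    return PeakWindowClassifier(cv_folds=cv_folds, C_grid=C_grid,
                                random_state=seed).fit(epochs)


def _movement_frame_masks(frame_times: np.ndarray, movement_times: np.ndarray,
                          positive_span_ms, guard_span_ms) -> tuple:
    """Boolean masks (positive, rest) over frames given movement onsets.

    A frame is positive when its timestamp falls in ``(t + span0, t + span1]``
    after some movement at ``t``; frames inside the wider guard interval of
    any movement are excluded from rest.
    """
    pos = np.zeros(frame_times.size, dtype=bool)
    guard = np.zeros(frame_times.size, dtype=bool)
    for t in movement_times:
        rel = frame_times - t
        pos |= (rel > positive_span_ms[0]) & (rel <= positive_span_ms[1])
        guard |= (rel > guard_span_ms[0]) & (rel <= guard_span_ms[1])
    return pos, ~guard


def train_onset_detector(
    recording: Recording,
    stats: BaselineStats,
    event_log=None,
    *,
    smoother_lags: int = 5,
    smoother_alpha: float = 1.0,
    train_fp_rate: float = 0.01,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
    C_grid=C_GRID,
    seed: int = 0,
) -> OnsetDetector:
    """Train the move-vs-rest stage on an offline recording.

    Frames shortly after each logged movement onset are positives; frames
    clear of any movement's neighborhood are rest.  The initial threshold is
    the rest-score quantile at ``1 - train_fp_rate`` (frame-level false
    positives); :func:`calibrate_threshold` re-sets it to an events-per-
    minute target before the closed-loop session.
    """
    events = recording.events if event_log is None else event_log
    moves = events[events["kind"] == "subject_movement"]
    if moves.empty:
        raise ValueError("no movement events to train the onset detector")
    series = sliding_features(recording, stats)
    t_moves = moves["time_ms"].to_numpy(dtype=np.int64)

    # positives: frames whose windows cover the bulk of the evoked response
    # (roughly 80% overlap and up) — early partial-overlap frames are left
    # in the guard zone so the detector learns to fire at the response
    # peak, where the class decoder is informative, not at its leading edge
    span_hi = 400.0 + stats.window_ms  # envelope + window memory
    pos, rest = _movement_frame_masks(
        series.times_ms, t_moves,
        positive_span_ms=(0.8 * stats.window_ms, span_hi),
        guard_span_ms=(-stats.window_ms, span_hi + stats.window_ms),
    )
    if not rest.any():
        raise ValueError("no rest frames available")

    used = pos | rest
    y = pos[used].astype(int)
    scorer = MoveRestScorer(C_grid=C_grid, random_state=seed).fit(
        series.frames[used], y)

    # Decorrelate detection from classification: remove the scorer's
    # projection on the grasp-vs-open mean-difference axis.  Otherwise
    # frames selected for a high onset score carry noise aligned with that
    # chance overlap, biasing the class decision at exactly the moments it
    # is used.  Uses the true movement labels, which the onset stage is
    # trained on in both the real and the sham pipeline.
    labels = moves["label"].to_numpy()
    if np.unique(labels).size == 2:
        frame_label = np.empty(len(series.times_ms), dtype=object)
        for t, lab in zip(t_moves, labels):
            sel = (series.times_ms - t > 0) & (series.times_ms - t <= span_hi)
            frame_label[sel] = lab
        means = [series.frames[pos & (frame_label == lab)].mean(axis=0)
                 for lab in np.unique(labels)]
        axis = means[0] - means[1]
        norm = np.linalg.norm(axis)
        if norm > 0:
            axis /= norm
            w = scorer.svc_.coef_.ravel()
            scorer.svc_.coef_ = (w - (w @ axis) * axis)[None, :]
    raw = scorer.score_frames(series.frames)
    smoother = CausalScoreSmoother(n_lags=smoother_lags, alpha=smoother_alpha)
    smoother.fit(raw, pos.astype(float), sample_mask=used)
    smoothed = smoother.transform(raw)
    threshold = float(np.quantile(smoothed[rest], 1.0 - train_fp_rate))
    return OnsetDetector(scorer=scorer, smoother=smoother,
                         threshold=threshold, refractory_ms=refractory_ms)


def make_real_decoder(epochs: EpochFeatures, recording: Recording,
                      stats: BaselineStats, seed: int = 0,
                      **onset_kw) -> OnlineDecoder:
    """Real decoder: class stage on true labels, onset stage on true timing."""
    clf = train_class_decoder(epochs, seed=seed)
    onset = train_onset_detector(recording, stats, seed=seed, **onset_kw)
    return OnlineDecoder(onset=onset, classifier=clf,
                         meta={"kind": "real", "seed": int(seed)})


def make_sham_decoder(epochs: EpochFeatures, recording: Recording,
                      stats: BaselineStats, seed: int = 0,
                      **onset_kw) -> OnlineDecoder:
    """Sham decoder: identical pipeline, movement-type labels permuted.

    Only the movement TYPE is randomized — the onset stage is trained on the
    true movement timing, so the sham decoder still reacts to movements but
    its grasp/open choice carries no information.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5AA5]))
    permuted = [epochs.labels[i] for i in rng.permutation(epochs.n_trials)]
    shuffled = replace(epochs, labels=permuted)
    clf = train_class_decoder(shuffled, seed=seed)
    onset = train_onset_detector(recording, stats, seed=seed, **onset_kw)
    return OnlineDecoder(onset=onset, classifier=clf,
                         meta={"kind": "sham", "seed": int(seed)})


# ---------------------------------------------------------------------------
# Threshold calibration and online stepping
# ---------------------------------------------------------------------------

def count_detections(scores: np.ndarray, times_ms: np.ndarray,
                     threshold: float, refractory_ms: float) -> int:
    """Detections = threshold up-crossings honoring the refractory period."""
    above = np.nonzero(np.asarray(scores) > threshold)[0]
    n, last = 0, -np.inf
    for i in above:
        t = times_ms[i]
        if t - last >= refractory_ms:
            n += 1
            last = t
    return n


def calibrate_threshold(
    detector: OnsetDetector,
    rest_recording: Recording,
    stats: BaselineStats,
    target_fp_per_min: float = 2.0,
) -> OnsetDetector:
    """Reset the threshold on a movement-free recording.

    Returns a detector whose threshold is the smallest observed-score value
    giving at most ``target_fp_per_min`` detections per minute (refractory
    applied) on the calibration span.  This replaces the experimenter's
    manual pre-session adjustment with a reproducible rule.
    """
    if rest_recording.duration_ms < 30000:
        raise ValueError("rest recording must be at least 30 s")
    if target_fp_per_min < 0:
        raise ValueError("target rate must be >= 0")
    series = sliding_features(rest_recording, stats,
                              window_ms=stats.window_ms)
    smoothed = detector.smoothed_scores(series.frames)
    allowed = target_fp_per_min * rest_recording.duration_ms / 60000.0
    candidates = np.sort(np.unique(smoothed))
    if candidates.size > 512:  # quantile-spaced subset; counts only coarsen
        candidates = np.unique(np.quantile(
            smoothed, np.linspace(0.0, 1.0, 512), method="closest_observation"))
    for theta in candidates:
        if count_detections(smoothed, series.times_ms, theta,
                            detector.refractory_ms) <= allowed:
            return replace(detector, threshold=float(theta))
    # unreachable with a finite span (max score yields zero detections)
    raise RuntimeError(
        f"target {target_fp_per_min}/min unattainable; max achievable "
        f"{count_detections(smoothed, series.times_ms, smoothed.max(), detector.refractory_ms)}"
    )


@dataclass
class DecoderState:
    """Mutable per-session state of the streaming decoder."""
    recent_raw: list
    last_command_ms: float
    last_clock_ms: float

    @classmethod
    def fresh(cls) -> "DecoderState":
        return cls(recent_raw=[], last_command_ms=-np.inf, last_clock_ms=-np.inf)


def decode_step(decoder: OnlineDecoder, state: DecoderState,
                frame: np.ndarray, clock_ms: float):
    """Advance the decoder by one frame; return a posture command or None.

    Updates the smoother with the frame's raw onset score; when the smoothed
    score exceeds the threshold outside the refractory window, emits the
    class decoder's label for this frame and restarts the refractory clock.
    """
    if clock_ms < state.last_clock_ms:
        raise ValueError("clock must be non-decreasing across calls")
    state.last_clock_ms = clock_ms
    frame = np.asarray(frame, float)
    if frame.shape != (decoder.n_channels,):
        raise ValueError("frame channel count mismatch")
    raw = float(decoder.onset.scorer.score_frames(frame[None, :])[0])
    state.recent_raw.append(raw)
    k = decoder.onset.smoother.n_lags
    if len(state.recent_raw) > k:
        del state.recent_raw[:-k]
    smoothed = decoder.onset.smoother.smooth_one(state.recent_raw)
    if (smoothed > decoder.onset.threshold
            and clock_ms - state.last_command_ms >= decoder.onset.refractory_ms):
        state.last_command_ms = clock_ms
        return str(decoder.classifier.predict(frame[None, :])[0]), smoothed
    return None, smoothed


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def decoder_to_json(decoder: OnlineDecoder, path=None) -> str:
    clf, onset = decoder.classifier, decoder.onset
    doc = {
        "classifier": {
            "coef": clf.svc_.coef_.tolist(),
            "intercept": clf.svc_.intercept_.tolist(),
            "classes": [str(c) for c in clf.classes_],
            "offset_ms": clf.offset_ms_,
            "offset_index": clf.offset_index_,
            "C": clf.C_,
            "cv_accuracy": clf.cv_accuracy_,
            "cv_accuracy_per_offset": clf.cv_accuracy_per_offset_.tolist(),
            "n_channels": clf.n_channels_,
            "params": {"cv_folds": clf.cv_folds, "C_grid": list(clf.C_grid),
                       "random_state": clf.random_state,
                       "scan_repeats": clf.scan_repeats,
                       "scan_C_grid": (list(clf.scan_C_grid)
                                       if clf.scan_C_grid else None)},
        },
        "onset": {
            "coef": onset.scorer.svc_.coef_.tolist(),
            "intercept": onset.scorer.svc_.intercept_.tolist(),
            "C": onset.scorer.C_,
            "smoother_weights": onset.smoother.weights_.tolist(),
            "smoother_intercept": onset.smoother.intercept_,
            "n_lags": onset.smoother.n_lags,
            "alpha": onset.smoother.alpha,
            "threshold": onset.threshold,
            "refractory_ms": onset.refractory_ms,
        },
        "step_ms": decoder.step_ms,
        "meta": decoder.meta or {},
    }
    text = json.dumps(doc, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def decoder_from_json(source) -> OnlineDecoder:
    if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")):
        doc = json.loads(Path(source).read_text())
    else:
        doc = json.loads(source)
    c = doc["classifier"]
    clf = PeakWindowClassifier(**c["params"])
    clf.svc_ = _LinearSVM(C=c["C"])
    clf.svc_.coef_ = np.asarray(c["coef"])
    clf.svc_.intercept_ = np.asarray(c["intercept"])
    clf.svc_.classes_ = np.asarray(c["classes"], dtype=object)
    clf.classes_ = clf.svc_.classes_
    clf.offset_ms_ = c["offset_ms"]
    clf.offset_index_ = c["offset_index"]
    clf.C_ = c["C"]
    clf.cv_accuracy_ = c["cv_accuracy"]
    clf.cv_accuracy_per_offset_ = np.asarray(c["cv_accuracy_per_offset"])
    clf.n_channels_ = c["n_channels"]

    o = doc["onset"]
    scorer = MoveRestScorer()
    scorer.svc_ = _LinearSVM(C=o["C"])
    scorer.svc_.coef_ = np.asarray(o["coef"])
    scorer.svc_.intercept_ = np.asarray(o["intercept"])
    scorer.svc_.classes_ = np.asarray([0, 1])
    scorer.C_ = o["C"]
    scorer.n_channels_ = clf.n_channels_
    smoother = CausalScoreSmoother(n_lags=o["n_lags"], alpha=o["alpha"])
    smoother.weights_ = np.asarray(o["smoother_weights"])
    smoother.intercept_ = o["smoother_intercept"]
    onset = OnsetDetector(scorer=scorer, smoother=smoother,
                          threshold=o["threshold"],
                          refractory_ms=o["refractory_ms"])
    return OnlineDecoder(onset=onset, classifier=clf,
                         step_ms=doc["step_ms"], meta=doc["meta"])
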