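"""Randomized crossover experiment: pre-offline -> training -> post-offline.

Each virtual subject runs two arms (real and sham decoder) in randomized,
counterbalanced order.  An arm is: simulate the cued offline task, build
features, train the decoder (real or sham), calibrate its onset threshold on
fresh rest signal, run the 10-min closed-loop session with feedback, then
repeat the offline task with the (possibly adapted) subject.  The crossover
report aggregates nested-CV accuracies and first/last-minute correct rates
into the paired and between-arm tests.

Every source of randomness derives from one master seed via a counter-based
scheme (see :func:`stage_seed`); the report manifest records the scheme and
the configuration hash, so any number in the report can be regenerated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .decoder import (OnlineDecoder, calibrate_threshold, decoder_to_json,
                      make_real_decoder, make_sham_decoder)
from .evaluation import (BONFERRONI_ALPHA, CVReport, correct_rate,
                         improvement_contrast, nested_cv_accuracy,
                         paired_comparison)
from .features import epoch_features, fit_baseline_stats, sliding_features
from .session import SessionLog, run_training_session, save_session_log
from .simulate import simulate_offline_task, simulate_rest
from .subject import SubjectModel, make_offline_schedule, make_subject

__all__ = ["ExperimentConfig", "ArmRecord", "run_arm", "run_crossover",
           "stage_seed", "SEED_STAGES"]

#: Stage identifiers of the counter-based seed-splitting scheme.  The seed of
#: stage ``name`` for subject ``i``, arm ``a`` is drawn from
#: ``SeedSequence([master_seed, SEED_STAGES[name], i, a])``.
SEED_STAGES = {
    "subject": 1, "arm_order": 2, "pre_schedule": 3, "pre_task": 4,
    "decoder": 5, "rest": 6, "session": 7, "post_schedule": 8,
    "post_task": 9, "cv_pre": 10, "cv_post": 11,
}


def stage_seed(master_seed: int, stage: str, subject_idx: int = 0,
               arm_idx: int = 0) -> int:
    ss = np.random.SeedSequence(
        [int(master_seed), SEED_STAGES[stage], int(subject_idx), int(arm_idx)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce a crossover run."""

    cohort_size: int = 8
    master_seed: int = 0
    subject_params: dict = field(default_factory=dict)  # SubjectModel kwargs
    sampling_rate: float = 250.0
    cues_per_class: int = 40
    baseline_duration_s: float = 50.0
    session_duration_s: float = 600.0
    movement_rate_per_min: float = 5.0
    target_fp_per_min: float = 2.0
    calibration_rest_s: float = 300.0
    refractory_ms: float = 1000.0
    match_window_ms: float = 1000.0
    outer_folds: int = 10
    inner_folds: int = 10
    feedback: bool = True
    washout_reset: bool = False
    washout_decay: float = 0.5
    dropout: dict = field(default_factory=dict)  # {"real": [idx..], "sham": [..]}

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ExperimentConfig":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            source = Path(source).read_text()
        return cls(**yaml.safe_load(source))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ArmRecord:
    decoder_kind: str
    decoder: OnlineDecoder
    session: SessionLog
    pre_cv: CVReport
    post_cv: CVReport
    first_min_rate: float | None
    last_min_rate: float | None
    s_before: float
    s_after: float
    subject_after: SubjectModel


def run_arm(config: ExperimentConfig, subject: SubjectModel,
            decoder_kind: str, subject_idx: int = 0,
            arm_idx: int = 0) -> ArmRecord:
    """Execute one experiment arm end to end; returns all artifacts."""
    if decoder_kind not in ("real", "sham"):
        raise ValueError(f"unknown decoder kind {decoder_kind!r}")
    c = config
    seed = lambda stage: stage_seed(c.master_seed, stage, subject_idx, arm_idx)
    try:
        # ---- pre-BMI offline task ------------------------------------
        schedule = make_offline_schedule(
            c.cues_per_class, seed("pre_schedule"),
            baseline_duration_s=c.baseline_duration_s)
        pre_rec = simulate_offline_task(subject, schedule,
                                        sampling_rate=c.sampling_rate,
                                        seed=seed("pre_task"))
        stats = fit_baseline_stats(pre_rec, c.baseline_duration_s)
        pre_series = sliding_features(pre_rec, stats)
        pre_epochs = epoch_features(pre_series, schedule.cue_times_ms,
                                    schedule.labels)

        # ---- decoder training + threshold calibration ----------------
        maker = make_real_decoder if decoder_kind == "real" else make_sham_decoder
        decoder = maker(pre_epochs, pre_rec, stats, seed=seed("decoder"),
                        refractory_ms=c.refractory_ms)
        rest = simulate_rest(subject, c.calibration_rest_s,
                             sampling_rate=c.sampling_rate, seed=seed("rest"))
        onset = calibrate_threshold(decoder.onset, rest, stats,
                                    c.target_fp_per_min)
        decoder = dataclasses.replace(decoder, onset=onset)

        # ---- closed-loop training session ----------------------------
        s_before = subject.s
        log, subject = run_training_session(
            subject, decoder, stats,
            duration_s=c.session_duration_s, feedback=c.feedback,
            movement_rate_per_min=c.movement_rate_per_min,
            seed=seed("session"), sampling_rate=c.sampling_rate,
            match_window_ms=c.match_window_ms)

        # ---- post-BMI offline task -----------------------------------
        post_schedule = make_offline_schedule(
            c.cues_per_class, seed("post_schedule"),
            baseline_duration_s=c.baseline_duration_s)
        post_rec = simulate_offline_task(subject, post_schedule,
                                         sampling_rate=c.sampling_rate,
                                         seed=seed("post_task"))
        post_stats = fit_baseline_stats(post_rec, c.baseline_duration_s)
        post_epochs = epoch_features(sliding_features(post_rec, post_stats),
                                     post_schedule.cue_times_ms,
                                     post_schedule.labels)

        # ---- scoring --------------------------------------------------
        pre_cv = nested_cv_accuracy(pre_epochs, c.outer_folds, c.inner_folds,
                                    seed=seed("cv_pre"))
        post_cv = nested_cv_accuracy(post_epochs, c.outer_folds, c.inner_folds,
                                     seed=seed("cv_post"))
        first = correct_rate(log, 0.0, 60.0, c.match_window_ms)
        last = correct_rate(log, c.session_duration_s - 60.0,
                            c.session_duration_s, c.match_window_ms)
    except Exception as exc:  # annotate failures with stage context
        raise RuntimeError(
            f"arm failed (kind={decoder_kind}, subject={subject_idx}, "
            f"arm={arm_idx}, master_seed={c.master_seed}): {exc}") from exc

    return ArmRecord(decoder_kind=decoder_kind, decoder=decoder, session=log,
                     pre_cv=pre_cv, post_cv=post_cv,
                     first_min_rate=first.rate, last_min_rate=last.rate,
                     s_before=s_before, s_after=subject.s,
                     subject_after=subject)


def _washout(config: ExperimentConfig, subject: SubjectModel,
             baseline_s: float) -> SubjectModel:
    if config.washout_reset:
        return dataclasses.replace(subject, s=baseline_s)
    decayed = baseline_s + (1.0 - config.washout_decay) * (subject.s - baseline_s)
    return dataclasses.replace(subject, s=decayed)


def run_crossover(config: ExperimentConfig, outdir=None) -> dict:
    """Run the full crossover and return the aggregated report (JSON-able).

    Arm order is counterbalanced: half the cohort (plus/minus one) starts
    with the real decoder.  Between arms the subject's separability decays
    toward its baseline (washout), or resets if configured.
    """
    c = config
    if c.cohort_size < 2:
        raise ValueError("cohort too small for the paired tests")
    order_rng = np.random.default_rng(
        np.random.SeedSequence([int(c.master_seed), SEED_STAGES["arm_order"]]))
    n_real_first = (c.cohort_size + 1) // 2
    orders = (["real", "sham"],) * n_real_first + \
             (["sham", "real"],) * (c.cohort_size - n_real_first)
    orders = [orders[i] for i in order_rng.permutation(c.cohort_size)]

    per_subject = []
    arms = {"real": {}, "sham": {}}
    for i in range(c.cohort_size):
        subject = make_subject(stage_seed(c.master_seed, "subject", i),
                               **c.subject_params)
        baseline_s = subject.s
        record = {"subject": i, "order": orders[i]}
        for arm_idx, kind in enumerate(orders[i]):
            if i in c.dropout.get(kind, []):
                record[kind] = None
                continue
            arm = run_arm(c, subject, kind, subject_idx=i, arm_idx=arm_idx)
            subject = _washout(c, arm.subject_after, baseline_s)
            arms[kind][i] = arm
            record[kind] = {
                "pre_accuracy_pct": arm.pre_cv.mean_accuracy_pct,
                "post_accuracy_pct": arm.post_cv.mean_accuracy_pct,
                "first_min_rate": arm.first_min_rate,
                "last_min_rate": arm.last_min_rate,
                "s_before": arm.s_before,
                "s_after": arm.s_after,
                "n_commands": len(arm.session.robot.commands),
                "n_movements": int(len(arm.session.movements)),
            }
            if outdir is not None:
                arm_dir = Path(outdir) / f"subject{i:02d}" / kind
                arm_dir.mkdir(parents=True, exist_ok=True)
                decoder_to_json(arm.decoder, arm_dir / "decoder.json")
                save_session_log(arm.session, arm_dir / "session")
        per_subject.append(record)

    report = {"config_hash": c.config_hash(), "master_seed": c.master_seed,
              "seed_scheme": ("SeedSequence([master_seed, stage_id, "
                              "subject_idx, arm_idx]) % 2**31; stage ids: "
                              + json.dumps(SEED_STAGES, sort_keys=True)),
              "alpha": BONFERRONI_ALPHA,
              "per_subject": per_subject, "arm_tests": {}}
    improvements = {}
    rate_improvements = {}
    for kind in ("real", "sham"):
        recs = arms[kind]
        pre = [recs[i].pre_cv.mean_accuracy_pct for i in sorted(recs)]
        post = [recs[i].post_cv.mean_accuracy_pct for i in sorted(recs)]
        entry = {"n": len(recs),
                 "pre_accuracy_pct_mean": float(np.mean(pre)) if pre else None,
                 "post_accuracy_pct_mean": float(np.mean(post)) if post else None}
        if len(recs) >= 2:
            res = paired_comparison(pre, post, alpha=BONFERRONI_ALPHA)
            entry["accuracy_paired_t"] = dataclasses.asdict(res)
            firsts = np.array([np.nan if recs[i].first_min_rate is None
                               else recs[i].first_min_rate for i in sorted(recs)])
            lasts = np.array([np.nan if recs[i].last_min_rate is None
                              else recs[i].last_min_rate for i in sorted(recs)])
            ok = np.isfinite(firsts) & np.isfinite(lasts)
            entry["first_min_rate_mean"] = float(np.nanmean(firsts)) if ok.any() else None
            entry["last_min_rate_mean"] = float(np.nanmean(lasts)) if ok.any() else None
            if ok.sum() >= 2:
                entry["correct_rate_paired_t"] = dataclasses.asdict(
                    paired_comparison(firsts[ok], lasts[ok], alpha=0.05))
                rate_improvements[kind] = (lasts[ok] - firsts[ok]).tolist()
        else:
            entry["accuracy_paired_t"] = None
            entry["note"] = "cohort too small for the paired test in this arm"
        improvements[kind] = (np.asarray(post) - np.asarray(pre)).tolist()
        report["arm_tests"][kind] = entry

    if len(improvements["real"]) >= 2 and len(improvements["sham"]) >= 2:
        contrast = improvement_contrast(improvements["real"],
                                        improvements["sham"])
        report["accuracy_improvement_contrast"] = dataclasses.asdict(contrast)
    if (len(rate_improvements.get("real", [])) >= 2
            and len(rate_improvements.get("sham", [])) >= 2):
        report["correct_rate_improvement_contrast"] = dataclasses.asdict(
            improvement_contrast(rate_improvements["real"],
                                 rate_improvements["sham"]))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        c.to_yaml(outdir / "config.yaml")
        (outdir / "report.json").write_text(json.dumps(report, sort_keys=True,
                                                       indent=1))
    return report
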