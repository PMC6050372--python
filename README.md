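# megbmi

Closed-loop MEG brain–machine-interface simulation and decoding analysis.

Neurofeedback training with a BMI-controlled robotic hand is thought to
induce plastic changes in the cortical representation of movement: a
decoder turns multichannel MEG signals into grasp/open commands in real
time, the participant watches the robotic hand, and training with an
*informative* (real) decoder should improve the decodability of their
brain activity more than training with a label-shuffled (sham) decoder.
`megbmi` implements that whole experimental design — signal model, online
decoder, closed-loop session, and the statistics of a sham-controlled
randomized crossover — as a tested, fully seeded simulation-plus-analysis
pipeline. It is intended for methodologists who want to study the design's
statistical behavior (chance levels, detector calibration, type-I control,
power) and as reusable analysis machinery for real event logs and feature
tables supplied in the package's CSV/JSON formats.

## The model in brief

* **Signal**: 84 channels of colored noise (white + 1/f with a 0.5-Hz
  knee), plus a raised-cosine evoked transient per hand movement with
  class pattern `g·u ± (s/2)·c·v`; the separability `s` scales the
  grasp-vs-open pattern distance.
* **Features**: causal 500-ms window means every 100 ms, z-scored against
  the first 50 s of the offline task; epochs from −2,000 to +1,000 ms
  around each cue.
* **Online decoder**: a movement-onset detector (linear move-vs-rest
  scorer + causal smoother + calibrated threshold with 1-s refractory)
  and a linear-SVM grasp/open classifier trained at the offset of peak
  cross-validated accuracy.
* **Closed loop**: self-paced movements; the robot enters the decoded
  posture; a movement followed within 1 s by the matching posture is
  `correct`, and correct feedback multiplies `s` by `1 + η` (capped) —
  the stand-in for training-induced plasticity. A sham decoder (trained
  on permuted movement-type labels) rewards at chance.
* **Evaluation**: correct rate in the first/last minute of training;
  nested 10-fold CV accuracy of the 11-window concatenated feature
  (inner CV selects the regularization); per-channel one-way ANOVA F
  between classes; paired t-tests per arm at Bonferroni-corrected
  α = 0.025 and an unpaired t for the real-vs-sham improvement contrast.

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```python
import dataclasses
import megbmi as m

subject = m.make_subject(seed=7)                      # 84 channels, s = 1
schedule = m.make_offline_schedule(cues_per_class=40, seed=7)
recording = m.simulate_offline_task(subject, schedule, seed=7)
stats = m.fit_baseline_stats(recording)
series = m.sliding_features(recording, stats)
epochs = m.epoch_features(series, schedule.cue_times_ms, schedule.labels)

report = m.nested_cv_accuracy(epochs, seed=7)
print(f"nested-CV accuracy: {report.mean_accuracy_pct:.1f}% "
      f"({epochs.n_trials} trials, {report.feature_dim} features)")

decoder = m.make_real_decoder(epochs, recording, stats, seed=7)
print(f"class decoder: peak offset {decoder.classifier.offset_ms_:+d} ms, "
      f"training CV accuracy {decoder.classifier.cv_accuracy_:.2f}")

rest = m.simulate_rest(subject, 300.0, seed=8)
onset = m.calibrate_threshold(decoder.onset, rest, stats,
                              target_fp_per_min=2.0)
decoder = dataclasses.replace(decoder, onset=onset)

log, trained = m.run_training_session(subject, decoder, stats,
                                      duration_s=600.0, seed=9)
print(f"session: {len(log.movements)} movements, "
      f"{len(log.robot.commands)} robot commands, "
      f"separability {subject.s:.2f} -> {trained.s:.2f}")
```

prints

```
nested-CV accuracy: 80.0% (80 trials, 924 features)
class decoder: peak offset +600 ms, training CV accuracy 0.90
session: 44 movements, 28 robot commands, separability 1.00 -> 1.21
```

Reading: before training, the 80-trial offline task decodes at 80%
(chance 50%); the class decoder peaks 600 ms after the cue — the first
frame whose window covers the whole evoked response, which starts 100 ms
after the cue and lasts 400 ms. During the 10-minute closed-loop session
the onset detector (calibrated to ≤ 2 false positives/min) catches a
minority of the 44 self-paced movements; each correctly decoded one
multiplies the subject's separability by 1.1, taking `s` from 1.0 to
1.21 — the post-training offline task would now decode correspondingly
better.

The full crossover (8 virtual subjects, real and sham arms in randomized
order) runs from one master seed:

```bash
megbmi crossover --seed 42 --out results/xover
```

or programmatically via `megbmi.run_crossover(ExperimentConfig(...))`.
Subcommands `simulate-offline`, `train-decoder`, `run-session`, `score`
and `nested-cv` expose the individual stages.

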