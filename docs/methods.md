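# Methods

`megbmi` simulates and analyses a sham-controlled crossover experiment in
which a participant controls a two-posture robotic hand through a
real-time decoder of multichannel MEG-like signals. Everything is built
around one question: does closed-loop training with an *informative*
decoder improve the decodability of the participant's movement-related
brain activity more than training with an uninformative (sham) decoder?
Because no recordings from such experiments are openly deposited, the
package ships a generative "virtual subject" whose decodability can change
under feedback; the analysis stack is written exactly as it would be for
real recordings and accepts externally supplied recordings in the package's
CSV/JSON formats.

## The virtual subject

A subject is a channels-space generative model (`SubjectModel`):

* **Background noise.** Per channel, a mixture of white and 1/f-power
  ("pink") Gaussian noise with total variance `noise_sd**2`
  (`pink_fraction` = 0.5 by default). The pink spectrum is flat below a
  0.5-Hz knee, mirroring the high-pass behavior of a real acquisition
  chain. The knee matters: without it, slow drift is shared by the four
  same-class cues of an instruction block, and a cross-validated classifier
  "decodes" block identity — hence movement class — even when the two
  movements are generated identically. With the knee, a zero-separability
  subject decodes at exactly chance (measured null mean 50.0%, SD 6.6
  percentage points over 60 replicates).
* **Evoked responses.** Each movement adds `pattern x envelope`, where the
  envelope is a raised cosine of 400 ms and the class pattern is
  `evoked_gain * u ± (s/2) * class_gain * v`, with `u` (movement component)
  and `v` (class-difference direction, orthogonal to `u`) unit-norm channel
  vectors fixed per subject. The class-pattern distance is `s * class_gain`
  — linear in the separability `s`, zero at `s = 0`.
* **Adaptation.** After each self-paced movement in a closed-loop session
  the subject receives `correct` or `incorrect` feedback (did the robot
  enter the matching posture within 1 s?). On `correct`,
  `s <- min(s * (1 + eta), s_max)` with `eta = 0.1` and `s_max = 3`;
  otherwise `s` is unchanged, so `s` is non-decreasing. This multiplicative
  reinforcement rule is an explicit stand-in for training-induced cortical
  change — nothing in the analysis depends on its specific form, and it is
  isolated in one function (`adaptation_update`).

Default amplitudes (`evoked_gain = 1.35`, `class_gain = 2.5`, in units of
the per-channel noise SD) place the untrained subject where the study
design needs it: offline decoding well above chance but far from ceiling,
and an onset-detector hit rate, at the calibrated 2 false-positives/min
threshold, of roughly 10–20% of self-paced movements. The hit rate is the
critical dial: each detected-and-correct movement multiplies `s` by 1.1,
so a detector that caught most movements would saturate `s` in *both* arms
(the sham decoder's posture matches the movement at chance, i.e. half as
often), erasing the real-vs-sham contrast; a detector that caught almost
none would leave both arms untrained. For the same reason the default
self-paced movement rate is 5 events/min — at, say, 12 events/min the
reward stream would saturate `s` through the sham arm as well.

## Feature pipeline

Sensor signals are reduced to causal 500-ms window means per channel,
emitted every 100 ms; a frame's timestamp is its window *end*, so the
batch (offline) and streaming (online) computations are the same
arithmetic and agree bit-exactly. Frames are z-scored per channel against
the mean and SD estimated from the initial 50 s of the offline task.
Baseline statistics are computed on the window means themselves (not raw
samples) so baseline frames have unit scale at the feature level; a
`mode="sample"` switch provides the raw-sample alternative. Epochs cover
−2,000 to +1,000 ms around each execution cue at 100-ms spacing
(31 offsets); trials whose grid does not fit inside the recording are
dropped with a warning.

## The online decoder

* **Class decoder** (`PeakWindowClassifier`): a linear SVM (squared hinge,
  L2, balanced class weights) on one frame's channel vector. Training
  scans all 31 epoch offsets, estimates stratified 10-fold CV accuracy per
  offset, and refits at the peak (ties break toward the earliest offset;
  regularization ties toward the strongest penalty). Because an arg-max
  over 31 noisy estimates is only as reliable as the estimates, the scan
  averages over three independent fold splits, ranks offsets with a coarse
  C grid, and re-selects C on the full grid at the winning offset.
* **Onset detector** (`OnsetDetector`): a linear move-vs-rest scorer on
  single frames, followed by a causal smoother. Positives are frames whose
  windows cover at least ~80% of the evoked response; frames on the
  response's leading edge stay in a guard zone, so the detector learns to
  fire at the peak — where the class decoder is informative — rather than
  at the first hint of movement. The fitted scorer is also orthogonalized
  against the grasp-vs-open mean-difference axis (computed from the true
  training labels, hence identical in the real and sham pipelines):
  without this, frames selected for a high onset score carry noise aligned
  with the scorer's chance overlap with the class axis, biasing the class
  decision at exactly the moments it is used. The smoother is a ridge
  regression (the posterior mean of a linear-kernel GP) from the last
  5 raw scores to the 0/1 movement indicator. A threshold with a 1,000-ms
  refractory period turns the smoothed score into discrete detections.
* **Threshold calibration** (`calibrate_threshold`): on a fresh 300-s
  movement-free recording, the threshold is reset to the smallest observed
  score value giving at most 2 detections/min (refractory applied). This
  replaces the experimenter's manual pre-session adjustment with a
  reproducible rule; 300 s (about 10 target events) keeps the calibrated
  threshold stable across subjects, which in turn keeps per-subject reward
  rates comparable.
* **Sham decoder**: the identical pipeline with movement-*type* labels
  permuted before class-decoder training. Only the type is randomized —
  the onset stage is trained on the true movement timing, so the sham
  robot reacts to movements but its grasp/open choice is uninformative.

All linear trainers select their regularization strength from the
logarithmic grid 10^-3..10^3 by internal CV. The SVM problems are solved
by the same liblinear routine scikit-learn's `LinearSVC` uses, called
through a thin wrapper (`_LinearSVM`) because the pipeline makes thousands
of small fits and the per-call validation overhead of the high-level
estimator dominates otherwise (verified to reproduce `LinearSVC`
coefficients to ~1e-5).

## Closed-loop session

`run_training_session` streams the subject through the decoder at 100-ms
steps for 10 min. Movement times (thinned Poisson, minimum spacing 2 s)
and classes are the subject's volition and are drawn upfront; evoked
*amplitudes* are not — each transient is injected into the signal buffer
only when the streaming clock passes it, using the subject's separability
at that moment, so the generator never looks ahead and the adaptation is
honestly causal. Robot posture persists between commands. The online
correct/incorrect judgment reuses the offline scorer's greedy matching
rule verbatim (earliest unconsumed same-posture command within 1 s; one
command satisfies at most one movement). `replay_session` re-decodes the
logged recording and must reproduce the command sequence bit-exactly.

## Evaluation

* **Correct rate**: correct movements / total movements in a segment,
  scored over the first and last minute of training.
* **Nested CV accuracy**: features concatenate the 11 windows from −500
  to +500 ms around the cue (924 dimensions at 84 channels). Outer
  stratified 10-fold CV estimates accuracy; an inner 10-fold CV on the
  training folds alone selects the SVM's regularization. Folds are built
  by an explicit rule (per-class shuffle, round-robin deal) so the fold
  logic itself has a brute-force oracle in the tests. At n = 80 trials
  this estimator is honest in the mean but disperses slightly wider than
  the 80-trial binomial SD (~6.6 vs 5.5 percentage points under the null)
  because fold models share training trials — scikit-learn's own nested CV
  shows the same width on iid data.
* **Discriminability map**: per-channel one-way ANOVA F between classes of
  the (0, 500]-ms window mean (the sensor-space analogue of a vertex-wise
  F map; source modeling is out of scope). With two groups F equals the
  squared pooled-variance t, checked numerically.
* **Crossover statistics**: within each arm a two-sided paired t-test on
  post-vs-pre accuracies at alpha = 0.025 (Bonferroni over the two arms);
  between arms an unpaired Student's t on per-subject improvements.
  Degenerate cases (zero-variance differences) are reported explicitly;
  undefined correct rates (no movements in a segment) propagate as missing
  with n adjusted.

## Crossover orchestration

`run_crossover` gives each virtual subject both arms in randomized,
counterbalanced order (half the cohort real-first, ±1). An arm is:
pre-offline task (40 cues/class, 5.5-s cue spacing, randomized block
order) → decoder training and calibration → 10-min feedback session →
post-offline task → nested-CV scoring. Between arms the washout decays the
subject's separability halfway back toward baseline (`washout_decay`,
with a full-reset switch): training-induced change is not assumed to
vanish completely even after weeks, and the partial carryover contributes
realistic order-dependent heterogeneity to the paired tests. Every stage seed derives from the master seed via
`SeedSequence([master, stage_id, subject, arm])`; the report records the
scheme and a configuration hash, and two runs from one master seed produce
byte-identical reports.

Per-arm dropout is a config option (`dropout`), mirroring designs where
not every participant completes both arms; dropped arms reduce n for that
arm's paired test and are excluded from the contrast.

## Numerical and design choices

* Sampling rate is configurable; 250 Hz is the working default (all
  stages are rate-agnostic; 1,000 Hz reproduces the nominal acquisition
  rate at 4x the cost). Problem sizes in the test suite are chosen at
  desk scale: unit tests use 8–16 channels and short tasks; the
  end-to-end checks run the full 84-channel, 40-cue, 10-minute geometry.
* Reaction latency to a cue is fixed at 100 ms (configurable); self-paced
  movements have no added latency.
* Windows and steps must be integer multiples of the sample period;
  violations raise rather than round.
* Trials overlapping the recording edges are dropped, not padded.
* Degenerate inputs (zero-variance baseline channels, single-class
  epochs, empty rest spans, infeasible movement rates) raise informative
  errors at the boundary where they are detectable.

## What the generator does and does not emulate

It emulates: the channel count and sampling geometry, colored background
noise, smooth class-specific evoked responses, cue-locked and self-paced
task structure, reward-contingent growth of class separability, and the
real/sham asymmetry of that growth. It does not emulate: sensor geometry
or biophysical forward models, artifacts (blinks, cardiac, movement),
non-stationary noise, subject fatigue or strategy changes, or any
particular cortical localization — so passing tests demonstrate that the
*analysis machinery* behaves correctly and that the *design logic*
(chance levels, calibration, type-I control, directional recovery) holds
under a plausible signal model, not that any specific human cohort would
show the same numbers. The separability parameter is an operational proxy,
not a biophysical quantity; no synthetic parameter set can claim fidelity
to the original cohort's evoked responses, which were never quantified
publicly.

## Known limitations

* The adaptation rule rewards any correct match, so separability also
  drifts upward slowly under the sham decoder (at roughly half the reward
  rate); the real-vs-sham contrast is therefore a matter of degree, as it
  is in the real experiment.
* Nested-CV accuracy at 80 trials carries ~6-7 percentage points of
  measurement noise per subject; arm-level tests at n = 8 inherit that
  noise, and single simulated crossovers occasionally miss significance
  in the real arm exactly as underpowered real experiments do.
* The onset detector's hit rate is not an explicit parameter; it emerges
  from the evoked gain, the noise model and the calibration rule.
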