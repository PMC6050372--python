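"""Scoring and statistics: correct rate, nested CV, ANOVA map, t-tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import megbmi as m
from megbmi.cv import stratified_folds
from megbmi.decoder import _fit_svc
from megbmi.evaluation import CV_FEATURE_OFFSETS_MS
from megbmi.recording import Recording, make_events
from megbmi.session import RobotTimeline, SessionLog
from conftest import toy_epochs


def scripted_log(movements, commands, duration_s=60.0):
    """SessionLog with scripted movement events and robot commands."""
    rows = [(int(t), "subject_movement", lab) for t, lab in movements]
    rec = Recording(sampling_rate=250.0,
                    signal=np.zeros((1, int(duration_s * 250))),
                    events=make_events(rows))
    return SessionLog(recording=rec,
                      robot=RobotTimeline(tuple(commands)),
                      score_times_ms=np.array([], dtype=np.int64),
                      smoothed_scores=np.array([]),
                      s_trajectory=[(0, 1.0)], rewards=[],
                      duration_s=duration_s, feedback=True)


def oracle_match(movements, commands, window_ms=1000.0):
    """Exhaustive re-statement of the pairing rule, written independently:
    walk movements in time order; each takes the earliest not-yet-used
    command of its own posture inside (t, t+window]."""
    used = set()
    flags = []
    for t, lab in movements:
        hit = None
        for j, (tc, posture) in enumerate(commands):
            if j in used:
                continue
            if posture == lab and t < tc <= t + window_ms:
                if hit is None or tc < commands[hit][0]:
                    hit = j
        flags.append(hit is not None)
        if hit is not None:
            used.add(hit)
    return flags


class TestCorrectRate:
    def test_scripted_example(self):
        # movements at 10/20/30 s; the 21.5-s command misses the 1-s window
        movements = [(10_000, "grasp"), (20_000, "open"), (30_000, "grasp")]
        commands = [(10_500, "grasp"), (21_500, "open"), (30_900, "grasp")]
        rep = m.correct_rate(scripted_log(movements, commands), 0.0, 60.0)
        assert (rep.n_movements, rep.n_correct) == (3, 2)
        assert rep.rate == pytest.approx(2 / 3)

    def test_opposite_postures_score_zero(self):
        movements = [(10_000, "grasp"), (20_000, "open")]
        commands = [(10_500, "open"), (20_500, "grasp")]
        rep = m.correct_rate(scripted_log(movements, commands), 0.0, 60.0)
        assert rep.rate == 0.0

    def test_all_matched_scores_one(self):
        movements = [(10_000, "grasp"), (20_000, "open")]
        commands = [(10_100, "grasp"), (20_100, "open")]
        rep = m.correct_rate(scripted_log(movements, commands), 0.0, 60.0)
        assert rep.rate == 1.0

    def test_no_movements_rate_undefined(self):
        rep = m.correct_rate(scripted_log([], []), 0.0, 60.0)
        assert rep.rate is None
        assert rep.n_movements == 0

    def test_inverted_segment_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            m.correct_rate(scripted_log([], []), 30.0, 10.0)

    def test_command_consumed_at_most_once(self):
        # one command cannot satisfy two movements
        movements = [(10_000, "grasp"), (10_400, "grasp")]
        commands = [(10_500, "grasp")]
        rep = m.correct_rate(scripted_log(movements, commands), 0.0, 60.0)
        assert rep.n_correct == 1

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**9))
    def test_matches_exhaustive_pairing_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_mov = int(rng.integers(0, 12))
        n_cmd = int(rng.integers(0, 12))
        movements = sorted(
            (int(t), ("grasp", "open")[rng.integers(2)])
            for t in rng.choice(59_000, size=n_mov, replace=False))
        commands = sorted(
            (int(t) + 1, ("grasp", "open")[rng.integers(2)])
            for t in rng.choice(59_000, size=n_cmd, replace=False))
        log = scripted_log(movements, commands)
        rep = m.correct_rate(log, 0.0, 60.0)
        assert rep.n_correct == sum(oracle_match(movements, commands))


class TestNestedCV:
    def test_perfectly_separable_scores_100(self):
        ep = toy_epochs(n_per_class=20, n_offsets=11, effect_offset=0,
                        effect=5.0, seed=1,
                        offsets_ms=CV_FEATURE_OFFSETS_MS)
        rep = m.nested_cv_accuracy(ep, seed=0)
        assert rep.mean_accuracy_pct == 100.0

    def test_feature_dimension(self):
        ep = toy_epochs(n_per_class=15, n_offsets=11, seed=2,
                        offsets_ms=CV_FEATURE_OFFSETS_MS, n_channels=84)
        rep = m.nested_cv_accuracy(ep, seed=0)
        assert rep.feature_dim == 924
        assert len(rep.fold_accuracies) == 10
        assert rep.n_per_class == {"grasp": 15, "open": 15}

    def test_missing_offsets_rejected(self):
        ep = toy_epochs(n_per_class=10, n_offsets=3, seed=3)
        with pytest.raises(KeyError):
            m.nested_cv_accuracy(ep, seed=0)

    def test_too_few_trials_rejected(self):
        ep = toy_epochs(n_per_class=4, n_offsets=11, seed=4,
                        offsets_ms=CV_FEATURE_OFFSETS_MS)
        with pytest.raises(ValueError, match="fold"):
            m.nested_cv_accuracy(ep, seed=0)

    def test_matches_independent_naive_nested_cv(self):
        # fold-for-fold equality with a from-scratch reimplementation of
        # the whole nested procedure on a small instance
        ep = toy_epochs(n_per_class=6, n_offsets=11, effect_offset=0,
                        effect=0.8, seed=5, offsets_ms=CV_FEATURE_OFFSETS_MS)
        grid = (0.01, 1.0, 100.0)
        rep = m.nested_cv_accuracy(ep, outer_folds=3, inner_folds=3, seed=7,
                                   C_grid=grid)

        X = np.concatenate([ep.data[:, ep.offset_index(o), :]
                            for o in CV_FEATURE_OFFSETS_MS], axis=1)
        y = np.asarray(ep.labels)
        rng = np.random.default_rng(np.random.SeedSequence([7, 0x0CE4]))
        outer = stratified_folds(y, 3, rng)
        expected = []
        for te in outer:
            tr = np.setdiff1d(np.arange(len(y)), te)
            inner = stratified_folds(y[tr], 3, rng)
            best_C, best_acc = None, -1.0
            for C in grid:
                accs = []
                for ite in inner:
                    itr = np.setdiff1d(np.arange(len(tr)), ite)
                    svc = _fit_svc(X[tr][itr], y[tr][itr], C)
                    accs.append((svc.predict(X[tr][ite]) == y[tr][ite]).mean())
                acc = float(np.mean(accs))
                if acc > best_acc:
                    best_C, best_acc = C, acc
            svc = _fit_svc(X[tr], y[tr], best_C)
            expected.append(float((svc.predict(X[te]) == y[te]).mean()))
        assert list(rep.fold_accuracies) == expected

    def test_test_fold_cannot_poison_hyperparameter_choice(self):
        # perturbing a held-out trial never changes the inner C choice
        ep = toy_epochs(n_per_class=10, n_offsets=11, effect_offset=0,
                        effect=0.5, seed=6, offsets_ms=CV_FEATURE_OFFSETS_MS)
        rep = m.nested_cv_accuracy(ep, outer_folds=5, inner_folds=5, seed=3)
        y = np.asarray(ep.labels)
        rng = np.random.default_rng(np.random.SeedSequence([3, 0x0CE4]))
        outer = stratified_folds(y, 5, rng)
        poisoned = ep.data.copy()
        poisoned[outer[0][0]] += 100.0  # a trial of the first test fold
        ep2 = m.EpochFeatures(data=poisoned, offsets_ms=ep.offsets_ms,
                              labels=ep.labels)
        rep2 = m.nested_cv_accuracy(ep2, outer_folds=5, inner_folds=5, seed=3)
        assert rep2.fold_C[0] == rep.fold_C[0]
        assert rep2.fold_accuracies[1:] == rep.fold_accuracies[1:]


class TestFoldLogic:
    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**9), k=st.integers(2, 5),
           n_a=st.integers(5, 20), n_b=st.integers(5, 20))
    def test_matches_round_robin_oracle(self, seed, k, n_a, n_b):
        """Fold construction equals an independently coded restatement of
        the documented rule (per-class shuffle, round-robin deal)."""
        labels = np.array(["a"] * n_a + ["b"] * n_b)
        folds = stratified_folds(labels, k, np.random.default_rng(seed))
        # oracle: replay the documented rule with its own bookkeeping
        rng = np.random.default_rng(seed)
        expected = {j: [] for j in range(k)}
        for cls in ("a", "b"):
            idx = np.nonzero(labels == cls)[0]
            shuffled = idx[rng.permutation(idx.size)]
            for j, trial in enumerate(shuffled):
                expected[j % k].append(int(trial))
        for j in range(k):
            assert sorted(expected[j]) == folds[j].tolist()
        # partition properties
        allidx = np.concatenate(folds)
        assert sorted(allidx.tolist()) == list(range(n_a + n_b))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 2


class TestDiscriminabilityMap:
    def test_hand_computed_example(self):
        # one channel, groups {1,2,3} vs {4,5,6}: F = 13.5
        data = np.array([1, 2, 3, 4, 5, 6], dtype=float)[:, None, None]
        ep = m.EpochFeatures(data=data, offsets_ms=np.array([500]),
                             labels=["grasp"] * 3 + ["open"] * 3)
        out = m.discriminability_map(ep)
        assert out["F"][0] == pytest.approx(13.5)
        assert out["group_sizes"] == {"grasp": 3, "open": 3}

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((30, 1, 6))
        labels = ["grasp"] * 15 + ["open"] * 15
        ep = m.EpochFeatures(data=data, offsets_ms=np.array([500]),
                             labels=labels)
        F = m.discriminability_map(ep)["F"]
        t = sps.ttest_ind(data[:15, 0, :], data[15:, 0, :], axis=0).statistic
        np.testing.assert_allclose(F, t ** 2, atol=1e-8)

    def test_null_mean_near_one(self):
        # E[F(1, n-2)] = (n-2)/(n-4); with many channels the mean is close
        rng = np.random.default_rng(9)
        n = 200
        data = rng.standard_normal((n, 1, 400))
        ep = m.EpochFeatures(data=data, offsets_ms=np.array([500]),
                             labels=["grasp"] * 100 + ["open"] * 100)
        F = m.discriminability_map(ep)["F"]
        assert np.mean(F) == pytest.approx((n - 2) / (n - 4), rel=0.2)

    def test_single_class_rejected(self):
        data = np.zeros((4, 1, 2))
        ep = m.EpochFeatures(data=data, offsets_ms=np.array([500]),
                             labels=["grasp"] * 4)
        with pytest.raises(ValueError):
            m.discriminability_map(ep)


class TestPairedComparison:
    def test_identical_gives_t0_p1(self):
        res = m.paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0 and not res.significant
        assert res.degenerate

    def test_hand_computed_example(self):
        # diffs (1, 1, 2): mean 4/3, sd 1/sqrt(3) -> t = 4.0, df = 2
        res = m.paired_comparison([1, 2, 3], [2, 3, 5])
        assert res.t == pytest.approx(4.0)
        assert res.df == 2

    def test_t_to_p_mapping_at_df7(self):
        # published pairing: |t| = 2.93 at df = 7 <-> two-sided p ~ 0.022
        e = np.array([-1.2, 0.3, 1.5, -0.7, 0.9, -1.1, 0.2, 0.1])
        e = (e - e.mean()) / e.std(ddof=1)
        d = 1.0 + e * (np.sqrt(8) / 2.93)   # constructed so t == 2.93
        res = m.paired_comparison(np.zeros(8), d)
        assert res.t == pytest.approx(2.93, abs=1e-9)
        assert 0.021 <= res.p <= 0.023

    def test_constant_nonzero_difference_degenerate(self):
        res = m.paired_comparison([0.0, 0.0], [1.0, 1.0])
        assert res.degenerate and res.p == 0.0 and np.isinf(res.t)

    def test_matches_scipy(self):
        rng = np.random.default_rng(10)
        pre, post = rng.standard_normal((2, 12))
        res = m.paired_comparison(pre, post, alpha=0.05)
        ref = sps.ttest_rel(post, pre)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_errors(self):
        with pytest.raises(ValueError):
            m.paired_comparison([1.0], [2.0])
        with pytest.raises(ValueError):
            m.paired_comparison([1, 2], [1, 2, 3])


class TestImprovementContrast:
    def test_textbook_two_sample(self):
        a, b = [2.0, 4.0, 6.0], [1.0, 2.0, 3.0]
        res = m.improvement_contrast(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        assert res.mean_difference == pytest.approx(2.0)

    def test_identical_values_give_t0(self):
        res = m.improvement_contrast([0.2, 0.2], [0.2, 0.2])
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_zero_variance_nonzero_difference_reported(self):
        res = m.improvement_contrast([0.2, 0.2, 0.2], [0.0, 0.0, 0.0])
        assert res.degenerate
        assert np.isinf(res.t) and res.t > 0 and res.p == 0.0

    def test_small_arm_rejected(self):
        with pytest.raises(ValueError):
            m.improvement_contrast([1.0], [1.0, 2.0])
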