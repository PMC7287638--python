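"""Metrics, exact signed-rank test, LOTO harness and ablation driver."""

import itertools

import numpy as np
import pytest
from scipy import stats

from fmgdecode.evaluate import (
    DegenerateTestError,
    DualNetSpec,
    ShallowSpec,
    accuracy,
    confusion,
    loto_folds,
    paired_nonparametric_test,
    r_squared,
    restrict_channels,
    run_experiment,
)
from fmgdecode.simulate import SimConfig, TrialRecording, simulate_dataset


class TestAccuracy:
    def test_examples(self):
        assert accuracy(np.array([0, 1, 2, 2]), np.array([0, 1, 2, 3])) == 0.75
        assert accuracy(np.zeros(5), np.zeros(5)) == 1.0
        assert accuracy(np.zeros(5), np.ones(5)) == 0.0

    def test_brute_force_agreement(self, rng):
        for _ in range(100):
            n = rng.integers(1, 50)
            a = rng.integers(0, 5, n)
            b = rng.integers(0, 5, n)
            naive = sum(1 for x, y in zip(a, b) if x == y) / n
            assert abs(accuracy(a, b) - naive) < 1e-12


class TestRSquared:
    def test_perfect_and_mean_predictors(self, rng):
        y = rng.standard_normal(20)
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, np.full(20, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        assert r_squared([0.0, 1.0, 2.0], [0.0, 0.0, 3.0]) == pytest.approx(0.0)

    def test_affine_invariance(self, rng):
        y = rng.standard_normal(30)
        yh = y + rng.normal(0, 0.3, 30)
        assert r_squared(3.0 * y + 2.0, 3.0 * yh + 2.0) == pytest.approx(
            r_squared(y, yh), rel=1e-9
        )

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(5), np.zeros(5))

    def test_brute_force_agreement(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 40))
            y = rng.standard_normal(n)
            yh = rng.standard_normal(n)
            ybar = sum(y) / n
            ss_res = sum((a - b) ** 2 for a, b in zip(y, yh))
            ss_tot = sum((a - ybar) ** 2 for a in y)
            assert abs(r_squared(y, yh) - (1 - ss_res / ss_tot)) < 1e-10


class TestConfusion:
    def test_perfect_is_diagonal(self):
        true = np.array([0, 1, 2, 2])
        mat = confusion(true, true, 3)
        assert np.array_equal(mat, np.diag([1, 1, 2]))

    def test_hand_example(self):
        mat = confusion(np.array([1, 1]), np.array([0, 1]), 3)
        expected = np.zeros((3, 3), int)
        expected[0, 1] = expected[1, 1] = 1
        assert np.array_equal(mat, expected)

    def test_conservation_and_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 60))
            t = rng.integers(0, 4, n)
            p = rng.integers(0, 4, n)
            mat = confusion(p, t, 4)
            assert mat.sum() == n
            naive = np.zeros((4, 4), int)
            for ti, pi in zip(t, p):
                naive[ti, pi] += 1
            assert np.array_equal(mat, naive)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([5]), np.array([0]), 5)


def _brute_force_signed_rank_p(d):
    """Enumerate all 2^m sign assignments of the ranked |d|."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    m = len(d)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=m)
    ]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestPairedNonparametricTest:
    def test_all_positive_distinct_differences(self, rng):
        b = rng.standard_normal(10)
        a = b + rng.uniform(0.5, 1.5, 10)
        result = paired_nonparametric_test(a, b)
        assert result.statistic == 55.0
        assert result.p_value == pytest.approx(2.0 / 1024.0, rel=1e-12)
        assert result.significant

    def test_symmetry_under_exchange(self, rng):
        a = rng.standard_normal(8)
        b = a + rng.normal(0, 1, 8)
        r1 = paired_nonparametric_test(a, b)
        r2 = paired_nonparametric_test(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    def test_all_ties_degenerate(self, rng):
        a = rng.standard_normal(6)
        with pytest.raises(DegenerateTestError):
            paired_nonparametric_test(a, a.copy())

    def test_zero_differences_dropped(self, rng):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = np.array([1.0, 1.5, 2.0, 4.0, 4.5, 5.0])  # two exact ties
        result = paired_nonparametric_test(a, b)
        assert result.n_zero_dropped == 2

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(40):
            m = int(rng.integers(5, 11))
            d = np.round(rng.standard_normal(m), 2)  # rounding forces rank ties
            if np.all(d == 0):
                continue
            result = paired_nonparametric_test(d, np.zeros(m))
            assert result.p_value == pytest.approx(
                _brute_force_signed_rank_p(d), abs=1e-12
            )

    def test_matches_scipy_exact_mode(self, rng):
        # independent library cross-check on tie-free data
        for seed in range(10):
            r = np.random.default_rng(seed)
            a = r.standard_normal(10)
            b = a + r.standard_normal(10)
            ours = paired_nonparametric_test(a, b)
            ref = stats.wilcoxon(a, b, mode="exact", zero_method="wilcox")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestLotoFolds:
    def _trials(self, n, subject=0):
        return [
            TrialRecording(subject, t, np.zeros((10, 2)), np.zeros(10, int),
                           np.arange(10.0), 40.0)
            for t in range(n)
        ]

    def test_ten_trials_ten_folds(self):
        folds = loto_folds(self._trials(10))
        assert len(folds) == 10
        assert all(len(train) == 9 for train, _ in folds)

    def test_partition_property(self):
        folds = loto_folds(self._trials(5))
        test_ids = [test.trial_id for _, test in folds]
        assert sorted(test_ids) == list(range(5))
        for train, test in folds:
            assert test.trial_id not in {t.trial_id for t in train}

    def test_two_trials_minimum(self):
        folds = loto_folds(self._trials(2))
        assert len(folds) == 2
        assert all(len(train) == 1 for train, _ in folds)

    def test_duplicate_ids_rejected(self):
        trials = self._trials(3)
        trials[2] = TrialRecording(0, 0, np.zeros((10, 2)), np.zeros(10, int),
                                   np.arange(10.0), 40.0)
        with pytest.raises(ValueError):
            loto_folds(trials)


@pytest.fixture(scope="module")
def micro_trials():
    """2 subjects x 2 trials, short segments: fast harness-level fixture."""
    cfg = SimConfig(n_subjects=2, n_trials_per_subject=2, seconds_per_finger=1.5,
                    noise_sd=0.02, drift_sd=0.0, seed=21)
    return simulate_dataset(cfg)


class TestRunExperiment:
    def test_bookkeeping_and_determinism(self, micro_trials):
        spec = ShallowSpec(family="rf", config=__import__("fmgdecode").ShallowConfig(
            rf_cls_trees=10, rf_reg_trees=10))
        results, summary = run_experiment(micro_trials, spec, root_seed=5)
        assert summary["n_subjects"] == 2
        assert summary["n_folds"] == 4
        _, summary2 = run_experiment(micro_trials, spec, root_seed=5)
        assert summary == summary2

    def test_subject_order_invariance(self, micro_trials):
        spec = ShallowSpec(family="rf", config=__import__("fmgdecode").ShallowConfig(
            rf_cls_trees=10, rf_reg_trees=10))
        _, s1 = run_experiment(micro_trials, spec, root_seed=5)
        _, s2 = run_experiment(list(reversed(micro_trials)), spec, root_seed=5)
        assert s1["mean_accuracy"] == pytest.approx(s2["mean_accuracy"])

    def test_unbalanced_cohort_rejected(self, micro_trials):
        spec = ShallowSpec(family="rf")
        with pytest.raises(ValueError):
            run_experiment(micro_trials[:-1], spec)

    def test_confusion_rows_sum_to_test_counts(self, micro_trials):
        spec = ShallowSpec(family="rf", config=__import__("fmgdecode").ShallowConfig(
            rf_cls_trees=10, rf_reg_trees=10))
        results, _ = run_experiment(micro_trials, spec, root_seed=5)
        for r in results:
            for f in r.folds:
                assert f.confusion.sum() == f.n_test
                trace = np.trace(f.confusion)
                assert f.accuracy == pytest.approx(trace / f.n_test)


class TestStrictAblation:
    def test_per_fold_importance_mode_runs_and_is_leakage_safe(self, micro_trials):
        from fmgdecode import ShallowConfig
        from fmgdecode.evaluate import sensor_ablation_strict

        spec = DualNetSpec(
            architecture="cnn_noaug",
            model_kwargs=tuple(sorted({"epochs": 1}.items())),
        )
        table = sensor_ablation_strict(
            micro_trials, [2], spec=spec,
            shallow_config=ShallowConfig(rf_cls_trees=5, rf_reg_trees=5),
            root_seed=0,
        )
        assert list(table["k"]) == [2]
        assert 0.0 <= table["mean_accuracy"][0] <= 1.0


class TestRestrictChannels:
    def test_selects_and_orders_columns(self, micro_trials):
        sub = restrict_channels(micro_trials[:1], (3, 1))
        assert sub[0].pressures.shape[1] == 2
        assert np.array_equal(sub[0].pressures[:, 0], micro_trials[0].pressures[:, 2])
        assert np.array_equal(sub[0].pressures[:, 1], micro_trials[0].pressures[:, 0])
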