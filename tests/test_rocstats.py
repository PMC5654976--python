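import numpy as np
import pytest
from scipy import stats

from bmorim.errors import InputError
from bmorim.rocstats import (
    HIGHER_IS_CASE,
    LOWER_IS_CASE,
    auc,
    benjamini_hochberg,
    bootstrap_pauc_test,
    compare_correlations_bootstrap,
    delong_paired_test,
    partial_auc,
    sensitivity_at_specificity,
    spearman_rho,
)


def _labels(n_case, n_control):
    return np.concatenate([np.ones(n_case, bool), np.zeros(n_control, bool)])


class TestAuc:
    def test_pair_counting_example(self):
        scores = [2.5, 4, 1, 2, 3]
        labels = _labels(2, 3)
        assert auc(scores, labels, HIGHER_IS_CASE) == pytest.approx(5 / 6)

    def test_perfect_separation(self):
        assert auc([10, 11, 1, 2], _labels(2, 2), HIGHER_IS_CASE) == 1.0

    def test_all_ties_is_half(self):
        assert auc([3, 3, 3, 3], _labels(2, 2), HIGHER_IS_CASE) == 0.5

    def test_direction_reversal_complements(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        if not labels.any() or labels.all():
            labels[0], labels[1] = True, False
        a = auc(scores, labels, HIGHER_IS_CASE)
        assert auc(scores, labels, LOWER_IS_CASE) == pytest.approx(1 - a)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        a = auc(scores, labels, HIGHER_IS_CASE)
        assert auc(np.exp(scores), labels, HIGHER_IS_CASE) == pytest.approx(a)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=50).round(1)  # rounding forces ties
        labels = rng.random(50) < 0.5
        labels[0], labels[1] = True, False
        assert auc(scores, labels, HIGHER_IS_CASE) == pytest.approx(
            roc_auc_score(labels, scores)
        )

    def test_missing_class_rejected(self):
        with pytest.raises(InputError):
            auc([1, 2], np.array([True, True]))


class TestDelong:
    def test_identical_scores_defined_result(self, rng):
        s = rng.normal(size=20)
        labels = _labels(10, 10)
        a1, a2, z, p = delong_paired_test(s, s, labels)
        assert (z, p) == (0.0, 1.0)
        assert a1 == a2

    def test_monotone_transform_gives_equal_aucs(self, rng):
        s = rng.normal(size=30)
        labels = _labels(15, 15)
        a1, a2, z, p = delong_paired_test(s, np.tanh(s), labels)
        assert a1 == pytest.approx(a2)
        assert z == pytest.approx(0.0, abs=1e-10)

    def test_agrees_with_permutation_oracle(self):
        """Paired permutation test: swap the two parameters within each eye
        (sign-flip of the per-eye contribution to the AUC difference)."""
        rng = np.random.default_rng(2024)
        n = 40
        latent = rng.normal(size=n) + np.where(np.arange(n) < 15, 1.0, 0.0)
        labels = _labels(15, 25)
        s1 = latent + rng.normal(scale=0.6, size=n)
        s2 = latent + rng.normal(scale=0.9, size=n)
        _, _, _, p_delong = delong_paired_test(s1, s2, labels, HIGHER_IS_CASE)

        B = 20000
        swap = rng.random((B, n)) < 0.5
        m1 = np.where(swap, s2, s1)
        m2 = np.where(swap, s1, s2)

        def auc_rows(m):
            r = stats.rankdata(m, axis=1)
            n1 = labels.sum()
            u = r[:, labels].sum(axis=1) - n1 * (n1 + 1) / 2
            return u / (n1 * (n - n1))

        d_perm = auc_rows(m1) - auc_rows(m2)
        d_obs = auc(s1, labels, HIGHER_IS_CASE) - auc(s2, labels, HIGHER_IS_CASE)
        p_perm = np.mean(np.abs(d_perm) >= abs(d_obs) - 1e-12)
        assert p_delong == pytest.approx(p_perm, abs=0.02)


class TestPartialAuc:
    def test_perfect_classifier_full_box(self):
        assert partial_auc([10, 11, 1, 2], _labels(2, 2), direction=HIGHER_IS_CASE) == (
            pytest.approx(0.1)
        )

    def test_uninformative_diagonal(self):
        assert partial_auc([5, 5, 5, 5], _labels(2, 2)) == pytest.approx(0.005)

    def test_bounds_and_full_range_consistency(self, rng):
        scores = rng.normal(size=60).round(1)
        labels = rng.random(60) < 0.4
        labels[0], labels[1] = True, False
        p = partial_auc(scores, labels, 0.9, 1.0, HIGHER_IS_CASE)
        a = auc(scores, labels, HIGHER_IS_CASE)
        assert 0.0 <= p <= 0.1 + 1e-12
        assert p <= a + 1e-12
        full = partial_auc(scores, labels, 0.0, 1.0, HIGHER_IS_CASE)
        assert full == pytest.approx(a, abs=1e-12)

    def test_invalid_range_rejected(self):
        with pytest.raises(InputError):
            partial_auc([1, 2, 3], _labels(1, 2), 0.95, 0.9)


class TestBootstrapPauc:
    def test_identical_parameters_give_p_one(self, rng):
        s = rng.normal(size=30)
        labels = _labels(15, 15)
        assert bootstrap_pauc_test(s, s, labels, B=200, seed=0) == 1.0

    def test_seed_reproducibility(self, rng):
        s1 = rng.normal(size=40)
        s2 = s1 + rng.normal(scale=0.3, size=40)
        labels = _labels(20, 20)
        p1 = bootstrap_pauc_test(s1, s2, labels, B=300, seed=5)
        p2 = bootstrap_pauc_test(s1, s2, labels, B=300, seed=5)
        assert p1 == p2

    def test_small_b_rejected(self):
        with pytest.raises(InputError):
            bootstrap_pauc_test([1, 2], [1, 2], [True, False], B=10)


class TestSensitivityAtSpecificity:
    def test_perfect_separation(self):
        labels = _labels(2, 3)
        s = [0.5, 0.2, 3, 4, 5]
        assert sensitivity_at_specificity(s, labels, 0.95) == 1.0
        assert sensitivity_at_specificity(s, labels, 0.90) == 1.0

    def test_hand_enumerated_roc(self):
        controls = list(range(1, 11))
        scores = np.array([5.5, 20.0] + controls)
        labels = _labels(2, 10)
        assert sensitivity_at_specificity(scores, labels, 0.90, HIGHER_IS_CASE) == 0.5

    def test_all_ties_zero(self):
        assert sensitivity_at_specificity([1, 1, 1, 1], _labels(2, 2), 0.90) == 0.0


class TestSpearman:
    def test_monotone_limits(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_rho(x, [10, 20, 25, 30, 41]) == pytest.approx(1.0)
        assert spearman_rho(x, [5, 4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # ranks differ by d = (1, -1, 1, -1, 0): 1 - 6*4/(5*24) = 0.8
        assert spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_constant_vector_flagged(self):
        with pytest.raises(InputError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestCompareCorrelations:
    def test_identical_series_p_one(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        assert compare_correlations_bootstrap(x, y, y, B=200, seed=1) == 1.0

    def test_seeded_determinism(self, rng):
        x = rng.normal(size=40)
        y1 = x + rng.normal(scale=0.5, size=40)
        y2 = rng.normal(size=40)
        args = (x, y1, y2)
        assert compare_correlations_bootstrap(*args, B=200, seed=9) == (
            compare_correlations_bootstrap(*args, B=200, seed=9)
        )

    def test_detects_strong_vs_weak_correlation(self):
        """Power check: strongly vs. weakly informative parameter at n=200
        should be flagged in the large majority of repetitions."""
        hits = 0
        reps = 30
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            x = rng.normal(size=200)
            y1 = x + rng.normal(scale=0.4, size=200)
            y2 = 0.2 * x + rng.normal(size=200)
            p = compare_correlations_bootstrap(x, y1, y2, B=300, seed=rep)
            hits += p < 0.05
        assert hits >= 0.8 * reps

    def test_small_n_refused(self):
        with pytest.raises(InputError):
            compare_correlations_bootstrap([1] * 5, [1] * 5, [1] * 5, B=200)


class TestBenjaminiHochberg:
    def test_step_up_hand_example(self):
        adjusted, threshold = benjamini_hochberg([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(adjusted, [0.05] * 5)
        assert threshold == 0.05

    def test_single_p_identity(self):
        adjusted, _ = benjamini_hochberg([0.03])
        assert adjusted[0] == pytest.approx(0.03)

    def test_all_ones_threshold_zero(self):
        adjusted, threshold = benjamini_hochberg([1.0, 1.0, 1.0])
        assert threshold == 0.0

    def test_adjusted_monotone_in_raw(self, rng):
        p = rng.uniform(size=20)
        adjusted, _ = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(adjusted[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            benjamini_hochberg([0.5, 1.2])
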