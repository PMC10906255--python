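"""Splitting, sparse classifier, ROC/CI, operating point, permutation, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

import fingermet as fm
from fingermet.containers import FeatureMatrix
from fingermet.diagnosis import auc_rank, default_lambda_grid

from conftest import label_vector, make_null_matrix, planted_single_matrix

SMALL_GRID = np.logspace(-2, 1, 8)


def concordance_oracle(scores, y):
    """O(n²) pairwise concordance with ties counted one half."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestSplit:
    @staticmethod
    def demo_metadata(n=100, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "group": ["HC"] * (n // 2) + ["AECOPD"] * (n - n // 2),
            "age": rng.normal(65, 8, n).round(1),
            "sex": rng.choice(["M", "F"], n),
        })

    def test_stratified_proportions(self):
        meta = self.demo_metadata()
        plan = fm.split_cohort(meta, 0.2, seed=1)
        assert len(plan.validation_ids) == 20
        val_groups = meta.set_index("sample_id").loc[plan.validation_ids, "group"]
        assert abs((val_groups == "HC").sum() - 10) <= 1

    def test_same_seed_same_split(self):
        meta = self.demo_metadata()
        p1 = fm.split_cohort(meta, 0.3, seed=5)
        p2 = fm.split_cohort(meta, 0.3, seed=5)
        assert p1.validation_ids == p2.validation_ids

    def test_balance_report_present(self):
        plan = fm.split_cohort(self.demo_metadata(), 0.2, seed=2)
        assert set(plan.balance) == {"age", "sex"}
        assert all(0 <= v <= 1 for v in plan.balance.values())

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            fm.split_cohort(self.demo_metadata(), 1.2, seed=0)


class TestAUC:
    def test_perfect_and_inverted(self):
        y = np.array([0, 0, 1, 1])
        assert auc_rank(y.astype(float), y) == 1.0
        assert auc_rank(1.0 - y, y) == 0.0

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(10, 51)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)  # induce ties
            assert auc_rank(scores, y) == pytest.approx(
                concordance_oracle(scores, y), abs=1e-12)
            assert auc_rank(scores, y) == pytest.approx(
                roc_auc_score(y, scores), abs=1e-12)

    def test_bootstrap_ci_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            y = rng.integers(0, 2, 40)
            if y.sum() in (0, 40):
                continue
            p = rng.uniform(size=40) + 0.3 * y
            auc, (lo, hi), _ = fm.roc_with_ci(p, y, n_boot=300, seed=seed)
            assert lo <= auc <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_rank(np.array([0.1, 0.2]), np.array([1, 1]))


class TestOperatingPoint:
    def test_separable_case_perfect(self):
        y = np.array([0] * 5 + [1] * 5)
        p = y * 0.8 + 0.1
        sens, spec, acc, _ = fm.operating_point(p, y)
        assert (sens, spec, acc) == (1.0, 1.0, 1.0)

    def test_degenerate_equal_probabilities(self):
        y = np.array([0, 1, 0, 1])
        p = np.full(4, 0.5)
        sens, spec, acc, thr = fm.operating_point(p, y)
        assert sens == 1.0 and spec == 0.0

    def test_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = rng.integers(10, 101)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            p = rng.uniform(size=n)
            sens, spec, _, _ = fm.operating_point(p, y)
            best = max(
                ((p >= t)[y == 1].mean() + (p < t)[y == 0].mean() - 1)
                for t in np.unique(p))
            assert sens + spec - 1 == pytest.approx(best, abs=1e-12)

    def test_fixed_rule(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.2, 0.4, 0.6, 0.8])
        sens, spec, acc, thr = fm.operating_point(p, y, rule="fixed",
                                                  fixed_threshold=0.5)
        assert thr == 0.5 and sens == 1.0 and spec == 1.0


class TestSparseClassifier:
    def test_separable_two_feature_data(self):
        rng = np.random.default_rng(8)
        n = 60
        y = np.repeat([0, 1], n // 2)
        x = np.column_stack([y * 4.0 + rng.normal(0, 0.1, n),
                             rng.normal(0, 1, n)])
        m = FeatureMatrix(np.array([110.0, 120.0]), np.abs(x) + 1.0,
                          [f"s{i}" for i in range(n)],
                          ["HC" if v == 0 else "AECOPD" for v in y])
        res = fm.fit_sparse_classifier(m, cv_folds=3, seed=8,
                                       lambda_grid=SMALL_GRID, n_boot=50)
        assert res.auc == 1.0

    def test_single_marker_matches_binormal_auc(self):
        """Δ=2 marker → discovery AUC near Φ(2/√2) = 0.921 at n=200/group."""
        matrix, _, _ = planted_single_matrix(2.0, 200, seed=9)
        res = fm.fit_sparse_classifier(matrix, cv_folds=3, seed=9,
                                       lambda_grid=SMALL_GRID, n_boot=50)
        target = stats.norm.cdf(2 / np.sqrt(2))
        assert res.auc == pytest.approx(target, abs=0.05)

    def test_null_cohort_cv_auc_near_chance(self):
        aucs = []
        for seed in range(9):
            matrix, _, _ = make_null_matrix(50, 15, seed=seed)
            res = fm.fit_sparse_classifier(matrix, cv_folds=3, seed=seed,
                                           lambda_grid=SMALL_GRID, n_boot=50)
            aucs.append(res.cv_auc_mean)
        assert 0.4 <= np.median(aucs) <= 0.6

    def test_discovery_model_independent_of_validation(self):
        matrix, _, _ = planted_single_matrix(1.0, 40, seed=10)
        r1 = fm.fit_sparse_classifier(matrix, cv_folds=3, seed=10,
                                      lambda_grid=SMALL_GRID, n_boot=50)
        r2 = fm.fit_sparse_classifier(matrix, cv_folds=3, seed=10,
                                      lambda_grid=SMALL_GRID, n_boot=50)
        assert np.array_equal(r1.coefficients, r2.coefficients)
        other, _, _ = make_null_matrix(10, 31, seed=99)
        assert np.allclose(r1.predict_proba(other), r2.predict_proba(other))

    def test_degenerate_fold_guidance(self):
        matrix, _, _ = planted_single_matrix(1.0, 4, n_null=5, seed=11)
        with pytest.raises(ValueError, match="cv_folds"):
            fm.fit_sparse_classifier(matrix, cv_folds=5, seed=11,
                                     lambda_grid=SMALL_GRID)


class TestPermutation:
    def test_add_one_lower_bound(self):
        matrix, _, _ = make_null_matrix(15, 8, seed=12)
        p, null, obs = fm.permutation_test(matrix, n_perm=100, seed=12,
                                           lambda_grid=SMALL_GRID[:4], cv_folds=3)
        assert p >= 1.0 / 101.0

    def test_strong_signal_attains_minimum_p(self):
        """Δ=2 at n=100/group with 199 permutations → p = 1/200."""
        matrix, _, _ = planted_single_matrix(2.0, 100, n_null=8, seed=13)
        p, _, obs = fm.permutation_test(matrix, n_perm=199, seed=13,
                                        lambda_grid=SMALL_GRID[:4], cv_folds=3)
        assert p == pytest.approx(1.0 / 200.0)


class TestPCA:
    def test_rank_one_matrix_single_component(self):
        u = np.linspace(1, 3, 10)[:, None]
        v = np.array([[2.0, 1.0, 4.0]])
        m = FeatureMatrix(np.array([110.0, 120.0, 130.0]), u @ v + 10,
                          [f"s{i}" for i in range(10)])
        scores, ev = fm.pca_scores(m, n_components=2)
        assert ev[0] > 0.999

    def test_scores_orthogonal(self, matrix_cohort):
        matrix, _, _ = matrix_cohort
        scores, _ = fm.pca_scores(matrix, n_components=4)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_matches_covariance_eigendecomposition(self):
        """5×4 oracle: scores/variances from the covariance eigenproblem."""
        rng = np.random.default_rng(14)
        x = rng.normal(size=(5, 4))
        m = FeatureMatrix(np.array([110.0, 120.0, 130.0, 140.0]), np.abs(x) + 1,
                          [f"s{i}" for i in range(5)])
        scores, ev = fm.pca_scores(m, n_components=3)
        vals = m.values
        z = (vals - vals.mean(0)) / vals.std(0)
        cov = z.T @ z / 5
        w, v = np.linalg.eigh(cov)
        w, v = w[::-1], v[:, ::-1]
        assert np.allclose(ev, (w / w.sum())[:3], atol=1e-10)
        expected = z @ v[:, :3]
        for k in range(3):  # eigenvectors defined up to sign
            assert (np.allclose(scores[:, k], expected[:, k], atol=1e-8)
                    or np.allclose(scores[:, k], -expected[:, k], atol=1e-8))

    def test_constant_feature_dropped_with_warning(self):
        vals = np.column_stack([np.ones(6), np.arange(6.0) + 1])
        m = FeatureMatrix(np.array([110.0, 120.0]), vals,
                          [f"s{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="constant"):
            scores, _ = fm.pca_scores(m, n_components=1)
        assert scores.shape == (6, 1)
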