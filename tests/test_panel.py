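"""Four-criterion screening, panel model, heatmap, panel PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fingermet as fm
from fingermet.containers import FeatureMatrix

from conftest import make_null_matrix, planted_single_matrix

SMALL_GRID = np.logspace(-2, 1, 8)
FAST_CRIT = fm.ScreeningCriteria(n_resamples=50)


class TestFrequency:
    def test_dominating_feature_always_selected(self):
        matrix, _, gt = planted_single_matrix(3.0, 30, n_null=20, seed=1)
        freq = fm.feature_frequency(matrix, criteria=FAST_CRIT, seed=1,
                                    lambda_grid=SMALL_GRID, cv_folds=3)
        planted = f"{gt.differential_features[0][1]:.4f}"
        assert freq.loc[planted] == 1.0

    def test_noise_features_rarely_selected(self):
        medians = []
        for seed in range(5):
            matrix, _, gt = planted_single_matrix(3.0, 30, n_null=20, seed=seed)
            freq = fm.feature_frequency(matrix, criteria=FAST_CRIT, seed=seed,
                                        lambda_grid=SMALL_GRID, cv_folds=3)
            planted = f"{gt.differential_features[0][1]:.4f}"
            medians.append(freq.drop(planted).median())
        assert np.median(medians) < 0.5

    def test_bounded_and_reproducible(self):
        matrix, _, _ = planted_single_matrix(1.0, 20, n_null=10, seed=2)
        f1 = fm.feature_frequency(matrix, criteria=FAST_CRIT, seed=2,
                                  lambda_grid=SMALL_GRID, cv_folds=3)
        f2 = fm.feature_frequency(matrix, criteria=FAST_CRIT, seed=2,
                                  lambda_grid=SMALL_GRID, cv_folds=3)
        assert ((f1 >= 0) & (f1 <= 1)).all()
        assert f1.equals(f2)


class TestFeatureStats:
    def test_constant_feature_conventions(self):
        vals = np.column_stack([np.full(12, 5.0), np.arange(12.0) + 1])
        m = FeatureMatrix(np.array([110.0, 120.0]), vals,
                          [f"s{i}" for i in range(12)],
                          ["HC"] * 6 + ["AECOPD"] * 6)
        t = fm.feature_stats(m)
        assert t.iloc[0]["p"] == 1.0
        assert t.iloc[0]["auc_single"] == 0.5
        assert t.iloc[0]["fold_change"] == pytest.approx(1.0)
        assert t.iloc[0]["direction"] == "up"  # documented tie convention

    def test_planted_marker_power(self):
        """Δ=2 at n=100/group: q < 0.05 in ≥95% of seeds and the single-feature
        AUC distributed around the binormal value Φ(2/√2) = 0.921."""
        sig = 0
        aucs = []
        n_seeds = 50
        for seed in range(n_seeds):
            matrix, _, gt = planted_single_matrix(2.0, 100, n_null=10, seed=seed)
            t = fm.feature_stats(matrix)
            row = t.loc[f"{gt.differential_features[0][1]:.4f}"]
            sig += row["q"] < 0.05
            aucs.append(row["auc_single"])
        assert sig >= 0.95 * n_seeds
        assert np.mean(aucs) == pytest.approx(stats.norm.cdf(2 / np.sqrt(2)),
                                              abs=0.02)

    def test_rank_sum_p_matches_exact_enumeration(self):
        """4v4: implementation p equals the full permutation distribution."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=8)
            if len(np.unique(x)) < 8:
                continue
            y = np.array([0] * 4 + [1] * 4)
            vals = np.column_stack([np.abs(x) + 1.0])
            m = FeatureMatrix(np.array([110.0]), vals,
                              [f"s{i}" for i in range(8)],
                              ["HC" if v == 0 else "AECOPD" for v in y])
            with np.errstate(all="ignore"):
                t = fm.feature_stats(m, positive_label="AECOPD")
            ranks = stats.rankdata(np.abs(x) + 1.0)
            obs = ranks[y == 1].sum()
            null = [sum(ranks[list(c)]) for c in itertools.combinations(range(8), 4)]
            null = np.array(null)
            mean = null.mean()
            p_exact = np.mean(np.abs(null - mean) >= np.abs(obs - mean) - 1e-12)
            assert t.iloc[0]["p"] == pytest.approx(p_exact, abs=1e-10)

    def test_direction_follows_fold_change(self, matrix_cohort):
        matrix, _, gt = matrix_cohort
        t = fm.feature_stats(matrix)
        for name, mz, direction, _ in gt.differential_features:
            assert t.loc[f"{mz:.4f}", "direction"] == direction


class TestScreen:
    @staticmethod
    def random_stats(seed=0, n=40):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "mz": np.sort(rng.uniform(100, 400, n)),
            "frequency": rng.uniform(size=n),
            "p": rng.uniform(size=n),
            "abundance": rng.uniform(0, 2000, n),
            "auc_single": rng.uniform(0.5, 1.0, n),
        })

    def test_vacuous_criteria_keep_everything(self):
        stats_table = self.random_stats()
        crit = fm.ScreeningCriteria(min_frequency=0.0, max_p=1.0,
                                    min_abundance=0.0, min_auc=0.0,
                                    n_resamples=50)
        rep = fm.screen_panel(stats_table, crit)
        assert rep.panel_index.size == len(stats_table)

    @pytest.mark.parametrize("field,delta", [
        ("min_frequency", 0.2), ("max_p", -0.02),
        ("min_abundance", 300.0), ("min_auc", 0.1),
    ])
    def test_tightening_any_threshold_never_enlarges_panel(self, field, delta):
        stats_table = self.random_stats(seed=3)
        base = fm.ScreeningCriteria(min_frequency=0.5, max_p=0.5,
                                    min_abundance=500.0, min_auc=0.6,
                                    n_resamples=50)
        tighter = fm.ScreeningCriteria(**{**base.__dict__, field:
                                          getattr(base, field) + delta})
        small = fm.screen_panel(stats_table, tighter).panel_index
        big = fm.screen_panel(stats_table, base).panel_index
        assert set(small) <= set(big)

    def test_deterministic_given_stats(self):
        stats_table = self.random_stats(seed=4)
        r1 = fm.screen_panel(stats_table)
        r2 = fm.screen_panel(stats_table)
        assert np.array_equal(r1.panel_index, r2.panel_index)

    def test_empty_panel_warns_not_raises(self):
        stats_table = self.random_stats(seed=5)
        crit = fm.ScreeningCriteria(min_frequency=1.0, max_p=1e-12,
                                    min_abundance=1e9, min_auc=1.0,
                                    n_resamples=50)
        with pytest.warns(UserWarning, match="empty panel"):
            rep = fm.screen_panel(stats_table, crit)
        assert rep.panel_index.size == 0

    def test_planted_markers_recovered(self):
        templates, truth = fm.build_template_library(60, 8, 1.5, seed=106)
        spec = fm.CohortSpec(groups=(("HC", 100), ("AECOPD", 100)), seed=106)
        matrix, _, gt = fm.simulate_feature_matrix(
            spec, templates,
            fm.NoiseSpec(baseline_amplitude=0.0, mz_jitter_sd=0.0,
                         additive_noise_sd=0.0), truth)
        rep = fm.run_screen(matrix, criteria=FAST_CRIT, seed=6,
                            lambda_grid=SMALL_GRID, cv_folds=3)
        truth_mz = {round(mz, 4) for _, mz, _, _ in gt.differential_features}
        got = {round(m, 4) for m in rep.panel_mz}
        assert len(truth_mz & got) >= 7
        assert len(got - truth_mz) <= 2


class TestPanelModel:
    def test_single_feature_panel_matches_single_auc(self):
        matrix, _, gt = planted_single_matrix(1.5, 50, n_null=5, seed=7)
        t = fm.feature_stats(matrix)
        planted_pos = int(np.argmin(np.abs(matrix.feature_mz
                                           - gt.differential_features[0][1])))
        res = fm.panel_model(matrix, np.array([planted_pos]), seed=7, n_boot=50)
        assert res.auc == pytest.approx(
            t.iloc[planted_pos]["auc_single"], abs=1e-6)

    def test_panel_beats_best_single_marker(self):
        """8 independent Δ=1 markers combined outperform any single one."""
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            templates, truth = fm.build_template_library(0, 8, 1.0, seed=seed)
            spec = fm.CohortSpec(groups=(("HC", 50), ("AECOPD", 50)), seed=seed)
            matrix, _, _ = fm.simulate_feature_matrix(spec, templates,
                                                      fm.NoiseSpec(), truth)
            t = fm.feature_stats(matrix)
            res = fm.panel_model(matrix, np.arange(8), seed=seed, n_boot=50)
            if res.auc > t["auc_single"].max():
                wins += 1
        assert wins >= 0.9 * n_seeds

    def test_permuted_labels_give_chance_validation_auc(self):
        """Out-of-sample panel AUC under permuted labels sits at chance."""
        aucs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            matrix, _, _ = planted_single_matrix(1.5, 40, n_null=7, seed=seed)
            perm = list(rng.permutation(matrix.labels))
            idx = rng.permutation(matrix.n_samples)
            split = (np.sort(idx[:48]), np.sort(idx[48:]))
            res = fm.panel_model(matrix, np.arange(4), labels=perm,
                                 seed=seed, n_boot=50, split=split)
            aucs.append(res.validation_auc)
        assert 0.45 <= np.median(aucs) <= 0.55

    def test_empty_panel_rejected(self, matrix_cohort):
        matrix, _, _ = matrix_cohort
        with pytest.raises(ValueError):
            fm.panel_model(matrix, np.array([], dtype=int))


class TestHeatmap:
    def test_rows_standardized(self, matrix_cohort):
        matrix, _, _ = matrix_cohort
        h = fm.heatmap_matrix(matrix, np.arange(6))
        assert np.abs(h.to_numpy().mean(axis=1)).max() < 1e-10
        assert np.allclose(h.to_numpy().std(axis=1), 1.0)

    def test_scale_invariance(self, matrix_cohort):
        matrix, _, _ = matrix_cohort
        doubled = FeatureMatrix(matrix.feature_mz, matrix.values * 2,
                                matrix.sample_ids, matrix.labels)
        h1 = fm.heatmap_matrix(matrix, np.arange(6))
        h2 = fm.heatmap_matrix(doubled, np.arange(6))
        assert np.allclose(h1.to_numpy(), h2.to_numpy())

    def test_up_markers_higher_in_case_block(self, matrix_cohort):
        matrix, _, gt = matrix_cohort
        idx = np.array([int(np.argmin(np.abs(matrix.feature_mz - mz)))
                        for _, mz, d, _ in gt.differential_features if d == "up"])
        h = fm.heatmap_matrix(matrix, idx)
        lab = np.array([str(g) for g in matrix.labels])
        case_cols = [c for c in h.columns if c.startswith("AECOPD")]
        ctrl_cols = [c for c in h.columns if c.startswith("HC")]
        assert (h[case_cols].mean(axis=1) > h[ctrl_cols].mean(axis=1)).all()


class TestPanelPCA:
    def test_panel_pca_separates_better_than_all_features(self):
        """Panel-restricted PCA beats all-feature PCA on group separation."""
        ratios = []
        for seed in range(20):
            templates, truth = fm.build_template_library(200, 8, 1.5, seed=seed)
            spec = fm.CohortSpec(groups=(("HC", 40), ("AECOPD", 40)), seed=seed)
            matrix, _, gt = fm.simulate_feature_matrix(spec, templates,
                                                       fm.NoiseSpec(), truth)
            idx = np.sort([int(np.argmin(np.abs(matrix.feature_mz - mz)))
                           for _, mz, _, _ in gt.differential_features])
            s_all, _ = fm.pca_scores(matrix, 2)
            s_panel, _ = fm.pca_scores(matrix.subset_features(idx), 2)
            ratios.append(fm.group_separation(s_panel, matrix.labels)
                          - fm.group_separation(s_all, matrix.labels))
        assert np.median(ratios) > 0
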