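import numpy as np
import pandas as pd
import pytest
from scipy import stats

from decaysense import (
    ModelSpec,
    compute_metrics,
    cross_validate,
    group_difference_test,
    pca_reduce,
    project_2d,
    standardize_features,
    sweep_models,
)

from conftest import pairwise_auc_oracle


def gaussian_clouds(n_per_class=30, n_features=4, separation=10.0, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, (n_per_class, n_features))
    X1 = rng.normal(separation, 1.0, (n_per_class, n_features))
    X = pd.DataFrame(np.vstack([X0, X1]), columns=[f"C{j}" for j in range(n_features)])
    labels = np.array(["HC"] * n_per_class + ["AD"] * n_per_class)
    return X, labels


class TestStandardize:
    def test_direct_arithmetic(self):
        Z = pd.DataFrame({"C1": [8.0, 10.0, 12.0]})
        S, (mean, sd) = standardize_features(Z)
        np.testing.assert_allclose(S["C1"], [-1.0, 0.0, 1.0])
        assert mean["C1"] == 10.0 and sd["C1"] == 2.0

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        Z = pd.DataFrame(rng.normal(5, 3, (20, 4)))
        S1, _ = standardize_features(Z)
        S2, _ = standardize_features(S1)
        np.testing.assert_allclose(S2.to_numpy(), S1.to_numpy(), atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        Z = pd.DataFrame({"C1": [1.0, 1.0, 1.0], "C2": [8.0, 10.0, 12.0]})
        with pytest.warns(UserWarning, match="C1"):
            S, _ = standardize_features(Z)
        assert list(S.columns) == ["C2"]
        np.testing.assert_allclose(S["C2"], [-1.0, 0.0, 1.0])

    def test_train_params_apply_to_held_out(self):
        Z = pd.DataFrame({"C1": [8.0, 10.0, 12.0]})
        _, params = standardize_features(Z)
        S_new, _ = standardize_features(pd.DataFrame({"C1": [14.0]}), params=params)
        assert S_new["C1"].iloc[0] == pytest.approx(2.0)


class TestPCA:
    def test_exact_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        basis = rng.normal(size=(2, 5))
        coords = rng.normal(size=(12, 2))
        M = coords @ basis
        scores, loadings, _ = pca_reduce(M, 2)
        np.testing.assert_allclose(scores @ loadings + M.mean(0), M, atol=1e-10)

    def test_explained_variance_fractions(self):
        rng = np.random.default_rng(3)
        S = rng.normal(size=(15, 6))
        _, _, evr = pca_reduce(S, 4)
        assert evr.sum() <= 1.0 + 1e-12
        assert (np.diff(evr) <= 1e-12).all()

    def test_scores_match_eigendecomposition(self):
        """Scores equal projections onto covariance eigenvectors (sign-aligned)."""
        rng = np.random.default_rng(4)
        S = rng.normal(size=(6, 4))
        scores, loadings, _ = pca_reduce(S, 3)
        centered = S - S.mean(0)
        w, V = np.linalg.eigh(np.cov(centered, rowvar=False))
        V = V[:, np.argsort(w)[::-1]][:, :3]
        expected = centered @ V
        for j in range(3):
            sign = np.sign(expected[:, j] @ scores[:, j])
            np.testing.assert_allclose(scores[:, j], sign * expected[:, j], atol=1e-10)

    def test_npc_bounds_enforced(self):
        with pytest.raises(ValueError):
            pca_reduce(np.zeros((5, 3)), 5)


class TestComputeMetrics:
    def test_confusion_matrix_formulas(self):
        """TP=8 FP=2 FN=2 TN=8 gives 0.80 across the four threshold metrics."""
        truth = [1] * 10 + [0] * 10
        scores = [1.0] * 8 + [0.0] * 2 + [1.0] * 2 + [0.0] * 8
        m = compute_metrics(truth, scores, threshold=0.5)
        for name in ("accuracy", "precision", "recall", "f1"):
            assert m[name] == pytest.approx(0.80)

    def test_perfect_scores(self):
        m = compute_metrics([0, 1, 0, 1], [0.0, 1.0, 0.0, 1.0])
        assert m["auc"] == 1.0

    def test_auc_pair_counting_example(self):
        m = compute_metrics([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.3])
        assert m["auc"] == pytest.approx(0.75)
        assert m["auc"] == pytest.approx(
            pairwise_auc_oracle([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.3])
        )

    def test_auc_equals_brute_force_on_random_vectors(self):
        """Rank-based AUC agrees with exhaustive positive-negative pair counting,
        ties included, across 100 random score vectors."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(6, 30))
            truth = rng.integers(0, 2, n)
            if truth.min() == truth.max():
                truth[0] = 1 - truth[0]
            scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
            m = compute_metrics(truth, scores)
            assert m["auc"] == pytest.approx(pairwise_auc_oracle(truth, scores), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        truth = rng.integers(0, 2, 40)
        truth[:2] = [0, 1]
        scores = rng.normal(size=40)
        a0 = compute_metrics(truth, scores)["auc"]
        a1 = compute_metrics(truth, np.exp(3 * scores) + 5)["auc"]
        assert a1 == pytest.approx(a0, abs=1e-12)

    def test_one_class_truth_gives_nan_auc_with_other_metrics(self):
        with pytest.warns(UserWarning, match="AUC"):
            m = compute_metrics([1, 1, 1], [0.9, 0.8, 0.2])
        assert np.isnan(m["auc"])
        assert m["recall"] == pytest.approx(2 / 3)


class TestCrossValidate:
    def test_separable_clouds_perfect_lda(self):
        X, labels = gaussian_clouds(separation=10.0, seed=8)
        report = cross_validate(X, labels, ModelSpec("lda", n_pc=2, seed=0))
        assert report.averages["auc"] == pytest.approx(1.0)
        assert report.averages["accuracy"] == pytest.approx(1.0)

    def test_permutation_null_auc_centers_on_half(self):
        """Permuting labels destroys signal: mean CV AUC over 101 permutations
        sits at 0.50 +/- 0.05."""
        X, labels = gaussian_clouds(separation=10.0, seed=9)
        aucs = []
        for perm_seed in range(101):
            rng = np.random.default_rng(perm_seed)
            permuted = rng.permutation(labels)
            report = cross_validate(X, permuted, ModelSpec("lda", n_pc=2, seed=perm_seed))
            aucs.append(report.averages["auc"])
        assert abs(np.mean(aucs) - 0.50) < 0.05

    def test_report_average_is_fold_mean(self):
        X, labels = gaussian_clouds(separation=2.0, seed=10)
        report = cross_validate(X, labels, ModelSpec("rf", n_pc=3, seed=1))
        for m, v in report.averages.items():
            assert v == pytest.approx(report.fold_metrics[m].mean())

    def test_stratified_fold_balance(self):
        """Each fold's class proportion is within one sample of the global one."""
        X, labels = gaussian_clouds(n_per_class=20, separation=1.0, seed=11)
        report = cross_validate(X, labels, ModelSpec("lda", n_pc=2, seed=2))
        y = (labels == "AD").astype(int)
        for fold in np.unique(report.fold_assignments):
            mask = report.fold_assignments == fold
            expected = y.mean() * mask.sum()
            assert abs(y[mask].sum() - expected) <= 1.0

    def test_infeasible_folds_rejected(self):
        X, labels = gaussian_clouds(n_per_class=5, seed=12)
        with pytest.raises(ValueError):
            cross_validate(X, labels, ModelSpec("lda", n_pc=2), k=20)

    def test_single_class_rejected(self):
        X, _ = gaussian_clouds(seed=13)
        with pytest.raises(ValueError):
            cross_validate(X, ["AD"] * len(X), ModelSpec("lda", n_pc=2))

    @pytest.mark.parametrize("family", ["logistic", "qda", "svm", "knn", "tree"])
    def test_all_families_run(self, family):
        X, labels = gaussian_clouds(n_per_class=15, separation=6.0, seed=14)
        report = cross_validate(X, labels, ModelSpec(family, n_pc=2, seed=3))
        assert report.averages["auc"] > 0.9


class TestSweepModels:
    def test_degenerate_grid_equals_single_cv(self):
        X, labels = gaussian_clouds(n_per_class=12, separation=3.0, seed=15)
        grid = sweep_models(X, labels, families=["lda"], npc_grid=[2], seed=4)
        assert len(grid) == 1
        report = cross_validate(X, labels, ModelSpec("lda", n_pc=2, seed=4))
        assert grid.iloc[0]["auc"] == pytest.approx(report.averages["auc"])

    def test_deterministic_given_seed(self):
        X, labels = gaussian_clouds(n_per_class=12, separation=1.5, seed=16)
        g1 = sweep_models(X, labels, families=["lda", "knn"], npc_grid=[2, 3], seed=5)
        g2 = sweep_models(X, labels, families=["lda", "knn"], npc_grid=[2, 3], seed=5)
        pd.testing.assert_frame_equal(g1, g2)

    def test_signal_in_leading_pcs_selects_small_npc(self):
        """When only the two leading PCs carry class signal, the winning family
        settles on nPC <= 3 across seeds."""
        chosen = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 24
            labels = np.array(["AD"] * n + ["HC"] * n)
            signal = np.where(labels == "AD", 3.0, -3.0)
            X = pd.DataFrame(
                {
                    "C1": signal + rng.normal(0, 1, 2 * n),
                    "C2": signal + rng.normal(0, 1, 2 * n),
                    "C3": rng.normal(0, 0.1, 2 * n),
                    "C4": rng.normal(0, 0.1, 2 * n),
                }
            )
            grid = sweep_models(X, labels, families=["lda"], npc_grid=[2, 3, 4], seed=seed)
            chosen.append(int(grid[grid["selected"]].iloc[0]["n_pc"]))
        assert np.mean([c <= 3 for c in chosen]) >= 0.9


class TestProject2D:
    def four_groups(self, seed=17):
        rng = np.random.default_rng(seed)
        means = np.array([[0, 0, 0], [8, 0, 0], [0, 8, 0], [8, 8, 8]], dtype=float)
        X = np.vstack([m + rng.normal(0, 0.5, (20, 3)) for m in means])
        labels = np.repeat(["AD", "HC", "MS", "RA"], 20)
        return X, labels

    def test_two_groups_single_axis(self):
        rng = np.random.default_rng(18)
        X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(5, 1, (10, 3))])
        coords = project_2d(X, ["AD"] * 10 + ["HC"] * 10, method="lda")
        assert np.all(coords[:, 1] == 0.0)
        assert np.ptp(coords[:, 0]) > 0

    def test_collinear_means_second_axis_uninformative(self):
        rng = np.random.default_rng(19)
        X = np.vstack([
            rng.normal(m, 0.1, (15, 3)) for m in ([0, 0, 0], [5, 5, 5], [10, 10, 10])
        ])
        labels = np.repeat(["A", "B", "C"], 15)
        coords = project_2d(X, labels, method="lda")
        between = [coords[labels == g].mean(0) for g in "ABC"]
        spread = np.var([b[1] for b in between]) / max(np.var([b[0] for b in between]), 1e-12)
        assert spread < 1e-2

    @pytest.mark.parametrize("method", ["lda", "qda"])
    def test_groups_separate_in_projection(self, method):
        """Within-group distances are smaller than between-group distances."""
        X, labels = self.four_groups()
        coords = project_2d(X, labels, method=method)
        within, between = [], []
        for i in range(len(X)):
            for j in range(i + 1, len(X), 7):
                d = np.linalg.norm(coords[i] - coords[j])
                (within if labels[i] == labels[j] else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_qda_insufficient_group_suggests_lda(self):
        rng = np.random.default_rng(20)
        X = np.vstack([rng.normal(0, 1, (3, 5)), rng.normal(4, 1, (20, 5))])
        with pytest.raises(ValueError, match="lda"):
            project_2d(X, ["A"] * 3 + ["B"] * 20, method="qda")


class TestGroupDifference:
    def test_identical_groups(self):
        res = group_difference_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert not res.significant

    def test_extreme_separation(self):
        res = group_difference_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.p < 0.001
        assert res.significant

    def test_matches_textbook_formula(self):
        """t and p agree with the pooled-variance formula computed by hand."""
        a, b = np.array([10.0, 12.0, 14.0]), np.array([11.0, 13.0, 15.0])
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        t_manual = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        p_manual = 2 * stats.t.sf(abs(t_manual), len(a) + len(b) - 2)
        res = group_difference_test(a, b)
        assert res.t == pytest.approx(t_manual, rel=1e-12)
        assert res.p == pytest.approx(p_manual, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_difference_test([1.0], [1.0, 2.0])
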