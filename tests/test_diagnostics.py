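"""Diagnostic pipeline: standardization, correlation PCA, stratified
split, GA-BP classifier, group profiles."""

import numpy as np
import pandas as pd
import pytest

import ovadx as ox
from ovadx.diagnostics import (
    GAConfig,
    StandardizedTable,
    _backprop_fine_tune,
    fit_pca,
    ga_optimize_bp,
    project_scores,
    stratified_split,
    zscore_standardize,
)
from ovadx.synthetic import INDICATOR_NAMES, NEGATIVE_DIRECTION_INDICATORS


@pytest.fixture(scope="module")
def cohort():
    return ox.generate_cohort(ox.CohortSpec(seed=7))


@pytest.fixture(scope="module")
def standardized(cohort):
    return zscore_standardize(cohort)


class TestZscore:
    def test_three_point_column(self):
        df = pd.DataFrame({"CA125": [1.0, 2.0, 3.0]})
        z = zscore_standardize(df, columns=("CA125",))
        np.testing.assert_allclose(z.values.ravel(), [-1, 0, 1])

    def test_training_columns_mean_zero_sd_one(self, standardized):
        assert np.abs(standardized.values.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(standardized.values.std(axis=0, ddof=1),
                                   1.0, atol=1e-10)

    def test_restandardizing_is_identity(self, standardized, cohort):
        df = pd.DataFrame(standardized.values, columns=standardized.columns)
        again = zscore_standardize(df)
        np.testing.assert_allclose(again.values, standardized.values,
                                   atol=1e-10)

    def test_test_rows_use_training_parameters(self, cohort):
        fit_rows = np.arange(0, 400)
        z = zscore_standardize(cohort, fit_rows=fit_rows)
        raw = cohort[list(z.columns)].to_numpy(dtype=float)
        manual = (raw - z.means) / z.sds
        np.testing.assert_allclose(z.values, manual, atol=1e-12)

    def test_constant_column_zeros_with_warning(self):
        df = pd.DataFrame({"CA125": [2.0, 2.0, 2.0], "CEA": [1.0, 2.0, 4.0]})
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_standardize(df, columns=("CA125", "CEA"))
        assert (z.values[:, 0] == 0).all()


class TestPCA:
    def test_two_perfectly_correlated_features(self):
        x = np.random.default_rng(0).standard_normal(200)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        model = fit_pca(zscore_standardize(df, columns=("a", "b")))
        np.testing.assert_allclose(model.eigenvalues, [2.0, 0.0], atol=1e-10)

    def test_eigenvalue_sum_equals_column_count(self, standardized):
        model = fit_pca(standardized)
        assert model.eigenvalues.sum() == pytest.approx(25.0, abs=1e-8)

    def test_loadings_match_sklearn_up_to_sign(self, standardized):
        from sklearn.decomposition import PCA as SkPCA

        model = fit_pca(standardized)
        sk = SkPCA(n_components=3).fit(standardized.values)
        for k in range(3):
            ours = model.loadings[:, k]
            theirs = sk.components_[k]
            agree = min(np.abs(ours - theirs).max(),
                        np.abs(ours + theirs).max())
            assert agree < 1e-8

    def test_three_dominant_components_on_strong_cohort(self, standardized):
        ev = fit_pca(standardized).eigenvalues
        assert ev[2] > 2 * ev[3]  # clear spectral gap after the 3rd

    def test_sign_convention_largest_loading_positive(self, standardized):
        model = fit_pca(standardized)
        for k in range(model.eigenvectors.shape[1]):
            v = model.eigenvectors[:, k]
            assert v[np.abs(v).argmax()] > 0

    def test_reconstruction_with_all_components(self, standardized):
        model = fit_pca(standardized)
        scores = standardized.values @ model.eigenvectors
        recon = scores @ model.eigenvectors.T
        assert np.abs(recon - standardized.values).max() < 1e-8

    def test_projected_variance_equals_eigenvalue(self, standardized):
        model = fit_pca(standardized)
        scores = project_scores(model, standardized)
        np.testing.assert_allclose(scores.var(axis=0, ddof=1),
                                   model.eigenvalues[:3], atol=1e-8)

    def test_scores_uncorrelated(self, standardized):
        scores = project_scores(fit_pca(standardized), standardized)
        corr = np.corrcoef(scores.T)
        assert abs(corr[0, 1]) < 1e-8

    def test_zero_row_zero_scores(self, standardized):
        model = fit_pca(standardized)
        z = StandardizedTable(values=np.zeros((1, 25)),
                              columns=standardized.columns,
                              means=standardized.means, sds=standardized.sds,
                              index=np.array([0]))
        assert (project_scores(model, z) == 0).all()

    def test_roster_mismatch_names_columns(self, standardized):
        model = fit_pca(standardized)
        bad = StandardizedTable(values=np.zeros((1, 2)), columns=("a", "b"),
                                means=np.zeros(2), sds=np.ones(2),
                                index=np.array([0]))
        with pytest.raises(ValueError, match="roster"):
            project_scores(model, bad)


class TestStratifiedSplit:
    def test_printed_case_counts(self, cohort):
        split = stratified_split(cohort, seed=0)
        assert split.stratum_counts["case"] == (123, 62)

    def test_control_floor_counts(self, cohort):
        split = stratified_split(cohort, seed=0)
        n_train_controls = sum(v[0] for k, v in split.stratum_counts.items()
                               if k != "case")
        n_test_controls = sum(v[1] for k, v in split.stratum_counts.items()
                              if k != "case")
        assert n_train_controls + n_test_controls == 569

    def test_disjoint_and_exhaustive(self, cohort):
        split = stratified_split(cohort, seed=3)
        train, test = set(split.train_ids), set(split.test_ids)
        assert not train & test
        assert train | test == set(cohort.index)

    def test_per_stratum_floor_rule(self, cohort):
        split = stratified_split(cohort, seed=1)
        for stratum, (n_train, n_test) in split.stratum_counts.items():
            n = n_train + n_test
            assert n_train == int(np.floor(2 / 3 * n))

    def test_reproducible_and_seed_sensitive(self, cohort):
        a = stratified_split(cohort, seed=5)
        b = stratified_split(cohort, seed=5)
        c = stratified_split(cohort, seed=6)
        assert np.array_equal(a.train_ids, b.train_ids)
        assert not np.array_equal(a.train_ids, c.train_ids)


class TestGABP:
    def test_linearly_separable_toy_problem(self):
        rng = np.random.default_rng(0)
        n = 120
        X = rng.standard_normal((n, 2))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        ga = GAConfig(population_size=30, generations=40, seed=1,
                      hidden_size_range=(2, 6), fine_tune=True)
        net = ga_optimize_bp(X[:80], y[:80], ga)
        acc = ((net.predict(X[80:]) >= 0.5).astype(int) == y[80:]).mean()
        assert acc >= 0.95

    def test_best_fitness_non_worsening(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 3))
        y = (X[:, 0] > 0).astype(int)
        ga = GAConfig(population_size=20, generations=25, seed=3)
        net = ga_optimize_bp(X, y, ga)
        hist = np.array(net.history)
        assert (np.diff(hist) <= 1e-12).all()

    def test_hidden_size_within_range(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 2))
        y = (X[:, 0] > 0).astype(int)
        ga = GAConfig(population_size=15, generations=10,
                      hidden_size_range=(3, 7), seed=5)
        net = ga_optimize_bp(X, y, ga)
        assert 3 <= net.hidden_size <= 7

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            ga_optimize_bp(np.zeros((10, 2)), np.zeros(10), GAConfig())

    def test_outputs_in_unit_interval(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((40, 2))
        y = (X[:, 0] > 0).astype(int)
        net = ga_optimize_bp(X, y, GAConfig(population_size=10,
                                            generations=5, seed=7))
        scores = ox.predict_scores(net, 100 * rng.standard_normal((30, 2)))
        assert scores.min() >= 0 and scores.max() <= 1

    def test_identical_rows_identical_scores(self):
        net = ox.BPNetwork(W1=np.array([[1.0, -2.0]]), b1=np.array([0.5]),
                           W2=np.array([2.0]), b2=-1.0)
        X = np.array([[0.3, 0.7], [0.3, 0.7]])
        s = net.predict(X)
        assert s[0] == s[1]

    def test_single_hidden_unit_hand_formula(self):
        net = ox.BPNetwork(W1=np.array([[1.0, -2.0]]), b1=np.array([0.5]),
                           W2=np.array([2.0]), b2=-1.0)
        x = np.array([0.3, 0.7])
        h = 1 / (1 + np.exp(-(1.0 * 0.3 - 2.0 * 0.7 + 0.5)))
        expected = 1 / (1 + np.exp(-(2.0 * h - 1.0)))
        assert net.predict(x)[0] == pytest.approx(expected, abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        net = ox.BPNetwork(W1=np.ones((2, 3)), b1=np.zeros(2),
                           W2=np.ones(2), b2=0.0)
        with pytest.raises(ValueError, match="features"):
            net.predict(np.ones((4, 5)))

    def test_fine_tune_reduces_training_error(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((100, 2))
        y = (X[:, 0] - X[:, 1] > 0).astype(int)
        start = ox.BPNetwork(W1=0.1 * rng.standard_normal((4, 2)),
                             b1=np.zeros(4), W2=0.1 * rng.standard_normal(4),
                             b2=0.0)
        tuned = _backprop_fine_tune(start, X, y, steps=300, lr=1.0)

        def xent(net):
            p = np.clip(net.predict(X), 1e-12, 1 - 1e-12)
            return -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))

        assert xent(tuned) < xent(start)


class TestGroupMeanProfile:
    def test_directions_on_strong_cohort(self, cohort):
        profile = ox.group_mean_profile(cohort)
        negatives = set(profile.index[profile.direction == -1])
        assert negatives == set(NEGATIVE_DIRECTION_INDICATORS)

    def test_identical_groups_zero_direction(self):
        base = ox.generate_cohort(ox.CohortSpec(
            n_cases=4, n_controls_by_subgroup=(4, 0, 0), seed=1))
        controls = base[base.label == "control"].copy()
        cases = controls.copy()
        cases["label"] = "case"
        table = pd.concat([cases, controls], ignore_index=True)
        profile = ox.group_mean_profile(table)
        assert (profile.direction == 0).all()

    def test_means_match_direct_averaging(self, cohort):
        profile = ox.group_mean_profile(cohort)
        direct = cohort.loc[cohort.label == "case", "CA125"].mean()
        assert profile.loc["CA125", "case_mean"] == pytest.approx(direct)

    def test_empty_group_rejected(self, cohort):
        only_cases = cohort[cohort.label == "case"]
        with pytest.raises(ValueError, match="nonempty"):
            ox.group_mean_profile(only_cases)


class TestEndToEnd:
    def test_auc_degrades_monotonically_with_effect_size(self):
        """Strong signal → AUC ≥ 0.9; null → AUC ≈ 0.5; monotone between."""
        aucs = []
        ga = GAConfig(population_size=24, generations=30, seed=2,
                      hidden_size_range=(2, 8), fine_tune=True)
        for effect in (1.0, 0.4, 0.0):
            table = ox.generate_cohort(ox.CohortSpec(
                n_cases=120, n_controls_by_subgroup=(60, 120, 60),
                effect_size=effect, seed=13))
            model = ox.fit_diagnostic_model(table, seed=2, ga=ga)
            test = table.loc[model.split.test_ids]
            scores = model.predict(test)
            labels = (test["label"] == "case").astype(int)
            aucs.append(ox.roc_curve(scores, labels).auc)
        assert aucs[0] >= 0.9
        assert aucs[0] > aucs[1] > aucs[2]
        assert abs(aucs[2] - 0.5) < 0.12
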