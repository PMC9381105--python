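"""Quartile labelling, feature selection, cross-validation and enrichment tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphoresponse.ml import (
    EnrichmentResult,
    FeatureWeights,
    _fold_indices,
    assign_quartiles,
    cross_validate_predictor,
    elastic_net_weights,
    genomic_baseline,
    mutation_quartile_enrichment,
    rf_recursive_feature_selection,
)


class TestAssignQuartiles:
    def test_even_split(self):
        gi50 = pd.Series([1, 2, 3, 4, 5, 6, 7, 8.0], index=list("abcdefgh"))
        labels = assign_quartiles(gi50)
        assert list(labels) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_remainder_goes_to_early_quartiles(self):
        gi50 = pd.Series([1, 2, 3, 4, 5.0], index=list("abcde"))
        labels = assign_quartiles(gi50)
        assert list(labels) == ["Q1", "Q1", "Q2", "Q3", "Q4"]

    def test_all_equal_values_tie_broken_by_sample_id(self):
        gi50 = pd.Series([3.0] * 5, index=list("edcba"))
        labels = assign_quartiles(gi50)
        # stable sample-id order: a,b -> Q1; c -> Q2; d -> Q3; e -> Q4
        assert labels[["a", "b", "c", "d", "e"]].tolist() == ["Q1", "Q1", "Q2", "Q3", "Q4"]

    def test_direction_flag_reverses_labels(self):
        gi50 = pd.Series([1, 2, 3, 4.0], index=list("abcd"))
        asc = assign_quartiles(gi50, "ascending")
        desc = assign_quartiles(gi50, "descending")
        assert asc["a"] == "Q1" and desc["a"] == "Q4"

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=20, unique=True))
    def test_invariant_under_strictly_monotone_transform(self, values):
        gi50 = pd.Series(values, index=[f"s{i:02d}" for i in range(len(values))])
        transformed = gi50**3 + gi50  # strictly monotone, collision-free
        assert assign_quartiles(gi50).equals(assign_quartiles(transformed))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            assign_quartiles(pd.Series([1.0, 2.0, 3.0]))


def signal_data(n=60, p=20, planted=5, strength=2.0, seed=0):
    """Binary-ish 4-class labels driven by the first `planted` features."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i:02d}" for i in range(p)])
    score = strength * X.iloc[:, :planted].sum(axis=1) + rng.normal(size=n)
    y = assign_quartiles(pd.Series(score.values, index=X.index)).to_numpy()
    return X, y


class TestRecursiveFeatureSelection:
    def test_keep_all_is_identity(self):
        X, y = signal_data(n=40)
        assert rf_recursive_feature_selection(X, y, keep=20, n_estimators=20) == list(X.columns)

    def test_recovers_planted_features(self):
        X, y = signal_data(n=80, planted=5, strength=2.0, seed=1)
        selected = rf_recursive_feature_selection(X, y, keep=10, n_estimators=100, seed=1)
        planted = {f"f{i:02d}" for i in range(5)}
        assert len(planted & set(selected)) >= 3

    def test_deterministic_under_seed(self):
        X, y = signal_data(n=40, seed=2)
        a = rf_recursive_feature_selection(X, y, keep=5, n_estimators=30, seed=9)
        b = rf_recursive_feature_selection(X, y, keep=5, n_estimators=30, seed=9)
        assert a == b

    def test_constant_columns_flagged(self):
        X, y = signal_data(n=40, seed=3)
        X["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            rf_recursive_feature_selection(X, y, keep=5, n_estimators=20)

    def test_null_selection_frequency_is_uniform(self):
        """Pure-noise features: per-feature selection frequency over repeated
        draws stays inside a binomial interval around keep/p."""
        p, keep, reps = 12, 3, 40
        counts = pd.Series(0, index=[f"f{i:02d}" for i in range(p)])
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            X = pd.DataFrame(rng.normal(size=(40, p)), columns=counts.index)
            y = rng.choice(["Q1", "Q2", "Q3", "Q4"], size=40)
            for f in rf_recursive_feature_selection(X, y, keep=keep, n_estimators=25, seed=rep):
                counts[f] += 1
        expected = reps * keep / p
        se = np.sqrt(reps * (keep / p) * (1 - keep / p))
        assert ((counts - expected).abs() < 4.5 * se).all()


class TestCrossValidation:
    def test_separable_labels_reach_perfect_auc(self):
        rng = np.random.default_rng(0)
        y = np.repeat(["Q1", "Q2", "Q3", "Q4"], 10)
        X = pd.DataFrame({"sig": np.repeat([0.0, 1.0, 2.0, 3.0], 10) + rng.normal(0, 0.01, 40)})
        cv = cross_validate_predictor(X, y, "rf_classifier", n_folds=10,
                                      seed=0, n_estimators=50)
        assert cv.auc_pooled["Q1"] == pytest.approx(1.0)
        assert cv.auc_pooled["Q4"] == pytest.approx(1.0)

    def test_permuted_labels_give_chance_auc(self):
        X, y = signal_data(n=80, seed=4)
        rng = np.random.default_rng(4)
        cv = cross_validate_predictor(
            X, rng.permutation(y), "rf_classifier", n_folds=25, seed=4, n_estimators=50
        )
        for q in ("Q1", "Q4"):
            assert 0.35 < cv.auc_pooled[q] < 0.65

    def test_deterministic_under_seed(self):
        X, y = signal_data(n=48, seed=5)
        a = cross_validate_predictor(X, y, "rf_classifier", n_folds=5, seed=3, n_estimators=30)
        b = cross_validate_predictor(X, y, "rf_classifier", n_folds=5, seed=3, n_estimators=30)
        assert a.auc_pooled == b.auc_pooled
        assert a.selected_features == b.selected_features

    def test_auc_antisymmetry_under_score_negation(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 60)
        s = rng.normal(size=60)
        assert roc_auc_score(y, s) == pytest.approx(1.0 - roc_auc_score(y, -s))

    def test_feature_selection_ignores_holdout_rows(self):
        """No leakage: corrupting holdout rows/labels leaves the training-fold
        feature selection unchanged."""
        X, y = signal_data(n=60, seed=7)
        folds = _fold_indices(y, 5, 0.15, seed=7)
        train, test = folds[0]
        baseline = rf_recursive_feature_selection(
            X.iloc[train], y[train], keep=5, n_estimators=30, seed=7
        )
        X2 = X.copy()
        X2.iloc[test] = 1e6  # poison the holdout rows
        poisoned = rf_recursive_feature_selection(
            X2.iloc[train], y[train], keep=5, n_estimators=30, seed=7
        )
        assert baseline == poisoned

    def test_all_model_kinds_run(self):
        X, y = signal_data(n=48, seed=8)
        for kind in ("rf_classifier", "rf_regressor", "elastic_net"):
            cv = cross_validate_predictor(X, y, kind, n_folds=4, seed=1, n_estimators=25)
            assert set(cv.auc_pooled) == {"Q1", "Q2", "Q3", "Q4"}
            assert all(0 <= v <= 1 for v in cv.auc_pooled.values() if np.isfinite(v))

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame({"a": range(6)})
        with pytest.raises(ValueError, match=">= 10"):
            cross_validate_predictor(X, ["Q1", "Q2"] * 3)


class TestElasticNetWeights:
    def test_significance_flags_follow_threshold_rule(self):
        w = FeatureWeights(pd.Series({"a": 0.15, "b": -0.05, "c": -0.2, "d": 0.1}))
        assert w.significant.to_dict() == {"a": True, "b": False, "c": True, "d": False}

    def test_flags_match_rule_on_fitted_weights(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(100, 8)), columns=list("abcdefgh"))
        y = 2.0 * X["a"] - 1.0 * X["b"] + rng.normal(0, 0.1, 100)
        w = elastic_net_weights(X, y, alpha=0.05)
        assert w.significant.equals((w.weights.abs() > 0.1))
        assert w.significant["a"] and w.significant["b"]

    def test_null_weights_stay_below_threshold(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(200, 10)))
            y = rng.normal(size=200)
            w = elastic_net_weights(X, y, seed=seed)
            hits += int((w.weights.abs() < 0.1).all())
        assert hits >= 9

    def test_rank_zero_matrix_rejected(self):
        X = pd.DataFrame(np.ones((20, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            elastic_net_weights(X, np.arange(20.0))


class TestGenomicBaseline:
    def _inputs(self, n=24, seed=0, deterministic=False):
        rng = np.random.default_rng(seed)
        samples = [f"s{i:02d}" for i in range(n)]
        y = pd.Series(
            np.tile(["Q1", "Q2", "Q3", "Q4"], n // 4),
            index=pd.MultiIndex.from_tuples(
                [(s, "drugX") for s in samples], names=["sample", "drug"]
            ),
        )
        if deterministic:
            flags = {g: (y.droplevel("drug") == q).astype(int)
                     for g, q in zip(("EGFR", "KRAS", "PIK3CA"), ("Q1", "Q2", "Q3"))}
            genotypes = pd.DataFrame(flags)
        else:
            genotypes = pd.DataFrame(
                {g: rng.integers(0, 2, n) for g in ("EGFR", "KRAS", "PIK3CA")},
                index=samples,
            )
        return genotypes, y

    def test_independent_genotype_gives_chance_auc(self):
        genotypes, y = self._inputs(n=40, seed=1)
        cv = genomic_baseline(genotypes, y, n_folds=25, seed=1, n_estimators=50)
        for q in ("Q1", "Q4"):
            assert 0.3 < cv.auc_pooled[q] < 0.7

    def test_deterministic_genotype_gives_perfect_auc(self):
        genotypes, y = self._inputs(deterministic=True)
        cv = genomic_baseline(genotypes, y, n_folds=10, seed=0, n_estimators=50)
        assert cv.auc_pooled["Q1"] == pytest.approx(1.0)

    def test_missing_gene_column_rejected(self):
        genotypes, y = self._inputs()
        with pytest.raises(KeyError, match="PIK3CA"):
            genomic_baseline(genotypes.drop(columns="PIK3CA"), y)


class TestMutationEnrichment:
    def test_perfect_association_chi_square(self):
        """[[10,0],[0,10]]: all expected counts 5, Yates gives 4*(4.5^2/5) = 16.2."""
        mutation = pd.Series([1] * 10 + [0] * 10)
        quartile = pd.Series(["Q1"] * 10 + ["Q4"] * 10)
        res = mutation_quartile_enrichment(mutation, quartile)
        assert res.table.tolist() == [[10, 0], [0, 10]]
        assert res.chi2 == pytest.approx(16.2)

    def test_no_association_gives_p_one(self):
        mutation = pd.Series(([1] * 5 + [0] * 5) * 2)
        quartile = pd.Series(["Q1"] * 10 + ["Q4"] * 10)
        res = mutation_quartile_enrichment(mutation, quartile)
        assert res.table.tolist() == [[5, 5], [5, 5]]
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_warns_and_returns_one(self):
        mutation = pd.Series([0] * 10)
        quartile = pd.Series(["Q1"] * 5 + ["Q4"] * 5)
        with pytest.warns(UserWarning, match="margin"):
            res = mutation_quartile_enrichment(mutation, quartile)
        assert res.p_value == 1.0
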