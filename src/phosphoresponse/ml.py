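"""Drug-sensitivity quartile labelling and machine-learning predictors.

Per drug, samples are split into four near-equal sensitivity quartiles of
their GI50 (Q1 = most sensitive by this package's convention).  Predictors
are trained on the acute phosphoprotein changes:

* random-forest recursive feature selection (drop the lowest-importance
  fraction per round until a target count remains);
* random-forest classifiers/regressors and one-vs-rest elastic-net models;
* Monte-Carlo cross-validation — repeated random stratified 85/15
  train/validation splits (default 100), feature selection strictly inside
  each training split — reporting one-vs-rest ROC AUC per quartile from the
  pooled out-of-fold predictions (per-fold mean +/- SD alongside);
* the genomic baseline runs the identical protocol on three binary mutation
  flags (EGFR, KRAS, PIK3CA).

Elastic-net coefficients are fitted on standardized features and flagged
significant when the weight exceeds +0.1 or falls below -0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler

from .core import CELL_LINE
from .synergy import quartile_sizes

__all__ = [
    "QUARTILES",
    "SensitivityTable",
    "CVResult",
    "FeatureWeights",
    "assign_quartiles",
    "rf_recursive_feature_selection",
    "cross_validate_predictor",
    "elastic_net_weights",
    "genomic_baseline",
    "mutation_quartile_enrichment",
    "EnrichmentResult",
]

QUARTILES = ("Q1", "Q2", "Q3", "Q4")
GENES = ("EGFR", "KRAS", "PIK3CA")


def assign_quartiles(gi50: pd.Series, direction: str = "ascending") -> pd.Series:
    """Quartile labels for one drug's GI50 values across samples.

    Samples are sorted ascending by GI50 (ties broken by stable sample-id
    order) and split into four contiguous near-equal groups, remainders
    going to the earlier quartiles.  With the default direction Q1 holds the
    lowest GI50s, i.e. the most sensitive samples; ``direction="descending"``
    reverses the labelling.
    """
    values = gi50.dropna()
    if len(values) < 4:
        raise ValueError(f"need >= 4 samples with finite GI50, got {len(values)}")
    if direction not in ("ascending", "descending"):
        raise ValueError(f"unknown direction {direction!r}")
    order = values.sort_index().sort_values(kind="mergesort").index
    sizes = quartile_sizes(len(order))
    labels = QUARTILES if direction == "ascending" else QUARTILES[::-1]
    out = pd.Series(index=values.index, dtype=object)
    start = 0
    for label, size in zip(labels, sizes):
        out[order[start : start + size]] = label
        start += size
    return out.reindex(gi50.index)


@dataclass
class SensitivityTable:
    """GI50 values (molar) and derived quartile labels, samples x drugs."""

    gi50: pd.DataFrame
    quartile: pd.DataFrame

    @classmethod
    def from_gi50(cls, gi50: pd.DataFrame, direction: str = "ascending") -> "SensitivityTable":
        quartile = pd.DataFrame(
            {drug: assign_quartiles(gi50[drug], direction) for drug in gi50.columns}
        )
        return cls(gi50=gi50, quartile=quartile)

    def labels_long(self) -> pd.Series:
        """Quartile labels indexed by (sample, drug), NaN rows dropped."""
        long = self.quartile.stack()
        long.index = long.index.set_names(["sample", "drug"])
        return long


def rf_recursive_feature_selection(
    X: pd.DataFrame,
    y: Sequence,
    keep: int,
    step: float = 0.2,
    n_estimators: int = 500,
    seed: int = 0,
) -> list[str]:
    """Random-forest recursive feature elimination down to ``keep`` features.

    Each round fits a random forest on the surviving features and drops the
    ``step`` fraction with the lowest impurity-decrease importance (at least
    one, never past ``keep``).  Constant feature columns are retained in the
    candidate set but reported with a warning.  Deterministic for a fixed
    seed.
    """
    if keep > X.shape[1]:
        raise ValueError(f"keep={keep} exceeds the {X.shape[1]} available features")
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant feature columns: {constant}", stacklevel=2)
    features = list(X.columns)
    y = np.asarray(y)
    round_idx = 0
    while len(features) > keep:
        rf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed + round_idx, n_jobs=1
        )
        rf.fit(X[features].to_numpy(), y)
        importance = pd.Series(rf.feature_importances_, index=features)
        n_drop = min(max(1, int(len(features) * step)), len(features) - keep)
        # stable tie-break: low importance first, then reverse column order
        order = importance.sort_index(ascending=False).sort_values(kind="mergesort")
        drop = set(order.index[:n_drop])
        features = [f for f in features if f not in drop]
        round_idx += 1
    return features


@dataclass
class CVResult:
    """Monte-Carlo cross-validation outcome.

    ``auc_pooled`` holds the headline one-vs-rest AUC per quartile computed
    from pooled out-of-fold predictions; ``auc_fold_mean``/``auc_fold_sd``
    aggregate the per-fold AUCs; ``n_skipped`` counts folds whose holdout
    lacked the class.
    """

    auc_pooled: dict[str, float]
    auc_fold_mean: dict[str, float]
    auc_fold_sd: dict[str, float]
    n_skipped: dict[str, int]
    selected_features: list[list[str]]
    n_folds: int
    split_fraction: float
    model_kind: str

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "n_folds": self.n_folds,
            "split_fraction": self.split_fraction,
            "auc_pooled": self.auc_pooled,
            "auc_fold_mean": self.auc_fold_mean,
            "auc_fold_sd": self.auc_fold_sd,
            "n_skipped": self.n_skipped,
        }


def _fold_indices(
    y: np.ndarray, n_folds: int, holdout: float, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random stratified train/holdout splits (the rotating 85/15 design)."""
    splitter = StratifiedShuffleSplit(
        n_splits=n_folds, test_size=holdout, random_state=seed
    )
    return list(splitter.split(np.zeros((len(y), 1)), y))


def _class_scores(model_kind, model, X_test, classes, codes=None):
    """Per-class decision scores for one fitted model on held-out rows."""
    if model_kind == "rf_classifier":
        proba = model.predict_proba(X_test)
        return {c: proba[:, i] for i, c in enumerate(model.classes_)}
    if model_kind == "rf_regressor":
        pred = model.predict(X_test)
        return {c: -np.abs(pred - codes[c]) for c in classes}
    raise AssertionError(model_kind)


def cross_validate_predictor(
    X: pd.DataFrame,
    y: Sequence,
    model_kind: Literal["rf_classifier", "rf_regressor", "elastic_net"] = "rf_classifier",
    n_folds: int = 100,
    holdout: float = 0.15,
    seed: int = 0,
    select: int | None = None,
    rfe_step: float = 0.2,
    n_estimators: int = 500,
    rfe_estimators: int | None = None,
    l1_ratio: float = 0.5,
    enet_alpha: float = 0.1,
) -> CVResult:
    """Monte-Carlo cross-validation of a quartile predictor.

    Runs ``n_folds`` random stratified ``1 - holdout``/``holdout`` splits.
    When ``select`` is set, random-forest recursive feature selection runs
    *inside each training split* (no leakage) before the model fit.  The
    elastic-net model fits one-vs-rest regressions on standardized features
    at a fixed penalty; random forests use impurity-decrease importances.
    """
    y = np.asarray(y)
    if len(y) < 10:
        raise ValueError(f"need >= 10 labelled rows, got {len(y)}")
    if X.shape[0] != len(y):
        raise ValueError("X rows must align with y")
    classes = sorted(set(y))
    codes = {c: i + 1 for i, c in enumerate(classes)}

    pooled_true: dict[str, list] = {c: [] for c in classes}
    pooled_score: dict[str, list] = {c: [] for c in classes}
    fold_aucs: dict[str, list] = {c: [] for c in classes}
    n_skipped = {c: 0 for c in classes}
    selected_features: list[list[str]] = []

    Xv = X.to_numpy()
    for fold, (train, test) in enumerate(_fold_indices(y, n_folds, holdout, seed)):
        fold_seed = seed + 1009 * (fold + 1)
        if select is not None:
            feats = rf_recursive_feature_selection(
                X.iloc[train], y[train], keep=select, step=rfe_step,
                n_estimators=rfe_estimators or n_estimators, seed=fold_seed,
            )
            cols = [X.columns.get_loc(f) for f in feats]
        else:
            feats = list(X.columns)
            cols = list(range(X.shape[1]))
        selected_features.append(feats)
        X_train, X_test = Xv[np.ix_(train, cols)], Xv[np.ix_(test, cols)]
        y_train, y_test = y[train], y[test]

        if model_kind == "rf_classifier":
            model = RandomForestClassifier(
                n_estimators=n_estimators, random_state=fold_seed, n_jobs=1
            ).fit(X_train, y_train)
            scores = _class_scores(model_kind, model, X_test, classes)
        elif model_kind == "rf_regressor":
            model = RandomForestRegressor(
                n_estimators=n_estimators, random_state=fold_seed, n_jobs=1
            ).fit(X_train, np.vectorize(codes.get)(y_train))
            scores = _class_scores(model_kind, model, X_test, classes, codes)
        elif model_kind == "elastic_net":
            scaler = StandardScaler().fit(X_train)
            Xs_train, Xs_test = scaler.transform(X_train), scaler.transform(X_test)
            scores = {}
            for c in classes:
                enet = ElasticNet(
                    alpha=enet_alpha, l1_ratio=l1_ratio, random_state=fold_seed
                ).fit(Xs_train, (y_train == c).astype(float))
                scores[c] = enet.predict(Xs_test)
        else:
            raise ValueError(f"unknown model_kind {model_kind!r}")

        for c in classes:
            binary = (y_test == c).astype(int)
            if c not in scores or binary.min() == binary.max():
                n_skipped[c] += 1
                continue
            pooled_true[c].extend(binary)
            pooled_score[c].extend(scores[c])
            fold_aucs[c].append(roc_auc_score(binary, scores[c]))

    auc_pooled, auc_mean, auc_sd = {}, {}, {}
    for c in classes:
        if pooled_true[c]:
            auc_pooled[c] = float(roc_auc_score(pooled_true[c], pooled_score[c]))
            auc_mean[c] = float(np.mean(fold_aucs[c]))
            auc_sd[c] = float(np.std(fold_aucs[c], ddof=1)) if len(fold_aucs[c]) > 1 else 0.0
        else:
            auc_pooled[c] = auc_mean[c] = auc_sd[c] = float("nan")
    return CVResult(
        auc_pooled=auc_pooled,
        auc_fold_mean=auc_mean,
        auc_fold_sd=auc_sd,
        n_skipped=n_skipped,
        selected_features=selected_features,
        n_folds=n_folds,
        split_fraction=holdout,
        model_kind=model_kind,
    )


@dataclass
class FeatureWeights:
    """Elastic-net coefficients (standardized scale) with the +/-0.1 rule."""

    weights: pd.Series
    threshold: float = 0.1

    @property
    def significant(self) -> pd.Series:
        return (self.weights > self.threshold) | (self.weights < -self.threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"weight": self.weights, "significant": self.significant}
        ).rename_axis("analyte")


def elastic_net_weights(
    X: pd.DataFrame,
    y: Sequence[float],
    l1_ratio: float = 0.5,
    alpha: float | None = None,
    threshold: float = 0.1,
    seed: int = 0,
) -> FeatureWeights:
    """Elastic-net coefficients of a response on standardized features.

    ``y`` is any numeric encoding of the response (e.g. a one-vs-rest
    quartile indicator).  Features are standardized to zero mean and unit
    variance before the fit so the +/-0.1 significance rule is
    scale-meaningful; when ``alpha`` is None the penalty is chosen by
    internal cross-validation.
    """
    values = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(values - values.mean(axis=0)) == 0:
        raise ValueError("degenerate feature matrix (rank 0 after centering)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns scale to 0
        Xs = StandardScaler().fit_transform(values)
    y = np.asarray(y, dtype=float)
    if alpha is None:
        model = ElasticNetCV(l1_ratio=l1_ratio, cv=5, random_state=seed).fit(Xs, y)
    else:
        model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, random_state=seed).fit(Xs, y)
    weights = pd.Series(model.coef_, index=X.columns)
    return FeatureWeights(weights=weights, threshold=threshold)


def genomic_baseline(
    genotypes: pd.DataFrame,
    y: pd.Series,
    genes: Sequence[str] = GENES,
    **cv_kwargs,
) -> CVResult:
    """The mutation-only comparison model under the identical CV protocol.

    ``genotypes`` is samples x genes with binary flags; ``y`` is the
    quartile label indexed by (sample, drug).  Each (sample, drug) row
    inherits the sample's three mutation flags as its features.
    """
    missing = [g for g in genes if g not in genotypes.columns]
    if missing:
        raise KeyError(f"genotype table is missing gene columns: {missing}")
    bad = genotypes[list(genes)].isin([0, 1]).all()
    if not bad.all():
        raise ValueError("genotype flags must be binary 0/1")
    samples = y.index.get_level_values("sample")
    absent = sorted(set(samples) - set(genotypes.index))
    if absent:
        raise KeyError(f"samples missing from genotype table: {absent}")
    X = genotypes.loc[samples, list(genes)].set_axis(y.index)
    return cross_validate_predictor(X, y.to_numpy(), **cv_kwargs)


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 mutation-by-sensitivity contingency with Yates-corrected chi-square."""

    table: np.ndarray  # rows: mutated / wild-type; cols: Q1+Q2 / Q3+Q4
    chi2: float
    p_value: float


def mutation_quartile_enrichment(
    mutation: pd.Series, quartile: pd.Series
) -> EnrichmentResult:
    """Test enrichment of mutants among sensitive quartiles for one gene/drug.

    Builds the 2x2 table (mutated vs wild-type) x (Q1 or Q2 vs Q3 or Q4) and
    applies the chi-square test with Yates continuity correction
    (1 degree of freedom, continuity term clipped at 0 when |O - E| < 0.5).
    A table with any zero margin is degenerate: p = 1 with a warning.
    """
    joined = pd.concat({"mut": mutation, "quartile": quartile}, axis=1).dropna()
    sensitive = joined["quartile"].isin(["Q1", "Q2"])
    mutated = joined["mut"].astype(int) == 1
    table = np.array(
        [
            [int((mutated & sensitive).sum()), int((mutated & ~sensitive).sum())],
            [int((~mutated & sensitive).sum()), int((~mutated & ~sensitive).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("zero margin in contingency table; p set to 1", stacklevel=2)
        return EnrichmentResult(table=table, chi2=0.0, p_value=1.0)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return EnrichmentResult(table=table, chi2=float(chi2), p_value=float(p))
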