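"""Statistical validation of EPS against measured synergy, and cohort comparison.

The rank-bias test asks whether combinations in the *top* quartile of Bliss
synergy scores have their partner-drug targets placed at better (lower)
EPS ranks than combinations in the *bottom* quartile — a Mann-Whitney U
comparison of two rank multisets.  Its robustness is probed by re-running
the test under random re-assignments of the EPS rankings (default 10,000
permutations, shuffled within each (sample, drug) ranking universe so the
rank support is preserved) and locating the observed p-value in that null.

Cohort comparison (cell lines vs patient-derived samples) uses PCA of the
condition x analyte change matrix, per-cohort kernel-density curves of the
pooled changes, and a Welch two-sample t-test on the pooled values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .core import CELL_LINE, PATIENT, PerturbationMatrix
from .eps import EPSTable, InteractionNetwork
from .synergy import synergy_quartiles

__all__ = [
    "RankBiasResult",
    "PermutationNull",
    "CohortComparison",
    "mann_whitney_rank_bias",
    "rank_bias_groups",
    "permutation_robustness",
    "cohort_compare",
    "hierarchical_cluster",
]

EXACT_MAX_N = 8


def _normal_approx_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney p, tie-corrected normal approximation with continuity.

    Matches scipy's asymptotic method; kept as a lean local routine so the
    permutation loop avoids per-call overhead.
    """
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    u = max(u1, n1 * n2 - u1)
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    sigma_sq = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma_sq <= 0:  # all values tied
        return float(u1), 1.0
    z = (u - n1 * n2 / 2.0 - 0.5) / np.sqrt(sigma_sq)
    return float(u1), float(min(1.0, 2.0 * stats.norm.sf(z)))


@dataclass
class RankBiasResult:
    """Mann-Whitney comparison of EPS ranks between Bliss quartile extremes.

    ``u`` is the U statistic of the top-quartile group;
    ``rank_biserial = 1 - 2U/(n1*n2)`` is positive when the top-synergy
    group sits at better (numerically lower) EPS ranks, the direction the
    method predicts.
    """

    ranks_top: np.ndarray
    ranks_bottom: np.ndarray
    u: float
    p_two_sided: float
    method: str

    @property
    def rank_biserial(self) -> float:
        n1, n2 = len(self.ranks_top), len(self.ranks_bottom)
        return 1.0 - 2.0 * self.u / (n1 * n2)

    @property
    def bias_toward_top(self) -> bool:
        return self.rank_biserial > 0


def mann_whitney_rank_bias(
    ranks_top: Sequence[float], ranks_bottom: Sequence[float]
) -> RankBiasResult:
    """Two-sided Mann-Whitney U test on two EPS-rank multisets.

    Uses exact enumeration when both groups have <= 8 untied observations
    and the tie-corrected normal approximation (with continuity correction)
    otherwise.
    """
    x = np.asarray(ranks_top, dtype=float)
    y = np.asarray(ranks_bottom, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both rank groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if max(len(x), len(y)) <= EXACT_MAX_N and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return RankBiasResult(x, y, float(res.statistic), float(res.pvalue), "exact")
    u1, p = _normal_approx_p(x, y)
    return RankBiasResult(x, y, u1, p, "normal_approximation")


def rank_bias_groups(
    eps_table: EPSTable,
    bliss_summary: pd.DataFrame,
    drug_targets: Mapping[str, Sequence[str]],
    network: InteractionNetwork,
    mode: str = "best",
) -> tuple[np.ndarray, np.ndarray]:
    """EPS-rank groups for the top and bottom Bliss quartiles.

    For each record (sample, anchor, partner) in an extreme quartile, the
    group receives the partner's best target-entity rank in the anchor's
    ranking (``mode="best"``, default) or all of its target-entity ranks
    (``mode="all"``).  Records whose partner has no ranked target are
    dropped with a warning.
    """
    if mode not in ("best", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    entity_node = dict(network.entities())
    target_entities = {
        drug: [e for e, node in entity_node.items() if node in set(targets)]
        for drug, targets in drug_targets.items()
    }
    top, bottom = synergy_quartiles(bliss_summary)
    groups = []
    for records in (top, bottom):
        ranks: list[float] = []
        dropped = 0
        for sample, anchor, partner in records[["sample", "drug_a", "drug_b"]].itertuples(
            index=False
        ):
            sel = eps_table.ranking(sample, anchor)
            r = sel.loc[sel["entity"].isin(target_entities[partner]), "rank"].dropna()
            if r.empty:
                dropped += 1
                continue
            if mode == "best":
                ranks.append(float(r.min()))
            else:
                ranks.extend(float(v) for v in r)
        if dropped:
            warnings.warn(f"{dropped} records without a ranked target dropped", stacklevel=2)
        groups.append(np.asarray(ranks))
    return groups[0], groups[1]


@dataclass
class PermutationNull:
    """Null distribution of the rank-bias p under shuffled EPS rankings."""

    n_permutations: int
    permuted_p_values: np.ndarray
    observed_p: float
    scheme: str

    @property
    def empirical_quantile(self) -> float:
        """Mid-quantile of the observed p in the permutation null."""
        below = (self.permuted_p_values < self.observed_p).sum()
        equal = (self.permuted_p_values == self.observed_p).sum()
        return float((below + 0.5 * equal) / self.n_permutations)


def permutation_robustness(
    eps_table: EPSTable,
    bliss_summary: pd.DataFrame,
    drug_targets: Mapping[str, Sequence[str]],
    network: InteractionNetwork,
    n: int = 10_000,
    seed: int = 0,
    scheme: str = "within",
    mode: str = "best",
) -> PermutationNull:
    """Re-run the rank-bias test under ``n`` random EPS-rank re-assignments.

    ``scheme="within"`` (default) shuffles the rank values among the
    tractable entities separately within each (sample, drug) ranking
    universe, preserving each universe's rank support; ``scheme="global"``
    shuffles rank values across all universes at once.  The observed
    pairing's p-value is located in the resulting null (mid-quantile).
    """
    if scheme not in ("within", "global"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if n < 100:
        warnings.warn(f"n={n} permutations gives an unstable quantile", stacklevel=2)
    rng = np.random.default_rng(seed)

    entity_node = dict(network.entities())
    target_entities = {
        drug: [e for e, node in entity_node.items() if node in set(targets)]
        for drug, targets in drug_targets.items()
    }
    top, bottom = synergy_quartiles(bliss_summary)

    # Pre-index every ranking universe: an array of rank values over its
    # tractable entities, plus per record the entity positions to minimize over.
    universes: dict[tuple[str, str], dict] = {}
    records: list[tuple[int, tuple[str, str], np.ndarray]] = []  # (group, key, positions)
    for group, table in ((0, top), (1, bottom)):
        for sample, anchor, partner in table[["sample", "drug_a", "drug_b"]].itertuples(
            index=False
        ):
            key = (sample, anchor)
            if key not in universes:
                sel = eps_table.ranking(sample, anchor)
                ranked = sel.dropna(subset=["rank"]).reset_index(drop=True)
                universes[key] = {
                    "ranks": ranked["rank"].to_numpy(dtype=float),
                    "pos": {e: i for i, e in enumerate(ranked["entity"])},
                }
            pos = universes[key]["pos"]
            idx = np.array(
                [pos[e] for e in target_entities[partner] if e in pos], dtype=int
            )
            if idx.size:
                records.append((group, key, idx))

    def groups_from(ranks_by_key: Mapping[tuple[str, str], np.ndarray]):
        tops, bottoms = [], []
        for group, key, idx in records:
            best = float(ranks_by_key[key][idx].min())
            (tops if group == 0 else bottoms).append(best)
        return np.asarray(tops), np.asarray(bottoms)

    observed = {k: u["ranks"] for k, u in universes.items()}
    obs_top, obs_bottom = groups_from(observed)
    if len(obs_top) == 0 or len(obs_bottom) == 0:
        raise ValueError("rank bias is not observable: an extreme quartile is empty")
    _, observed_p = _normal_approx_p(obs_top, obs_bottom)

    keys = list(universes)
    all_ranks = np.concatenate([universes[k]["ranks"] for k in keys])
    splits = np.cumsum([len(universes[k]["ranks"]) for k in keys])[:-1]
    null_p = np.empty(n)
    for i in range(n):
        if scheme == "within":
            permuted = {k: rng.permutation(universes[k]["ranks"]) for k in keys}
        else:
            shuffled = np.split(rng.permutation(all_ranks), splits)
            permuted = dict(zip(keys, shuffled))
        t, b = groups_from(permuted)
        _, null_p[i] = _normal_approx_p(t, b)
    return PermutationNull(
        n_permutations=n, permuted_p_values=null_p, observed_p=observed_p, scheme=scheme
    )


@dataclass
class CohortComparison:
    """PCA, density curves and Welch test comparing cell lines vs patients."""

    pca_coords: pd.DataFrame  # (sample, drug) x [PC1..PC3, sample_type]
    explained_variance_ratio: np.ndarray
    density: dict[str, tuple[np.ndarray, np.ndarray]]  # cohort -> (grid, density)
    welch_t: float | None
    welch_p: float | None


def cohort_compare(matrix: PerturbationMatrix, n_components: int = 3) -> CohortComparison:
    """Compare the cell-line and patient cohorts of a perturbation matrix.

    PCA is run on the per-analyte-centered (condition x analyte) change
    matrix; density curves use a Gaussian KDE (Silverman bandwidth) of each
    cohort's pooled change values; the Welch two-sample t-test compares the
    pooled values.  With a single cohort the Welch test is skipped with a
    warning.
    """
    data = matrix.data
    n_components = min(n_components, min(data.shape) - 1) or 1
    pca = PCA(n_components=n_components, random_state=0)
    coords = pca.fit_transform(data - data.mean(axis=0))
    pca_coords = pd.DataFrame(
        coords, index=data.index, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
    )
    types = pd.Series(
        [matrix.sample_type[s] for s in data.index.get_level_values("sample")],
        index=data.index,
    )
    pca_coords["sample_type"] = types

    pooled = {
        cohort: data.loc[types == cohort].to_numpy().ravel()
        for cohort in sorted(set(types))
    }
    density = {}
    for cohort, values in pooled.items():
        if len(np.unique(values)) > 1:
            kde = stats.gaussian_kde(values, bw_method="silverman")
            grid = np.linspace(values.min(), values.max(), 256)
            density[cohort] = (grid, kde(grid))
        else:
            density[cohort] = (np.array([values[0]]), np.array([np.inf]))

    if CELL_LINE in pooled and PATIENT in pooled:
        t, p = stats.ttest_ind(pooled[CELL_LINE], pooled[PATIENT], equal_var=False)
        welch_t, welch_p = float(t), float(p)
    else:
        warnings.warn("single-cohort matrix: Welch test skipped", stacklevel=2)
        welch_t = welch_p = None
    return CohortComparison(
        pca_coords=pca_coords,
        explained_variance_ratio=pca.explained_variance_ratio_,
        density=density,
        welch_t=welch_t,
        welch_p=welch_p,
    )


def hierarchical_cluster(
    matrix: PerturbationMatrix,
    axis: str = "analytes",
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[np.ndarray, list]:
    """Agglomerative clustering of analytes or conditions by change vectors.

    Returns the scipy linkage matrix and the deterministic leaf order
    (labels).  Average linkage on Euclidean distances by default.
    """
    if axis == "analytes":
        data = matrix.data.T
    elif axis == "conditions":
        data = matrix.data
    else:
        raise ValueError(f"axis must be 'analytes' or 'conditions', got {axis!r}")
    linkage = hierarchy.linkage(data.to_numpy(), method=method, metric=metric)
    leaves = hierarchy.leaves_list(linkage)
    return linkage, [data.index[i] for i in leaves]
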