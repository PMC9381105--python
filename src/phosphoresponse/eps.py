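"""Environmental perturbation score (EPS) over a protein-protein interaction network.

EPS integrates the absolute phosphoprotein changes measured in a node's
*neighborhood*: for a node ``v`` with direct neighbors ``N(v)`` (self
excluded),

    EPS(v) = sum over analytes a mapped to nodes in N(v) of |change(a)|.

A node can therefore score highly as a signalling junction even if its own
perturbation is small or unmeasured.  Proteins carrying several measured
phosphosites (e.g. AKT1_T308 and AKT1_S473) are ranked as separate
site-level entities; by default both inherit the protein node's neighborhood
sum, optionally plus a per-site self term ``self_weight * |change(site)|``.

Only entities on *tractable* (druggable) nodes enter the per-condition
ranking; rank 1 is the highest EPS, ties share the minimum rank of the tied
block, and the block is ordered by entity id for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import DrugInfo, PerturbationMatrix, PerturbationProfile

__all__ = [
    "InteractionNetwork",
    "EPSTable",
    "UnmappedAnalyteError",
    "eps_score",
    "rank_tractable",
    "compute_eps_table",
    "nominate_combinations",
    "topk_concordance",
    "ConcordanceResult",
    "read_network",
    "write_network",
]


class UnmappedAnalyteError(KeyError):
    """A profile carries analytes with no node in the network."""


@dataclass
class InteractionNetwork:
    """Undirected PPI graph with tractability flags and an analyte->node map."""

    graph: nx.Graph
    tractable: dict[str, bool]
    analyte_map: dict[str, str]

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"network must be a simple graph; self-loops: {loops}")
        nodes = set(self.graph.nodes)
        orphan = {a: n for a, n in self.analyte_map.items() if n not in nodes}
        if orphan:
            raise ValueError(f"analyte_map targets nodes absent from the graph: {orphan}")
        self.tractable = {n: bool(self.tractable.get(n, False)) for n in nodes}

    @property
    def node_analytes(self) -> dict[str, list[str]]:
        """Analytes measured on each node (sorted for determinism)."""
        out: dict[str, list[str]] = {}
        for analyte, node in sorted(self.analyte_map.items()):
            out.setdefault(node, []).append(analyte)
        return out

    def entities(self) -> list[tuple[str, str]]:
        """Scored entities as (entity_id, node_id) pairs.

        A node with >= 2 mapped analytes contributes one entity per
        phosphosite analyte; every other node contributes itself.
        """
        multi = {n: a for n, a in self.node_analytes.items() if len(a) >= 2}
        out: list[tuple[str, str]] = []
        for node in sorted(self.graph.nodes):
            if node in multi:
                out.extend((analyte, node) for analyte in multi[node])
            else:
                out.append((node, node))
        return out

    def drug_target_entities(self, drug: DrugInfo) -> list[str]:
        """Entity ids belonging to a drug's target nodes."""
        return [e for e, node in self.entities() if node in drug.target_node_ids]


def eps_score(
    profile: PerturbationProfile,
    network: InteractionNetwork,
    self_weight: float = 0.0,
) -> pd.DataFrame:
    """EPS for every scored entity of the network, for one (sample, drug).

    Returns a DataFrame with columns ``entity, node, eps`` sorted by entity.
    Raises :class:`UnmappedAnalyteError` if the profile has analytes the
    network cannot place.
    """
    unmapped = sorted(set(profile.changes) - set(network.analyte_map))
    if unmapped:
        raise UnmappedAnalyteError(f"analytes without a network node: {unmapped}")

    node_abs: dict[str, float] = {}
    for analyte, change in profile.changes.items():
        node = network.analyte_map[analyte]
        node_abs[node] = node_abs.get(node, 0.0) + abs(change)

    neighborhood = {
        v: sum(node_abs.get(u, 0.0) for u in network.graph.neighbors(v))
        for v in network.graph.nodes
    }

    rows = []
    for entity, node in network.entities():
        eps = neighborhood[node]
        if entity != node and self_weight != 0.0:
            eps += self_weight * abs(profile.changes.get(entity, 0.0))
        rows.append((entity, node, eps))
    return pd.DataFrame(rows, columns=["entity", "node", "eps"])


def rank_tractable(scores: pd.DataFrame, tractable: Mapping[str, bool]) -> pd.Series:
    """Descending-EPS ranks over tractable entities.

    Ties take the minimum rank of the tied block; non-tractable entities are
    excluded from the ranking (NaN) but remain in the score table.
    """
    mask = scores["node"].map(lambda n: bool(tractable.get(n, False)))
    if not mask.any():
        raise ValueError("no tractable entity to rank")
    eps = scores.loc[mask].set_index("entity")["eps"].sort_index()
    ranks = eps.rank(method="min", ascending=False).astype(int)
    return ranks.reindex(scores["entity"]).set_axis(scores.index)


@dataclass
class EPSTable:
    """Long table of EPS values and tractable ranks per (sample, drug, entity)."""

    table: pd.DataFrame  # columns: sample, drug, entity, node, eps, rank

    def ranking(self, sample: str, drug: str) -> pd.DataFrame:
        sel = self.table[(self.table["sample"] == sample) & (self.table["drug"] == drug)]
        if sel.empty:
            raise KeyError(f"no EPS rows for ({sample}, {drug})")
        return sel

    def best_target_rank(
        self, sample: str, anchor_drug: str, target_entities: Sequence[str]
    ) -> float:
        """Minimum rank achieved by any of the given entities in the anchor's ranking."""
        sel = self.ranking(sample, anchor_drug)
        ranks = sel.loc[sel["entity"].isin(target_entities), "rank"].dropna()
        if ranks.empty:
            return float("nan")
        return float(ranks.min())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def compute_eps_table(
    matrix: PerturbationMatrix,
    network: InteractionNetwork,
    self_weight: float = 0.0,
) -> EPSTable:
    """EPS scores and tractable ranks for every profile in the matrix."""
    frames = []
    for profile in matrix.profiles():
        scores = eps_score(profile, network, self_weight=self_weight)
        scores.insert(0, "drug", profile.drug_id)
        scores.insert(0, "sample", profile.sample_id)
        scores["rank"] = rank_tractable(scores, network.tractable)
        frames.append(scores)
    return EPSTable(pd.concat(frames, ignore_index=True))


def nominate_combinations(
    eps_table: EPSTable,
    drugs: Sequence[DrugInfo],
    network: InteractionNetwork,
    k: int = 5,
) -> pd.DataFrame:
    """Rank candidate partner drugs for each (sample, anchor drug).

    A partner is scored by the best (minimum) EPS rank among its target
    entities in the anchor's ranking; the top ``k`` partners are returned
    with the achieving target entity.  Partners with no ranked target are
    excluded with a warning.
    """
    by_id = {d.drug_id: d for d in drugs}
    rows = []
    conditions = eps_table.table[["sample", "drug"]].drop_duplicates()
    for sample, anchor in conditions.itertuples(index=False):
        if anchor not in by_id:
            continue
        ranking = eps_table.ranking(sample, anchor).set_index("entity")["rank"]
        partners = []
        for partner_id, partner in by_id.items():
            if partner_id == anchor:
                continue
            targets = network.drug_target_entities(partner)
            ranks = ranking.reindex(targets).dropna()
            if ranks.empty:
                warnings.warn(
                    f"partner {partner_id} has no ranked target entity for "
                    f"({sample}, {anchor}); excluded",
                    stacklevel=2,
                )
                continue
            best_entity = ranks.idxmin()
            partners.append((partner_id, float(ranks.min()), best_entity))
        partners.sort(key=lambda t: (t[1], t[0]))
        for order, (partner_id, rank, entity) in enumerate(partners[:k], start=1):
            rows.append((sample, anchor, order, partner_id, entity, rank))
    return pd.DataFrame(
        rows,
        columns=["sample", "anchor", "order", "partner", "target_entity", "rank"],
    )


@dataclass(frozen=True)
class ConcordanceResult:
    """Top-k concordance between EPS rankings and synergistic combinations."""

    n_synergistic: int
    n_hit: int
    k: int
    bliss_threshold: float

    @property
    def fraction(self) -> float | None:
        """Hit fraction; ``None`` when no combination cleared the threshold."""
        if self.n_synergistic == 0:
            return None
        return self.n_hit / self.n_synergistic

    @property
    def percent(self) -> float | None:
        """Hit fraction as a rounded percentage (as customarily reported)."""
        if self.fraction is None:
            return None
        return round(100.0 * self.fraction)


def topk_concordance(
    eps_table: EPSTable,
    bliss_summary: pd.DataFrame,
    drug_targets: Mapping[str, Sequence[str]],
    network: InteractionNetwork,
    bliss_threshold: float = 0.1,
    k: int = 5,
) -> ConcordanceResult:
    """How often EPS places a synergistic partner's target in the anchor's top k.

    ``bliss_summary`` has columns ``sample, drug_a, drug_b, bliss`` (ordered
    pairs, ``drug_a`` is the anchor).  Over records with ``bliss >
    bliss_threshold``, a record is a hit when some target entity of the
    partner ``drug_b`` has rank <= ``k`` in the anchor's EPS ranking.
    """
    entity_node = dict(network.entities())
    target_entities = {
        drug: [e for e, node in entity_node.items() if node in set(targets)]
        for drug, targets in drug_targets.items()
    }
    synergistic = bliss_summary[bliss_summary["bliss"] > bliss_threshold]
    hits = 0
    for sample, anchor, partner in synergistic[["sample", "drug_a", "drug_b"]].itertuples(
        index=False
    ):
        best = eps_table.best_target_rank(sample, anchor, target_entities[partner])
        if np.isfinite(best) and best <= k:
            hits += 1
    return ConcordanceResult(
        n_synergistic=len(synergistic), n_hit=hits, k=k, bliss_threshold=bliss_threshold
    )


def write_network(network: InteractionNetwork, edge_path, tractable_path, map_path) -> None:
    """Write the SIF-like edge list plus node-attribute and analyte-map TSVs."""
    edges = pd.DataFrame(sorted(tuple(sorted(e)) for e in network.graph.edges))
    edges.to_csv(edge_path, sep="\t", index=False, header=False)
    pd.DataFrame(
        sorted(network.tractable.items()), columns=["node", "tractable"]
    ).to_csv(tractable_path, sep="\t", index=False)
    pd.DataFrame(
        sorted(network.analyte_map.items()), columns=["analyte", "node"]
    ).to_csv(map_path, sep="\t", index=False)


def read_network(edge_path, tractable_path, map_path) -> InteractionNetwork:
    """Read a network from the 2-column edge list and its two attribute TSVs."""
    edges = pd.read_csv(edge_path, sep="\t", header=None, names=["a", "b"], dtype=str)
    graph = nx.Graph()
    graph.add_edges_from(edges.itertuples(index=False))
    flags = pd.read_csv(tractable_path, sep="\t", dtype={"node": str})
    tractable = dict(zip(flags["node"], flags["tractable"].astype(bool)))
    graph.add_nodes_from(tractable)  # keep degree-0 tractable nodes
    amap = pd.read_csv(map_path, sep="\t", dtype=str)
    analyte_map = dict(zip(amap["analyte"], amap["node"]))
    return InteractionNetwork(graph=graph, tractable=tractable, analyte_map=analyte_map)
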