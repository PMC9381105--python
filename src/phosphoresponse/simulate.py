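"""Synthetic cohort generator with the statistical structure the analysis assumes.

The generator emulates the study design end to end so every downstream
stage is testable without any external download:

* a connected protein-protein interaction network with tractability flags,
  drug-target nodes, and an analyte->node map in which one protein (AKT1)
  carries two phosphosite analytes;
* acute perturbation profiles: drug inhibition propagates from the target
  node over the network, the mean change at an analyte of a node at graph
  distance d from the target being ``-effect_size * 0.5**d`` (zero beyond
  distance 2), with optional feedback up-regulation at a configured number
  of distant analytes and Gaussian measurement noise (inflated for
  patient-derived samples);
* GI50 values: log10(GI50) is a linear combination of the sample's
  *observed* signature-analyte changes plus Gaussian noise, so sensitivity
  is learnable from the measured profiles and the noiseless linear score
  defines the ground-truth quartile;
* decoy genotypes: independent Bernoulli mutation flags for EGFR/KRAS/
  PIK3CA, deliberately carrying no information about sensitivity;
* a pairwise combination screen on Hill-curve single agents, with Bliss
  excess planted preferentially on pairs whose partner target sits high in
  the anchor's simulated EPS ranking, so rank concordance is recoverable.

One master seed drives everything through named ``numpy.random.SeedSequence``
children (``network``, ``perturbations``, ``sensitivity``, ``genotypes``,
``screen``), so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import CELL_LINE, GAPDH, PATIENT, AnalytePanel, DrugInfo, PerturbationMatrix
from .eps import EPSTable, InteractionNetwork, compute_eps_table
from .ml import SensitivityTable, assign_quartiles
from .synergy import CombinationScreen, DoseResponseGrid, bliss_expected

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "STUDY_DRUGS",
    "make_drugs",
    "simulate_network",
    "simulate_perturbations",
    "simulate_sensitivity",
    "simulate_genotypes",
    "simulate_combination_screen",
    "simulate_cohort",
]

# The study's seven targeted agents and their primary target proteins.
STUDY_DRUGS: tuple[tuple[str, str], ...] = (
    ("gefitinib", "EGFR"),
    ("trametinib", "MAP2K1"),
    ("pictilisib", "PIK3CA"),
    ("capivasertib", "AKT1"),
    ("everolimus", "MTOR"),
    ("vemurafenib", "BRAF"),
    ("luminespib", "HSP90AA1"),
)

DOUBLE_SITE_PROTEIN = "AKT1"
DOUBLE_SITES = ("AKT1_T308", "AKT1_S473")


@dataclass
class SimulationConfig:
    """All tunables of the synthetic cohort.

    Defaults reproduce the study conditions: 35 cell lines plus 16
    patient-derived samples, 7 drugs, a 52-analyte panel, and a 6-cell-line
    pairwise combination screen (252 ordered records).
    """

    seed: int
    n_cell_lines: int = 35
    n_patients: int = 16
    n_drugs: int = 7
    panel_size: int = 52
    # network
    n_nodes: int = 80
    edges_per_node: int = 3
    tractable_fraction: float = 0.5
    # perturbations
    effect_size: float = 2.0
    noise_sd: float = 1.0
    decay: float = 0.5
    max_distance: int = 2
    feedback_size: int = 2
    feedback_effect: float = 1.0
    patient_variance_inflation: float = 1.5
    # sensitivity
    signature_size: int = 5
    gi50_coef: float = 0.5
    gi50_log_sd: float = 0.2
    gi50_base: float = -6.5  # log10 molar, ~0.3 uM
    mutation_rates: tuple[float, float, float] = (0.2, 0.3, 0.15)  # EGFR, KRAS, PIK3CA
    # combination screen
    n_combo_samples: int = 6
    n_conc: int = 4
    hill_slope: float = 1.0
    planted_excess: float = 0.3
    synergy_top_rank: int = 5
    bliss_noise_sd: float = 0.02
    synergy_pairs: list[tuple[str, str, float]] | None = None

    def __post_init__(self) -> None:
        for name in (
            "n_cell_lines", "n_patients", "n_drugs", "panel_size", "n_nodes",
            "edges_per_node", "signature_size", "n_combo_samples", "n_conc",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.bliss_noise_sd < 0 or self.gi50_log_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_drugs > len(STUDY_DRUGS):
            raise ValueError(f"at most {len(STUDY_DRUGS)} drugs are modelled")
        if self.n_combo_samples > self.n_cell_lines:
            raise ValueError("n_combo_samples cannot exceed n_cell_lines")
        if self.panel_size < self.n_drugs + 1:
            raise ValueError("panel must cover at least the drug targets")

    def seeds(self) -> dict[str, np.random.SeedSequence]:
        """Named per-stage seed sequences derived from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ["network", "perturbations", "sensitivity", "genotypes", "screen"]
        return dict(zip(names, ss.spawn(len(names))))


@dataclass
class GroundTruth:
    """Planted quantities, recorded before noise is added."""

    signature_analytes: dict[str, list[str]] = field(default_factory=dict)
    true_quartile: dict[str, str] = field(default_factory=dict)  # "sample|drug" -> label
    planted_synergy: dict[str, float] = field(default_factory=dict)  # "sample|a|b" -> excess
    log10_gi50: dict[str, float] = field(default_factory=dict)  # "sample|drug" -> value

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def make_drugs(cfg: SimulationConfig) -> list[DrugInfo]:
    return [
        DrugInfo(drug_id=drug, target_node_ids=(target,))
        for drug, target in STUDY_DRUGS[: cfg.n_drugs]
    ]


def _node_names(cfg: SimulationConfig) -> list[str]:
    targets = [t for _, t in STUDY_DRUGS[: cfg.n_drugs]]
    generic = [f"P{i:03d}" for i in range(cfg.n_nodes - len(targets))]
    return targets + generic


def simulate_network(cfg: SimulationConfig, max_tries: int = 10) -> InteractionNetwork:
    """Connected scale-free PPI stand-in with tractability and analyte map.

    Drug targets occupy the earliest (hub) positions of a Barabasi-Albert
    graph, mirroring the hub role of signalling drug targets.  The first
    ``panel_size - 1`` nodes carry one phosphosite analyte each, except
    AKT1 which carries two (T308 and S473), giving exactly ``panel_size``
    analytes.  All drug-target nodes are tractable; the remaining flags are
    Bernoulli(``tractable_fraction``).
    """
    names = _node_names(cfg)
    if cfg.panel_size - 1 > cfg.n_nodes:
        raise ValueError("panel larger than the network")
    ss = cfg.seeds()["network"]
    for attempt in range(max_tries):
        rng = np.random.default_rng(ss)
        graph_seed = int(rng.integers(2**31))
        m = min(cfg.edges_per_node, cfg.n_nodes - 1)
        g = nx.barabasi_albert_graph(cfg.n_nodes, m, seed=graph_seed)
        if nx.is_connected(g):
            break
        logger.info("disconnected graph on attempt %d; regenerating", attempt)
        ss = ss.spawn(1)[0]
    else:
        raise RuntimeError("could not generate a connected network")
    graph = nx.relabel_nodes(g, dict(enumerate(names)))

    analyte_map: dict[str, str] = {}
    for node in names[: cfg.panel_size - 1]:
        if node == DOUBLE_SITE_PROTEIN:
            for site in DOUBLE_SITES:
                analyte_map[site] = node
        else:
            analyte_map[f"{node}_P1"] = node

    targets = {t for _, t in STUDY_DRUGS[: cfg.n_drugs]}
    tractable = {
        node: bool(node in targets or rng.random() < cfg.tractable_fraction)
        for node in names
    }
    return InteractionNetwork(graph=graph, tractable=tractable, analyte_map=analyte_map)


def _panel_from_network(network: InteractionNetwork) -> AnalytePanel:
    analytes = tuple(sorted(network.analyte_map)) + (GAPDH,)
    return AnalytePanel(analytes=analytes)


def _sample_ids(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    cells = [f"CL{i+1:02d}" for i in range(cfg.n_cell_lines)]
    patients = [f"PT{i+1:02d}" for i in range(cfg.n_patients)]
    return cells, patients


def _mean_changes(
    cfg: SimulationConfig, network: InteractionNetwork, drug: DrugInfo
) -> pd.Series:
    """Noiseless mean change per analyte for one drug (inhibition decay law)."""
    dist: dict[str, int] = {}
    for target in drug.target_node_ids:
        lengths = nx.single_source_shortest_path_length(
            network.graph, target, cutoff=cfg.max_distance
        )
        for node, d in lengths.items():
            dist[node] = min(d, dist.get(node, d))
    analytes = sorted(network.analyte_map)
    means = pd.Series(0.0, index=analytes)
    for analyte in analytes:
        node = network.analyte_map[analyte]
        if node in dist:
            means[analyte] = -cfg.effect_size * cfg.decay ** dist[node]
    return means


def simulate_perturbations(
    cfg: SimulationConfig, network: InteractionNetwork
) -> tuple[PerturbationMatrix, GroundTruth]:
    """Perturbation profiles for every (sample, drug), plus the ground truth.

    Mean change at an analyte of a node at distance d <= ``max_distance``
    from the drug target is ``-effect_size * decay**d``; ``feedback_size``
    analytes beyond that shell receive a positive feedback mean; everything
    else has mean zero.  Gaussian noise with sd ``noise_sd`` is added
    (``noise_sd * patient_variance_inflation`` for patient samples).
    """
    rng = np.random.default_rng(cfg.seeds()["perturbations"])
    drugs = make_drugs(cfg)
    panel = _panel_from_network(network)
    analytes = list(panel.phospho_analytes)
    cells, patients = _sample_ids(cfg)
    truth = GroundTruth()

    rows, index = [], []
    for drug in drugs:
        means = _mean_changes(cfg, network, drug).reindex(analytes).fillna(0.0)
        unaffected = [a for a in analytes if means[a] == 0.0]
        n_fb = min(cfg.feedback_size, len(unaffected))
        feedback = list(rng.choice(unaffected, size=n_fb, replace=False)) if n_fb else []
        means[feedback] = cfg.feedback_effect
        for sample, cohort in [(s, CELL_LINE) for s in cells] + [
            (s, PATIENT) for s in patients
        ]:
            sd = cfg.noise_sd * (
                cfg.patient_variance_inflation if cohort == PATIENT else 1.0
            )
            noise = rng.normal(0.0, sd, size=len(analytes)) if sd > 0 else 0.0
            rows.append(means.to_numpy() + noise)
            index.append((sample, drug.drug_id))

    data = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["sample", "drug"]),
        columns=analytes,
    )
    sample_type = {s: CELL_LINE for s in cells} | {s: PATIENT for s in patients}
    return PerturbationMatrix(data, sample_type), truth


def _signature(
    cfg: SimulationConfig, network: InteractionNetwork, drug: DrugInfo
) -> list[str]:
    """Signature analytes: the closest perturbed analytes to the drug target."""
    means = _mean_changes(cfg, network, drug)
    perturbed = means[means != 0.0]
    order = perturbed.abs().sort_index().sort_values(ascending=False, kind="mergesort")
    return list(order.index[: cfg.signature_size])


def simulate_sensitivity(
    cfg: SimulationConfig,
    matrix: PerturbationMatrix,
    network: InteractionNetwork,
    truth: GroundTruth,
) -> SensitivityTable:
    """GI50 table driven by the planted signature analytes (cell lines only).

    ``log10(GI50) = gi50_base + gi50_coef * sum(signature changes) + noise``:
    stronger inhibition at the signature analytes (more negative changes)
    yields a lower GI50, i.e. a more sensitive sample.  The ground-truth
    quartile comes from the noiseless linear score.
    """
    rng = np.random.default_rng(cfg.seeds()["sensitivity"])
    drugs = make_drugs(cfg)
    cells = [s for s, t in matrix.sample_type.items() if t == CELL_LINE]

    gi50 = pd.DataFrame(index=cells, columns=[d.drug_id for d in drugs], dtype=float)
    scores = pd.DataFrame(index=cells, columns=[d.drug_id for d in drugs], dtype=float)
    for drug in drugs:
        signature = _signature(cfg, network, drug)
        truth.signature_analytes[drug.drug_id] = signature
        for sample in cells:
            changes = matrix.data.loc[(sample, drug.drug_id), signature]
            score = cfg.gi50_base + cfg.gi50_coef * float(changes.sum())
            scores.loc[sample, drug.drug_id] = score
            noise = rng.normal(0.0, cfg.gi50_log_sd) if cfg.gi50_log_sd > 0 else 0.0
            gi50.loc[sample, drug.drug_id] = 10.0 ** (score + noise)

    for drug_id in scores.columns:
        labels = assign_quartiles(scores[drug_id])
        for sample, label in labels.items():
            truth.true_quartile[f"{sample}|{drug_id}"] = label
    for (sample, drug_id), value in gi50.stack().items():
        truth.log10_gi50[f"{sample}|{drug_id}"] = float(np.log10(value))
    return SensitivityTable.from_gi50(gi50)


def simulate_genotypes(cfg: SimulationConfig, samples: Sequence[str]) -> pd.DataFrame:
    """Independent Bernoulli mutation flags — a decoy carrying no signal."""
    rng = np.random.default_rng(cfg.seeds()["genotypes"])
    genes = ("EGFR", "KRAS", "PIK3CA")
    flags = {
        gene: (rng.random(len(samples)) < rate).astype(int)
        for gene, rate in zip(genes, cfg.mutation_rates)
    }
    return pd.DataFrame(flags, index=list(samples))


def simulate_combination_screen(
    cfg: SimulationConfig,
    truth: GroundTruth,
    network: InteractionNetwork,
    eps_table: EPSTable | None = None,
) -> CombinationScreen:
    """Pairwise combination screen over the first ``n_combo_samples`` cell lines.

    Single-agent effects follow Hill curves anchored at each (sample, drug)
    GI50; the observed combined effect is the Bliss expectation plus the
    planted excess plus Gaussian noise, clipped to [0, 1].  When
    ``synergy_pairs`` is not given explicitly, excess is planted on exactly
    the ordered pairs whose partner target achieves EPS rank <=
    ``synergy_top_rank`` in the anchor's ranking, so top-k concordance and
    the rank-bias test have a recoverable signal.
    """
    rng = np.random.default_rng(cfg.seeds()["screen"])
    drugs = make_drugs(cfg)
    cells, _ = _sample_ids(cfg)
    combo_samples = cells[: cfg.n_combo_samples]
    explicit = None
    if cfg.synergy_pairs is not None:
        explicit = {(a, b): excess for a, b, excess in cfg.synergy_pairs}

    # Concentration grid at fixed fractions of GI50 keeps single-agent
    # effects <= 1/3 (hill slope 1), so planted excess never clips at 1.
    fractions = 2.0 ** -np.arange(cfg.n_conc, 0, -1)  # 1/16 .. 1/2 for n_conc=4

    def hill(frac: np.ndarray) -> np.ndarray:
        return frac**cfg.hill_slope / (1.0 + frac**cfg.hill_slope)

    grids = []
    for sample in combo_samples:
        for anchor in drugs:
            for partner in drugs:
                if partner.drug_id == anchor.drug_id:
                    continue
                if explicit is not None:
                    excess = explicit.get((anchor.drug_id, partner.drug_id), 0.0)
                elif eps_table is not None:
                    targets = network.drug_target_entities(partner)
                    best = eps_table.best_target_rank(sample, anchor.drug_id, targets)
                    hot = np.isfinite(best) and best <= cfg.synergy_top_rank
                    excess = cfg.planted_excess if hot else 0.0
                else:
                    excess = 0.0
                truth.planted_synergy[
                    f"{sample}|{anchor.drug_id}|{partner.drug_id}"
                ] = excess

                gi50_a = 10.0 ** truth.log10_gi50[f"{sample}|{anchor.drug_id}"]
                gi50_b = 10.0 ** truth.log10_gi50[f"{sample}|{partner.drug_id}"]
                conc_a, conc_b = fractions * gi50_a, fractions * gi50_b
                fa, fb = hill(fractions), hill(fractions)
                expected = bliss_expected(
                    np.repeat(fa[:, None], cfg.n_conc, axis=1),
                    np.repeat(fb[None, :], cfg.n_conc, axis=0),
                )
                noise = (
                    rng.normal(0.0, cfg.bliss_noise_sd, size=expected.shape)
                    if cfg.bliss_noise_sd > 0
                    else 0.0
                )
                f_obs = np.clip(expected + excess + noise, 0.0, 1.0)
                grids.append(
                    DoseResponseGrid(
                        sample_id=sample,
                        drug_a=anchor.drug_id,
                        drug_b=partner.drug_id,
                        conc_a=conc_a,
                        conc_b=conc_b,
                        fa=fa,
                        fb=fb,
                        f_obs=f_obs,
                    )
                )
    return CombinationScreen.from_grids(grids)


@dataclass
class SyntheticCohort:
    """Everything one simulated study produces, bundled."""

    config: SimulationConfig
    panel: AnalytePanel
    network: InteractionNetwork
    drugs: list[DrugInfo]
    matrix: PerturbationMatrix
    sensitivity: SensitivityTable
    genotypes: pd.DataFrame
    eps_table: EPSTable
    screen: CombinationScreen
    truth: GroundTruth

    @property
    def drug_targets(self) -> dict[str, tuple[str, ...]]:
        return {d.drug_id: d.target_node_ids for d in self.drugs}


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Run every simulation stage in dependency order under one master seed."""
    network = simulate_network(cfg)
    matrix, truth = simulate_perturbations(cfg, network)
    sensitivity = simulate_sensitivity(cfg, matrix, network, truth)
    genotypes = simulate_genotypes(
        cfg, [s for s, t in matrix.sample_type.items() if t == CELL_LINE]
    )
    cells, _ = _sample_ids(cfg)
    combo = matrix.subset_samples(cells[: cfg.n_combo_samples])
    eps_table = compute_eps_table(combo, network)
    screen = simulate_combination_screen(cfg, truth, network, eps_table=eps_table)
    return SyntheticCohort(
        config=cfg,
        panel=_panel_from_network(network),
        network=network,
        drugs=make_drugs(cfg),
        matrix=matrix,
        sensitivity=sensitivity,
        genotypes=genotypes,
        eps_table=eps_table,
        screen=screen,
        truth=truth,
    )
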