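"""End-to-end pipeline orchestration with a single config and a run manifest.

Stages run in dependency order:

    simulate -> normalize -> predict -> eps -> synergy -> report

``simulate`` writes a full synthetic cohort (perturbation matrix, GI50 and
genotype tables, network files, combination grids, ground truth);
``normalize`` turns a raw long-format plate CSV into a perturbation matrix
(only when a plate is configured); ``predict`` cross-validates the
phospho-based and genomic predictors; ``eps`` scores and ranks the network;
``synergy`` summarizes Bliss excess; ``report`` runs the rank-bias and
permutation statistics plus the cohort comparison.  Every output is plain
CSV/TSV/JSON, and the manifest records the config snapshot, per-stage seeds,
output checksums and row counts so a rerun with the same config reproduces
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    AnalytePanel,
    count_regulated,
    normalize_plate,
    read_perturbation_matrix,
    read_raw_plate,
    write_perturbation_matrix,
)
from .eps import compute_eps_table, read_network, topk_concordance, write_network
from .ml import SensitivityTable, cross_validate_predictor, elastic_net_weights, genomic_baseline
from .simulate import STUDY_DRUGS, SimulationConfig, simulate_cohort
from .stats import cohort_compare, mann_whitney_rank_bias, permutation_robustness, rank_bias_groups
from .synergy import CombinationScreen, DoseResponseGrid, bliss_excess_grid

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]

ALL_STAGES = ("simulate", "normalize", "predict", "eps", "synergy", "report")


class ConfigError(ValueError):
    """Invalid or unknown run-configuration key/value."""


@dataclass
class RunConfig:
    """Validated run configuration with every tunable echoed into the manifest."""

    seed: int = 1
    out_dir: str = "run_out"
    stages: tuple[str, ...] = ALL_STAGES
    # inputs (filled by the simulate stage when absent)
    matrix_path: str | None = None
    plate_path: str | None = None
    gi50_path: str | None = None
    genotypes_path: str | None = None
    network_edges: str | None = None
    network_tractable: str | None = None
    network_map: str | None = None
    grids_path: str | None = None
    # tunables
    tau: float = 0.1
    cv_folds: int = 100
    cv_holdout: float = 0.15
    cv_model: str = "rf_classifier"
    cv_select: int | None = None
    n_estimators: int = 500
    eps_self_weight: float = 0.0
    bliss_summary: str = "mean"
    bliss_threshold: float = 0.1
    concordance_k: int = 5
    n_permutations: int = 10_000
    quartile_direction: str = "ascending"
    simulation: dict = field(default_factory=dict)
    force: bool = False

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ConfigError("tau must be > 0")
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}; valid: {list(ALL_STAGES)}")
        if self.bliss_summary not in ("mean", "max", "topq"):
            raise ConfigError(f"unknown bliss_summary {self.bliss_summary!r}")
        if self.cv_model not in ("rf_classifier", "rf_regressor", "elastic_net"):
            raise ConfigError(f"unknown cv_model {self.cv_model!r}")
        if self.quartile_direction not in ("ascending", "descending"):
            raise ConfigError(f"unknown quartile_direction {self.quartile_direction!r}")


def validate_config(raw: str | dict | None) -> RunConfig:
    """Parse YAML/dict config text, rejecting unknown keys with a suggestion."""
    if raw is None:
        data = {}
    elif isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    else:
        data = dict(raw)
    if not isinstance(data, dict):
        raise ConfigError("config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in data:
        if key not in known:
            close = difflib.get_close_matches(key, known, n=1)
            hint = f"; did you mean {close[0]!r}?" if close else ""
            raise ConfigError(f"unknown config key {key!r}{hint}")
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_grids_csv(screen: CombinationScreen, path: Path) -> None:
    rows = []
    for g in screen.grids:
        for i, ca in enumerate(g.conc_a):
            rows.append((g.sample_id, g.drug_a, g.drug_b, ca, 0.0, g.fa[i]))
        for j, cb in enumerate(g.conc_b):
            rows.append((g.sample_id, g.drug_a, g.drug_b, 0.0, cb, g.fb[j]))
        for i, ca in enumerate(g.conc_a):
            for j, cb in enumerate(g.conc_b):
                rows.append((g.sample_id, g.drug_a, g.drug_b, ca, cb, g.f_obs[i, j]))
    pd.DataFrame(
        rows, columns=["sample", "drug_a", "drug_b", "conc_a", "conc_b", "effect"]
    ).to_csv(path, index=False, float_format="%.17g")


def read_grids_csv(path) -> list[DoseResponseGrid]:
    """Read long-format dose grids (single-agent rows have the other conc = 0)."""
    t = pd.read_csv(path)
    grids = []
    for (sample, da, db), g in t.groupby(["sample", "drug_a", "drug_b"], sort=True):
        a_rows = g[(g["conc_b"] == 0) & (g["conc_a"] > 0)].sort_values("conc_a")
        b_rows = g[(g["conc_a"] == 0) & (g["conc_b"] > 0)].sort_values("conc_b")
        combo = g[(g["conc_a"] > 0) & (g["conc_b"] > 0)]
        conc_a = a_rows["conc_a"].to_numpy()
        conc_b = b_rows["conc_b"].to_numpy()
        f_obs = (
            combo.pivot_table(index="conc_a", columns="conc_b", values="effect")
            .reindex(index=conc_a, columns=conc_b)
            .to_numpy()
        )
        grids.append(
            DoseResponseGrid(
                sample_id=sample, drug_a=da, drug_b=db,
                conc_a=conc_a, conc_b=conc_b,
                fa=a_rows["effect"].to_numpy(), fb=b_rows["effect"].to_numpy(),
                f_obs=f_obs,
            )
        )
    return grids


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run manifest (also written).

    A stage whose outputs already exist with matching manifest checksums is
    skipped on resume unless ``force`` is set; a checksum mismatch refuses
    the resume.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    manifest: dict = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def record(stage: str, outputs: dict[str, Path], counts: dict[str, int]) -> None:
        manifest["stages"][stage] = {
            "outputs": {
                name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()
            },
            "row_counts": counts,
        }
        logger.info("stage %s done: %s", stage, counts)

    def resumable(stage: str, outputs: dict[str, Path]) -> bool:
        if config.force or stage not in previous.get("stages", {}):
            return False
        prev = previous["stages"][stage]["outputs"]
        if set(prev) != set(map(str, outputs)) or not all(
            p.exists() for p in outputs.values()
        ):
            return False
        mismatch = [
            name
            for name, p in outputs.items()
            if _sha256(p) != prev[name]["sha256"]
        ]
        if mismatch:
            raise RuntimeError(
                f"stage {stage}: existing outputs {sorted(mismatch)} do not match the "
                "previous manifest; rerun with force=true to overwrite"
            )
        manifest["stages"][stage] = previous["stages"][stage]
        logger.info("stage %s resumed from existing outputs", stage)
        return True

    paths = {
        "matrix": Path(config.matrix_path) if config.matrix_path else out / "matrix.csv",
        "gi50": Path(config.gi50_path) if config.gi50_path else out / "gi50.csv",
        "genotypes": Path(config.genotypes_path) if config.genotypes_path else out / "genotypes.csv",
        "edges": Path(config.network_edges) if config.network_edges else out / "network_edges.tsv",
        "tractable": Path(config.network_tractable) if config.network_tractable else out / "network_tractable.tsv",
        "map": Path(config.network_map) if config.network_map else out / "analyte_map.tsv",
        "grids": Path(config.grids_path) if config.grids_path else out / "grids.csv",
    }

    sim_cfg = SimulationConfig(seed=config.seed, **config.simulation)

    if "simulate" in config.stages:
        outputs = {
            **{k: paths[k] for k in ("matrix", "gi50", "genotypes", "edges", "tractable", "map", "grids")},
            "truth": out / "truth.json",
        }
        if not resumable("simulate", outputs):
            cohort = simulate_cohort(sim_cfg)
            write_perturbation_matrix(cohort.matrix, paths["matrix"])
            cohort.sensitivity.gi50.rename_axis("sample").to_csv(
                paths["gi50"], float_format="%.17g"
            )
            cohort.genotypes.rename_axis("sample").to_csv(paths["genotypes"])
            write_network(cohort.network, paths["edges"], paths["tractable"], paths["map"])
            _write_grids_csv(cohort.screen, paths["grids"])
            cohort.truth.to_json(out / "truth.json")
            record("simulate", outputs, {
                "profiles": len(cohort.matrix.data),
                "grids": len(cohort.screen.grids),
                "nodes": cohort.network.graph.number_of_nodes(),
            })

    network = None
    if any(s in config.stages for s in ("eps", "report")):
        for key in ("edges", "tractable", "map"):
            if not paths[key].exists():
                raise FileNotFoundError(
                    f"stage eps/report needs network file {paths[key]} "
                    "(enable the simulate stage or provide network_* paths)"
                )
        network = read_network(paths["edges"], paths["tractable"], paths["map"])

    matrix = None
    if "normalize" in config.stages and not config.plate_path and paths["matrix"].exists():
        # synthetic runs produce normalized changes directly; nothing to do
        logger.info("normalize skipped: no raw plate configured, matrix present")
        manifest["stages"]["normalize"] = {"skipped": "no plate_path; matrix present"}
    elif "normalize" in config.stages:
        if not config.plate_path:
            raise FileNotFoundError("normalize stage requires plate_path")
        plate = read_raw_plate(config.plate_path)
        analytes = sorted(set(plate.wells["analyte"]) - {"GAPDH"})
        panel = AnalytePanel(analytes=tuple(analytes) + ("GAPDH",))
        matrix = normalize_plate(plate, panel)
        write_perturbation_matrix(matrix, paths["matrix"])
        record("normalize", {"matrix": paths["matrix"]}, {"profiles": len(matrix.data)})

    def load_matrix():
        if not paths["matrix"].exists():
            raise FileNotFoundError(
                f"stage needs {paths['matrix']}; run simulate/normalize first"
            )
        raw = pd.read_csv(paths["matrix"], nrows=0)
        analytes = tuple(c for c in raw.columns if c not in ("sample", "drug", "sample_type"))
        panel = AnalytePanel(analytes=analytes + ("GAPDH",))
        return read_perturbation_matrix(paths["matrix"], panel)

    if "predict" in config.stages:
        matrix = matrix or load_matrix()
        gi50 = pd.read_csv(paths["gi50"], index_col="sample")
        sens = SensitivityTable.from_gi50(gi50, direction=config.quartile_direction)
        labels = sens.labels_long()
        X = matrix.data.reindex(labels.index).dropna()
        labels = labels.loc[X.index]
        cv = cross_validate_predictor(
            X, labels.to_numpy(), model_kind=config.cv_model,
            n_folds=config.cv_folds, holdout=config.cv_holdout,
            seed=config.seed, select=config.cv_select,
            n_estimators=config.n_estimators,
        )
        genotypes = pd.read_csv(paths["genotypes"], index_col="sample")
        baseline = genomic_baseline(
            genotypes, labels, model_kind=config.cv_model,
            n_folds=config.cv_folds, holdout=config.cv_holdout,
            seed=config.seed, n_estimators=config.n_estimators,
        )
        weights = {
            q: elastic_net_weights(X, (labels == q).astype(float), seed=config.seed)
            for q in sorted(labels.unique())
        }
        (out / "cv_result.json").write_text(
            json.dumps({"phospho": cv.to_dict(), "genomic": baseline.to_dict()}, indent=1)
        )
        wtab = pd.concat({q: w.to_frame() for q, w in weights.items()}, names=["quartile"])
        wtab.to_csv(out / "feature_weights.tsv", sep="\t", float_format="%.17g")
        record(
            "predict",
            {"cv_result": out / "cv_result.json", "weights": out / "feature_weights.tsv"},
            {"rows": len(X)},
        )

    eps_table = None
    if "eps" in config.stages:
        matrix = matrix or load_matrix()
        eps_table = compute_eps_table(matrix, network, self_weight=config.eps_self_weight)
        eps_table.to_tsv(out / "eps.tsv")
        record("eps", {"eps": out / "eps.tsv"}, {"rows": len(eps_table.table)})

    screen = None
    if "synergy" in config.stages:
        if not paths["grids"].exists():
            raise FileNotFoundError(f"synergy stage needs {paths['grids']}")
        grids = read_grids_csv(paths["grids"])
        screen = CombinationScreen.from_grids(grids, summary=config.bliss_summary)
        screen.bliss_summary.to_csv(
            out / "bliss.tsv", sep="\t", index=False, float_format="%.17g"
        )
        screen.unordered_summary().to_csv(
            out / "bliss_unordered.tsv", sep="\t", index=False, float_format="%.17g"
        )
        record(
            "synergy",
            {"bliss": out / "bliss.tsv", "bliss_unordered": out / "bliss_unordered.tsv"},
            {"records": len(screen.bliss_summary)},
        )

    if "report" in config.stages:
        matrix = matrix or load_matrix()
        if eps_table is None or screen is None:
            raise FileNotFoundError("report stage needs the eps and synergy stages")
        known = dict(STUDY_DRUGS)
        drug_targets = {
            drug: (known[drug],)
            for drug in screen.bliss_summary["drug_a"].unique()
            if drug in known
        }
        per_condition, cohort_summary = count_regulated(matrix, tau=config.tau)
        conc = topk_concordance(
            eps_table, screen.bliss_summary, drug_targets, network,
            bliss_threshold=config.bliss_threshold, k=config.concordance_k,
        )
        ranks_top, ranks_bottom = rank_bias_groups(
            eps_table, screen.bliss_summary, drug_targets, network
        )
        bias = mann_whitney_rank_bias(ranks_top, ranks_bottom)
        null = permutation_robustness(
            eps_table, screen.bliss_summary, drug_targets, network,
            n=config.n_permutations, seed=config.seed,
        )
        comparison = cohort_compare(matrix)
        report = {
            "regulated": cohort_summary.to_dict(),
            "concordance": {
                "n_synergistic": conc.n_synergistic,
                "n_hit": conc.n_hit,
                "fraction": conc.fraction,
                "k": conc.k,
            },
            "rank_bias": {
                "U": bias.u, "p_two_sided": bias.p_two_sided,
                "rank_biserial": bias.rank_biserial, "method": bias.method,
            },
            "permutation": {
                "n": null.n_permutations,
                "observed_p": null.observed_p,
                "empirical_quantile": null.empirical_quantile,
            },
            "welch": {"t": comparison.welch_t, "p": comparison.welch_p},
        }
        (out / "report.json").write_text(json.dumps(report, indent=1))
        pd.DataFrame(
            {"null_p": np.sort(null.permuted_p_values)}
        ).to_csv(out / "permutation_null.tsv", sep="\t", index=False)
        record(
            "report",
            {"report": out / "report.json", "null": out / "permutation_null.tsv"},
            {"synergistic": conc.n_synergistic},
        )

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
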