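"""Core domain types, file I/O and normalization of bead-assay measurements.

The measurement model: cells are exposed for one hour to a single drug (or
DMSO vehicle), lysed, and a multiplexed bead assay reports one fluorescence
intensity (MFI) per phospho-analyte per well.  GAPDH is carried as a loading
control in every well.  Normalization turns raw MFIs into signed, unitless
log2-scale *changes* of each phospho-analyte versus the sample's DMSO
controls:

1. every analyte MFI is divided by the well's GAPDH MFI and log2-transformed;
2. per analyte, the median of those log2 ratios across all DMSO wells of the
   plate is subtracted from every well (median-centering anchored on the
   vehicle controls);
3. the change for (sample, drug, analyte) is the centered value of the
   drugged well minus the mean centered value of that sample's DMSO
   replicates.

Because step 3 is a difference, the per-analyte centering constant cancels:
changes are DMSO-referenced and invariant to any per-well scaling of the raw
intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

GAPDH = "GAPDH"
DMSO = "DMSO"

CELL_LINE = "cell_line"
PATIENT = "patient"

__all__ = [
    "GAPDH",
    "DMSO",
    "CELL_LINE",
    "PATIENT",
    "AnalytePanel",
    "RawPlate",
    "PerturbationProfile",
    "PerturbationMatrix",
    "DrugInfo",
    "PanelMismatchError",
    "DuplicateConditionError",
    "NormalizationError",
    "read_perturbation_matrix",
    "write_perturbation_matrix",
    "read_raw_plate",
    "normalize_plate",
    "adjust_cmax_for_binding",
    "count_regulated",
]


class PanelMismatchError(ValueError):
    """A table does not carry the analytes the panel requires."""


class DuplicateConditionError(ValueError):
    """The same (sample, drug) condition appears more than once."""


class NormalizationError(ValueError):
    """Raw plate cannot be normalized (e.g. non-positive GAPDH)."""


@dataclass(frozen=True)
class AnalytePanel:
    """An ordered panel of phosphosite-resolved analytes plus loading controls.

    ``analytes`` lists every measured analyte (e.g. ``"AKT1_S473"``);
    ``controls`` is the subset used only for normalization and must include
    GAPDH.  ``size`` counts the non-control phospho-analytes; the study
    panel has size 52.
    """

    analytes: tuple[str, ...]
    controls: frozenset[str] = frozenset({GAPDH})

    def __post_init__(self) -> None:
        if len(set(self.analytes)) != len(self.analytes):
            raise ValueError("analyte identifiers must be unique")
        if not self.controls <= set(self.analytes):
            raise ValueError("controls must be a subset of the panel analytes")
        if GAPDH not in self.controls:
            raise ValueError(f"controls must include {GAPDH!r}")

    @property
    def phospho_analytes(self) -> tuple[str, ...]:
        """Non-control analytes, in panel order."""
        return tuple(a for a in self.analytes if a not in self.controls)

    @property
    def size(self) -> int:
        return len(self.analytes) - len(self.controls)


@dataclass(frozen=True)
class DrugInfo:
    """One drug: network targets and concentration bookkeeping.

    Concentrations are molar.  ``fu_plasma`` / ``fu_medium`` are the unbound
    drug fractions in plasma and in 20% FBS culture medium; the assay
    concentration is chosen so the *unbound* concentration in medium matches
    the unbound concentration at clinical Cmax in plasma.
    """

    drug_id: str
    target_node_ids: tuple[str, ...]
    cmax_plasma: float | None = None
    fu_plasma: float | None = None
    fu_medium: float | None = None
    assay_concentration: float | None = None

    def __post_init__(self) -> None:
        if not self.target_node_ids:
            raise ValueError(f"drug {self.drug_id!r} has no target nodes")
        if self.assay_concentration is not None and self.assay_concentration <= 0:
            raise ValueError("assay_concentration must be > 0")


def adjust_cmax_for_binding(info: DrugInfo) -> float:
    """Assay concentration giving the same unbound exposure as plasma Cmax.

    Returns ``cmax_plasma * fu_plasma / fu_medium``.  With equal unbound
    fractions this is just Cmax; a drug more highly bound in plasma than in
    medium is dosed lower in the assay.
    """
    if info.cmax_plasma is None or info.fu_plasma is None or info.fu_medium is None:
        raise ValueError("cmax_plasma, fu_plasma and fu_medium must all be set")
    for name, fu in (("fu_plasma", info.fu_plasma), ("fu_medium", info.fu_medium)):
        if not (0.0 < fu <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1], got {fu}")
    if info.cmax_plasma <= 0:
        raise ValueError("cmax_plasma must be > 0")
    return info.cmax_plasma * info.fu_plasma / info.fu_medium


@dataclass(frozen=True)
class PerturbationProfile:
    """Signed normalized changes for one (sample, drug) condition."""

    sample_id: str
    drug_id: str
    changes: Mapping[str, float]

    def validate(self, panel: AnalytePanel) -> None:
        expected = set(panel.phospho_analytes)
        got = set(self.changes)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise PanelMismatchError(
                f"profile ({self.sample_id}, {self.drug_id}) does not match the "
                f"panel: missing {missing}, unexpected {extra}"
            )
        values = np.asarray(list(self.changes.values()), dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError(
                f"profile ({self.sample_id}, {self.drug_id}) has non-finite changes"
            )


class PerturbationMatrix:
    """All perturbation profiles of a cohort.

    Backed by a DataFrame indexed by (sample, drug) with one column per
    non-control analyte, plus a per-sample cohort label
    (``"cell_line"`` or ``"patient"``).
    """

    def __init__(self, data: pd.DataFrame, sample_type: Mapping[str, str] | None = None):
        if data.index.nlevels != 2:
            raise ValueError("data must be indexed by (sample, drug)")
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise DuplicateConditionError(f"duplicate (sample, drug) rows: {dupes}")
        self.data = data.astype(float)
        self.data.index = self.data.index.set_names(["sample", "drug"])
        samples = self.data.index.get_level_values("sample").unique()
        st = dict(sample_type or {})
        self.sample_type = {s: st.get(s, CELL_LINE) for s in samples}
        bad = {s: t for s, t in self.sample_type.items() if t not in (CELL_LINE, PATIENT)}
        if bad:
            raise ValueError(f"invalid sample types: {bad}")

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.data.index.get_level_values("sample").unique())

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self.data.index.get_level_values("drug").unique())

    def profiles(self) -> Iterator[PerturbationProfile]:
        for (sample, drug), row in self.data.iterrows():
            yield PerturbationProfile(sample, drug, row.to_dict())

    def subset_samples(self, samples: Iterable[str]) -> "PerturbationMatrix":
        keep = list(samples)
        sub = self.data.loc[self.data.index.get_level_values("sample").isin(keep)]
        return PerturbationMatrix(sub.copy(), self.sample_type)

    @classmethod
    def from_profiles(
        cls,
        profiles: Sequence[PerturbationProfile],
        panel: AnalytePanel,
        sample_type: Mapping[str, str] | None = None,
    ) -> "PerturbationMatrix":
        for p in profiles:
            p.validate(panel)
        index = pd.MultiIndex.from_tuples(
            [(p.sample_id, p.drug_id) for p in profiles], names=["sample", "drug"]
        )
        data = pd.DataFrame(
            [[p.changes[a] for a in panel.phospho_analytes] for p in profiles],
            index=index,
            columns=list(panel.phospho_analytes),
        )
        return cls(data, sample_type)


def write_perturbation_matrix(matrix: PerturbationMatrix, path) -> None:
    """Write the matrix as CSV with columns ``sample,drug,sample_type,<analyte...>``.

    Full float precision is kept so a write -> read round trip preserves the
    values to at least 12 significant digits.
    """
    out = matrix.data.reset_index()
    out.insert(2, "sample_type", out["sample"].map(matrix.sample_type))
    out.to_csv(path, index=False, float_format="%.17g")


def read_perturbation_matrix(path, panel: AnalytePanel, sep: str = ",") -> PerturbationMatrix:
    """Read a ``sample,drug,<analyte...>`` table and validate it against a panel.

    Missing panel analytes raise :class:`PanelMismatchError`; unrecognized
    extra columns are dropped with a warning; duplicate (sample, drug) rows
    raise :class:`DuplicateConditionError`; a non-numeric change value raises
    a ``ValueError`` naming the offending row and column.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("sample", "drug"):
        if col not in raw.columns:
            raise PanelMismatchError(f"table is missing required column {col!r}")
    expected = list(panel.phospho_analytes)
    missing = [a for a in expected if a not in raw.columns]
    if missing:
        raise PanelMismatchError(f"table is missing panel analytes: {missing}")
    known = {"sample", "drug", "sample_type", *expected}
    extra = [c for c in raw.columns if c not in known]
    if extra:
        warnings.warn(f"ignoring extra columns: {extra}", stacklevel=2)

    values = pd.DataFrame(index=raw.index, columns=expected, dtype=float)
    for col in expected:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any() or converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise ValueError(
                f"non-numeric change value at row {row} "
                f"(sample={raw.loc[row, 'sample']!r}), column {col!r}"
            )
        values[col] = converted

    index = pd.MultiIndex.from_frame(raw[["sample", "drug"]])
    values.index = index
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise DuplicateConditionError(f"duplicate (sample, drug) rows: {dupes}")

    sample_type = None
    if "sample_type" in raw.columns:
        sample_type = dict(zip(raw["sample"], raw["sample_type"]))
    return PerturbationMatrix(values, sample_type)


@dataclass
class RawPlate:
    """Raw bead-assay plate in long format.

    ``wells`` columns: ``sample, condition, replicate, analyte, mfi`` where
    ``condition`` is a drug identifier or ``"DMSO"``.  Each sample carries
    DMSO replicate wells (study design: 3) next to its drugged wells.
    """

    wells: pd.DataFrame

    REQUIRED = ("sample", "condition", "replicate", "analyte", "mfi")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.wells.columns]
        if missing:
            raise ValueError(f"plate table is missing columns: {missing}")
        self.wells = self.wells.copy()
        self.wells["mfi"] = self.wells["mfi"].astype(float)

    def validate(self) -> None:
        gapdh = self.wells[self.wells["analyte"] == GAPDH]
        wells = self.wells[["sample", "condition", "replicate"]].drop_duplicates()
        have = gapdh[["sample", "condition", "replicate"]].drop_duplicates()
        if len(wells.merge(have)) != len(wells):
            raise NormalizationError("every well must carry a GAPDH measurement")
        if (gapdh["mfi"] <= 0).any():
            bad = gapdh.loc[gapdh["mfi"] <= 0, ["sample", "condition", "replicate"]]
            raise NormalizationError(
                f"non-positive GAPDH intensity in wells:\n{bad.to_string(index=False)}"
            )
        drugged = self.wells.loc[self.wells["condition"] != DMSO, "sample"].unique()
        dmso_samples = set(self.wells.loc[self.wells["condition"] == DMSO, "sample"])
        orphans = sorted(set(drugged) - dmso_samples)
        if orphans:
            raise NormalizationError(f"samples without DMSO controls: {orphans}")


def read_raw_plate(path, sep: str = ",") -> RawPlate:
    return RawPlate(pd.read_csv(path, sep=sep))


def normalize_plate(
    plate: RawPlate,
    panel: AnalytePanel,
    sample_type: Mapping[str, str] | None = None,
    floor_factor: float = 0.5,
) -> PerturbationMatrix:
    """GAPDH-normalize, median-center on DMSO wells, and difference vs DMSO.

    See the module docstring for the three-step arithmetic.  Non-positive
    phospho-analyte intensities are clamped to ``floor_factor`` times the
    smallest positive intensity on the plate (with a warning) so the log is
    defined; non-positive GAPDH is an error.
    """
    plate.validate()
    wide = plate.wells.pivot_table(
        index=["sample", "condition", "replicate"],
        columns="analyte",
        values="mfi",
        aggfunc="first",
    )
    expected = list(panel.phospho_analytes)
    missing = [a for a in expected if a not in wide.columns]
    if missing:
        raise PanelMismatchError(f"plate is missing panel analytes: {missing}")
    intensities = wide[expected].copy()
    if intensities.isna().any().any():
        raise NormalizationError("plate has wells with missing analyte measurements")

    nonpos = intensities.values <= 0
    if nonpos.any():
        positive_min = float(intensities.values[intensities.values > 0].min())
        floor = positive_min * floor_factor
        warnings.warn(
            f"{int(nonpos.sum())} non-positive intensities clamped to {floor:g}",
            stacklevel=2,
        )
        intensities = intensities.clip(lower=floor)

    gapdh = wide[GAPDH]
    log_ratio = np.log2(intensities.div(gapdh, axis=0))

    dmso_mask = log_ratio.index.get_level_values("condition") == DMSO
    centering = log_ratio.loc[dmso_mask].median(axis=0)
    centered = log_ratio.sub(centering, axis=1)

    dmso_mean = (
        centered.loc[dmso_mask]
        .groupby(level="sample")
        .mean()
    )
    drugged = centered.loc[~dmso_mask]
    per_condition = drugged.groupby(level=["sample", "condition"]).mean()
    changes = per_condition - dmso_mean.reindex(
        per_condition.index.get_level_values("sample")
    ).set_axis(per_condition.index)
    changes.index = changes.index.set_names(["sample", "drug"])
    return PerturbationMatrix(changes, sample_type)


def count_regulated(
    matrix: PerturbationMatrix, tau: float = 0.1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count down-/up-regulated analytes per condition and summarize by cohort.

    An analyte is down-regulated when its change is below ``-tau`` and
    up-regulated above ``+tau`` (log2 scale).  Returns a per-(sample, drug)
    table with ``n_down``/``n_up`` and a cohort summary with the mean counts
    and the means as percent of panel size, split by cell-line vs patient
    samples.
    """
    if not tau > 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    data = matrix.data
    per_condition = pd.DataFrame(
        {
            "n_down": (data < -tau).sum(axis=1),
            "n_up": (data > tau).sum(axis=1),
        }
    )
    panel_size = data.shape[1]
    cohort = per_condition.copy()
    cohort["sample_type"] = [
        matrix.sample_type[s] for s in cohort.index.get_level_values("sample")
    ]
    summary = cohort.groupby("sample_type")[["n_down", "n_up"]].mean()
    summary = summary.rename(columns={"n_down": "mean_down", "n_up": "mean_up"})
    summary["pct_down"] = 100.0 * summary["mean_down"] / panel_size
    summary["pct_up"] = 100.0 * summary["mean_up"] / panel_size
    return per_condition, summary
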