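"""Bliss-independence scoring of two-drug combination dose grids.

The Bliss independence null model for two drugs with fractional effects
``fa`` and ``fb`` (effect = 1 - viability relative to control, in [0, 1])
predicts a combined effect ``fa + fb - fa*fb``.  The *excess* of the
observed combined effect over this expectation, cell by cell over a dose
grid, measures synergy (positive) or antagonism (negative); a configurable
scalar reduction (default: the mean excess over the grid) gives one Bliss
summary score per (sample, ordered drug pair).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseGrid",
    "CombinationScreen",
    "enumerate_screen",
    "bliss_expected",
    "bliss_excess_grid",
    "synergy_quartiles",
    "quartile_sizes",
]


def quartile_sizes(n: int) -> tuple[int, int, int, int]:
    """Sizes of four near-equal contiguous groups; remainders go to earlier groups."""
    base, rem = divmod(n, 4)
    return tuple(base + (1 if i < rem else 0) for i in range(4))


def enumerate_screen(
    drugs: Sequence[str], samples: Sequence[str], ordered: bool = True
) -> list[tuple[str, tuple[str, str]]]:
    """All (sample, drug-pair) records of a pairwise combination screen.

    ``ordered=True`` yields every ordered pair (a, b), a != b — the
    anchor/partner view (7 drugs x 6 samples -> 252 records); ``ordered=False``
    yields unordered pairs (21 for 7 drugs).
    """
    if len(drugs) < 2:
        raise ValueError("need at least 2 drugs")
    if len(set(drugs)) != len(drugs):
        raise ValueError("duplicate drug identifiers")
    if ordered:
        pairs = [(a, b) for a, b in itertools.permutations(drugs, 2)]
    else:
        pairs = list(itertools.combinations(drugs, 2))
    return [(s, p) for s in samples for p in pairs]


def bliss_expected(fa, fb):
    """Bliss-independence expected combined effect ``fa + fb - fa*fb``.

    Accepts scalars or arrays; inputs must lie in [0, 1].
    """
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if np.any((fa < 0) | (fa > 1)) or np.any((fb < 0) | (fb > 1)):
        raise ValueError("fractional effects must lie in [0, 1]")
    out = fa + fb - fa * fb
    return float(out) if out.ndim == 0 else out


@dataclass
class DoseResponseGrid:
    """Checkerboard dose grid for one (sample, ordered drug pair).

    ``fa[i]`` / ``fb[j]`` are single-agent fractional effects at the i-th /
    j-th concentration; ``f_obs[i, j]`` is the observed combined effect.
    Missing combination cells may be NaN.
    """

    sample_id: str
    drug_a: str
    drug_b: str
    conc_a: np.ndarray
    conc_b: np.ndarray
    fa: np.ndarray
    fb: np.ndarray
    f_obs: np.ndarray

    def __post_init__(self) -> None:
        self.conc_a = np.asarray(self.conc_a, dtype=float)
        self.conc_b = np.asarray(self.conc_b, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        self.fb = np.asarray(self.fb, dtype=float)
        self.f_obs = np.asarray(self.f_obs, dtype=float)
        if np.any(np.diff(self.conc_a) <= 0) or np.any(np.diff(self.conc_b) <= 0):
            raise ValueError("concentration vectors must be strictly ascending")
        if self.fa.shape != self.conc_a.shape or self.fb.shape != self.conc_b.shape:
            raise ValueError("single-agent effect vectors must match concentrations")
        if self.f_obs.shape != (len(self.conc_a), len(self.conc_b)):
            raise ValueError(
                f"f_obs must be {len(self.conc_a)} x {len(self.conc_b)}, "
                f"got {self.f_obs.shape}"
            )
        for name, arr in (("fa", self.fa), ("fb", self.fb), ("f_obs", self.f_obs)):
            finite = arr[np.isfinite(arr)]
            if np.any((finite < 0) | (finite > 1)):
                raise ValueError(f"{name} effects must lie in [0, 1]")


def bliss_excess_grid(
    grid: DoseResponseGrid, summary: str = "mean", max_missing: float = 0.25
) -> tuple[np.ndarray, float]:
    """Per-cell Bliss excess and its scalar summary for one grid.

    ``excess[i, j] = f_obs[i, j] - bliss_expected(fa[i], fb[j])``.  Summary
    modes: ``"mean"`` (default), ``"max"``, and ``"topq"`` (mean of the
    top-quartile cells).  Missing cells are excluded with a warning; more
    than ``max_missing`` of the grid missing is an error.
    """
    expected = bliss_expected(
        np.repeat(grid.fa[:, None], len(grid.fb), axis=1),
        np.repeat(grid.fb[None, :], len(grid.fa), axis=0),
    )
    excess = grid.f_obs - expected
    missing = ~np.isfinite(excess)
    if missing.any():
        frac = missing.mean()
        if frac > max_missing:
            raise ValueError(
                f"{frac:.0%} of grid cells missing for "
                f"({grid.sample_id}, {grid.drug_a}, {grid.drug_b}); limit {max_missing:.0%}"
            )
        warnings.warn(
            f"{int(missing.sum())} missing cells excluded from the Bliss summary",
            stacklevel=2,
        )
    values = np.sort(excess[~missing])
    if summary == "mean":
        score = float(values.mean())
    elif summary == "max":
        score = float(values.max())
    elif summary == "topq":
        n_top = quartile_sizes(len(values))[0]
        score = float(values[-n_top:].mean())
    else:
        raise ValueError(f"unknown summary mode {summary!r}")
    return excess, score


@dataclass
class CombinationScreen:
    """Dose grids plus one Bliss summary per (sample, ordered drug pair)."""

    grids: list[DoseResponseGrid]
    bliss_summary: pd.DataFrame  # columns: sample, drug_a, drug_b, bliss

    @classmethod
    def from_grids(
        cls, grids: Sequence[DoseResponseGrid], summary: str = "mean"
    ) -> "CombinationScreen":
        rows = []
        for g in grids:
            _, score = bliss_excess_grid(g, summary=summary)
            rows.append((g.sample_id, g.drug_a, g.drug_b, score))
        table = pd.DataFrame(rows, columns=["sample", "drug_a", "drug_b", "bliss"])
        if table.duplicated(["sample", "drug_a", "drug_b"]).any():
            raise ValueError("duplicate (sample, drug_a, drug_b) grids")
        return cls(grids=list(grids), bliss_summary=table)

    def unordered_summary(self) -> pd.DataFrame:
        """21-combination view: mean of the two orientations of each pair."""
        t = self.bliss_summary.copy()
        key = [tuple(sorted(p)) for p in zip(t["drug_a"], t["drug_b"])]
        t["pair"] = key
        out = (
            t.groupby(["sample", "pair"], as_index=False)["bliss"]
            .mean()
            .assign(
                drug_a=lambda d: [p[0] for p in d["pair"]],
                drug_b=lambda d: [p[1] for p in d["pair"]],
            )
            .drop(columns="pair")
        )
        return out[["sample", "drug_a", "drug_b", "bliss"]]


def synergy_quartiles(bliss_summary: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-25% and bottom-25% records by Bliss summary score.

    Records are sorted by score with ties broken by (sample, drug_a, drug_b)
    for determinism; group sizes follow the same remainder rule as
    sensitivity quartiles, so 252 records give 63 per extreme quartile.
    """
    if len(bliss_summary) < 4:
        raise ValueError("need at least 4 records to take quartiles")
    t = bliss_summary.sort_values(
        ["bliss", "sample", "drug_a", "drug_b"], kind="mergesort"
    ).reset_index(drop=True)
    sizes = quartile_sizes(len(t))
    bottom = t.iloc[: sizes[0]]
    top = t.iloc[len(t) - sizes[3] :]
    return top.reset_index(drop=True), bottom.reset_index(drop=True)
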