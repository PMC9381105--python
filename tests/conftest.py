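import numpy as np
import pandas as pd
import pytest

from phosphoresponse import SimulationConfig, simulate_cohort
from phosphoresponse.core import AnalytePanel, RawPlate


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A reduced cohort that keeps every downstream stage fast."""
    return SimulationConfig(
        seed=7,
        n_cell_lines=12,
        n_patients=5,
        n_combo_samples=4,
        panel_size=20,
        n_nodes=30,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size study conditions: 35 cell lines, 16 patients, 7 drugs, 52 analytes."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture
def toy_panel() -> AnalytePanel:
    return AnalytePanel(analytes=("A1", "A2", "GAPDH"))


def make_plate(rows) -> RawPlate:
    return RawPlate(
        pd.DataFrame(rows, columns=["sample", "condition", "replicate", "analyte", "mfi"])
    )


@pytest.fixture
def toy_plate() -> RawPlate:
    """One sample, 3 DMSO wells and one drugged well, 2 analytes plus GAPDH.

    Analyte A1 has log2 MFI/GAPDH ratios {0.0, 0.2, 0.4} in the DMSO wells
    and 1.0 in the drugged well; A2 is flat at ratio 1 everywhere.
    """
    rows = []
    for rep, log_ratio in enumerate((0.0, 0.2, 0.4)):
        rows += [
            ("S1", "DMSO", rep, "GAPDH", 100.0),
            ("S1", "DMSO", rep, "A1", 100.0 * 2.0**log_ratio),
            ("S1", "DMSO", rep, "A2", 100.0),
        ]
    rows += [
        ("S1", "drugX", 0, "GAPDH", 200.0),
        ("S1", "drugX", 0, "A1", 200.0 * 2.0),
        ("S1", "drugX", 0, "A2", 200.0),
    ]
    return make_plate(rows)
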