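"""Normalize a raw bead-assay plate into DMSO-referenced log2 changes.

Builds a 4-well toy plate (3 DMSO controls + 1 gefitinib well) for one
sample: analyte EGFR_P1 drops to half its GAPDH-relative DMSO level under
drug, AKT1_S473 is unchanged.
"""

import pandas as pd

from phosphoresponse import AnalytePanel, RawPlate, normalize_plate

rows = []
for rep in range(3):  # three DMSO vehicle wells
    rows += [
        ("H522", "DMSO", rep, "GAPDH", 1000.0),
        ("H522", "DMSO", rep, "EGFR_P1", 800.0),
        ("H522", "DMSO", rep, "AKT1_S473", 500.0),
    ]
rows += [  # one drugged well, scaled 2x overall to show loading invariance
    ("H522", "gefitinib", 0, "GAPDH", 2000.0),
    ("H522", "gefitinib", 0, "EGFR_P1", 800.0),   # half the DMSO ratio
    ("H522", "gefitinib", 0, "AKT1_S473", 1000.0),  # same ratio as DMSO
]
plate = RawPlate(pd.DataFrame(rows, columns=["sample", "condition", "replicate", "analyte", "mfi"]))
panel = AnalytePanel(analytes=("EGFR_P1", "AKT1_S473", "GAPDH"))

matrix = normalize_plate(plate, panel)
print(matrix.data.round(3))
# EGFR_P1 = -1.0: the drug halved the GAPDH-normalized signal (log2 scale);
# AKT1_S473 = 0.0: no change vs DMSO, and the 2x well scaling cancelled out.
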