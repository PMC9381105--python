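"""Generate a synthetic cohort and count drug-regulated phosphoproteins.

The generator plants drug-target inhibition that decays over the
interaction network, adds measurement noise, and derives GI50 values from
signature analytes.  Here a reduced cohort keeps the printout small.
"""

from phosphoresponse import SimulationConfig, count_regulated, simulate_cohort

cfg = SimulationConfig(seed=42, n_cell_lines=10, n_patients=4,
                       n_combo_samples=4, panel_size=24, n_nodes=36)
cohort = simulate_cohort(cfg)

print(f"profiles: {len(cohort.matrix.data)} (sample x drug), "
      f"{len(cohort.matrix.analytes)} analytes")
print(f"network: {cohort.network.graph.number_of_nodes()} nodes, "
      f"{cohort.network.graph.number_of_edges()} edges")

per_condition, summary = count_regulated(cohort.matrix, tau=0.1)
print(summary.round(2))
# mean_down / mean_up: average number of analytes moved below -0.1 / above
# +0.1 (log2) per condition, with the same means as percent of the panel,
# reported separately for cell lines and patient-derived samples.

print("\nGI50 quartiles for gefitinib (Q1 = most sensitive):")
print(cohort.sensitivity.quartile["gefitinib"].value_counts().sort_index())
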