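"""Score network nodes by the environmental perturbation score (EPS).

EPS(v) sums |change| over the analytes of v's direct neighbors, so a node
can surface as a signalling junction even when its own perturbation is
small.  Tractable (druggable) entities are ranked, and candidate partner
drugs are nominated by the best rank among their targets.
"""

from phosphoresponse import SimulationConfig, nominate_combinations, simulate_cohort

cohort = simulate_cohort(SimulationConfig(seed=7, n_cell_lines=8, n_patients=2,
                                          n_combo_samples=3, panel_size=24, n_nodes=36))

one = cohort.eps_table.ranking("CL01", "capivasertib")
print("top tractable entities by EPS after AKT inhibition in CL01:")
print(one.dropna(subset=["rank"]).nsmallest(5, "rank")[["entity", "eps", "rank"]]
      .to_string(index=False))
# rank 1 = hottest neighborhood; the AKT1_T308/AKT1_S473 site entities are
# ranked separately but share the protein node's neighborhood sum.

noms = nominate_combinations(cohort.eps_table, cohort.drugs, cohort.network, k=3)
block = noms[(noms["sample"] == "CL01") & (noms["anchor"] == "capivasertib")]
print("\nnominated combination partners for capivasertib in CL01:")
print(block[["partner", "target_entity", "rank"]].to_string(index=False))
# partners are ordered by the best EPS rank achieved by any of their targets.
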