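"""Does the disease contrast mimic the aging contrast?

From one simulated study, two contrasts are formed against the same young
controls: symptomatic carriers (the disease signal) and elderly controls
(the aging signal).  Because the planted trend genes drift with age in both
cohorts, the two contrasts should share significant genes that move in the
same direction.  The pathway-set overlap arithmetic is shown alongside.
"""

import myoaging as ma

cfg = ma.SimulationConfig(
    n_genes=600, n_control=60, n_carrier=30,
    fractions={"null": 0.5, "concordant": 0.3, "accelerated": 0.1, "decelerated": 0.1},
    seed=1,
)
expr, meta, annot, _ = ma.generate_transcriptome_cohorts(cfg)
genes = ma.collapse_to_genes(expr, annot)

# one shared reference group: young controls
meta["group"] = "other"
meta.loc[(meta["cohort"] == "control") & (meta["age_years"] < 40), "group"] = "young"
meta.loc[(meta["cohort"] == "control") & (meta["age_years"] > 70), "group"] = "elderly"
meta.loc[(meta["cohort"] == "carrier") & (meta["age_years"] > 55), "group"] = "disease"
print(meta["group"].value_counts().to_string())

de_disease = ma.differential_expression(genes, meta, ("disease", "young"), group_col="group")
de_aging = ma.differential_expression(genes, meta, ("elderly", "young"), group_col="group")

r = ma.overlap_concordance(de_disease, de_aging, p_threshold=0.01)
print(f"\nsignificant: {r.n_a} (disease), {r.n_b} (aging); overlap {r.n_overlap}")
if r.pct_same_direction is not None:
    print(f"{r.pct_same_direction:.0f}% of overlapping genes agree in direction; "
          f"{r.pct_down_of_concordant:.0f}% of the agreeing genes are down-regulated")

print(f"pathway overlap: {ma.pathway_overlap_percent(75, 3):.0f}% "
      "(72 of 75 reference pathways recovered)")
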