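"""Validation-assay arithmetic: ΔΔCt fold changes, fusion index, JC-1 ratio."""

import pandas as pd

import myoaging as ma

# qPCR: three knockdown groups with planted fold changes vs a reference
qpcr = ma.generate_qpcr_table(
    {"control": 1.0, "sh_strong": 0.3, "sh_mild": 0.8}, "control", ct_sd=0.15, seed=2
)
_, summary = ma.ddct_fold_change(qpcr, "control")
print("ddct group fold changes (planted 1.0 / 0.3 / 0.8):")
print(summary[["n", "mean_ddct", "fold_change"]].round(3).to_string())

# fusion: percent of nuclei inside fused, MHC-positive myotubes
counts = pd.DataFrame(
    {
        "sample_id": ["control", "sh_mild", "sh_strong"],
        "n_nuclei_total": [412, 388, 405],
        "n_nuclei_in_positive_objects": [289, 214, 97],
        "n_myotubes": [41, 38, 22],
    }
)
print("\nfusion index (% nuclei in fused myotubes):")
print(ma.fusion_index(counts)[["sample_id", "fusion_index_pct",
                               "nuclei_per_myotube"]].round(1).to_string(index=False))

# JC-1: red/green ratio per perinuclear compartment, lower = depolarized
jc1 = pd.DataFrame(
    {
        "sample_id": ["control"] * 3 + ["sh_strong"] * 3,
        "red_intensity": [210.0, 190.0, 205.0, 90.0, 0.0, 85.0],
        "green_intensity": [100.0, 95.0, 0.0, 100.0, 110.0, 95.0],
    }
)
_, jc1_summary = ma.jc1_ratio(jc1)
print("\nJC-1 red/green summary (zero-green compartments excluded):")
print(jc1_summary.round(2).to_string())
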