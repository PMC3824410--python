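"""Literature-association enrichment of a gene set via weight CDFs.

Weights are normalized to each concept's maximum; the gene set's CDF is
compared against the background of all measured genes with a two-sample
Kolmogorov-Smirnov test.  A right-shifted CDF (large D, tiny p) means the
set's genes are unusually strongly tied to the concept's literature.
"""

import myoaging as ma

genes = list(range(1, 401))
planted = set(range(1, 61))  # the genes we pretend came out of the DE stage
raw = ma.generate_concept_weights(genes, planted, seed=3)
weights = ma.normalize_weights(raw)

result = ma.enrich_concepts(weights, planted)
print(result.round(4).to_string())

aging = weights[weights["concept"] == "aging"]
cdf = ma.concept_cdf(aging.loc[aging["gene_id"].isin(planted), "normalized_weight"])
print(f"\ngene-set CDF for 'aging' has {len(cdf)} steps; "
      f"median normalized weight {cdf['weight'].iloc[len(cdf) // 2]:.2f}")
# only the planted concept should clear the p < 1e-3 significance gate
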