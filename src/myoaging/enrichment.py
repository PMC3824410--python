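"""Literature-association concept enrichment.

Each gene carries a text-mining association weight to a biological concept
(aging, muscle contraction, ...).  Within a concept, weights are normalized
to the concept's maximum; the empirical CDF of normalized weights over a
gene set is compared to a reference distribution with a Kolmogorov-Smirnov
test.  A gene set whose weight CDF is right-shifted relative to the
background is enriched for the concept: its genes are more strongly tied to
the concept's literature than measured genes at large.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SIGNIFICANCE_THRESHOLD = 1e-3


@dataclass
class EnrichmentResult:
    concept: str
    ks_d: float
    p_value: float
    n_geneset: int
    n_background: int
    mode: str  # "two-sample" or "uniform"

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_THRESHOLD


def normalize_weights(weights: pd.DataFrame) -> pd.DataFrame:
    """Add ``normalized_weight`` = raw_weight / max(raw_weight) per concept.

    Expects a tidy table with columns gene_id, concept, raw_weight; raises if
    any concept has all-zero (or negative) weights.
    """
    w = weights.copy()
    if (w["raw_weight"] < 0).any():
        raise ValueError("raw weights must be >= 0")
    maxima = w.groupby("concept")["raw_weight"].transform("max")
    dead = w.loc[maxima == 0, "concept"].unique()
    if len(dead):
        raise ValueError(f"all-zero association weights for concepts: {list(dead)}")
    w["normalized_weight"] = w["raw_weight"] / maxima
    return w


def filter_enrichment_genes(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    weights: pd.Series,
    w_min: float = 0.1,
    p_max: float = 0.05,
) -> list:
    """Drop genes that are both weakly associated and insignificant everywhere.

    A gene is excluded only when its normalized weight is below ``w_min``
    AND its p-value exceeds ``p_max`` in *both* DE tables (the exclusion is a
    conjunction); everything else is retained.  ``weights`` maps gene_id to
    normalized weight; genes missing from it count as weight 0.
    """
    genes = de_a.index.intersection(de_b.index)
    w = weights.reindex(genes).fillna(0.0)
    weak = w < w_min
    insignificant = (de_a.loc[genes, "p"] > p_max) & (de_b.loc[genes, "p"] > p_max)
    keep = ~(weak & insignificant)
    retained = list(genes[keep])
    logger.info("filter_enrichment_genes: retained %d of %d genes", len(retained), len(genes))
    if not retained:
        raise ValueError("enrichment filter removed every gene; nothing to test")
    return retained


def concept_cdf(weights) -> pd.DataFrame:
    """Empirical CDF of a gene set's weights as a right-continuous step
    function: for each distinct weight, the fraction of genes with weight <=
    it.  Ties collapse to one step; the last value is exactly 1."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty gene set")
    values, counts = np.unique(w, return_counts=True)
    return pd.DataFrame(
        {"weight": values, "cumulative_fraction": np.cumsum(counts) / w.size}
    )


def ks_enrichment(
    geneset_weights,
    reference="uniform",
    concept: str = "",
    exact: bool = False,
) -> EnrichmentResult:
    """Kolmogorov-Smirnov comparison of a gene set's weight distribution
    against a reference.

    ``reference`` is either an array of background weights (two-sample mode,
    D = sup |F_geneset - F_background|) or the string ``"uniform"``
    (one-sample mode against Uniform[0, 1]; weights must then lie in [0, 1]).
    p-values use the asymptotic Kolmogorov distribution by default; ``exact``
    switches to the exact small-sample computation.
    """
    gs = np.asarray(geneset_weights, dtype=float)
    if gs.size == 0:
        raise ValueError("empty gene set")
    method = "exact" if exact else "asymp"
    if isinstance(reference, str):
        if reference != "uniform":
            raise ValueError(f"unknown reference {reference!r}")
        if np.any((gs < 0) | (gs > 1)):
            raise ValueError("one-sample uniform mode requires weights in [0, 1]")
        res = stats.kstest(gs, "uniform", method=method)
        return EnrichmentResult(concept, float(res.statistic), float(res.pvalue),
                                gs.size, 0, "uniform")
    bg = np.asarray(reference, dtype=float)
    if bg.size == 0:
        raise ValueError("empty background")
    res = stats.ks_2samp(gs, bg, method=method)
    return EnrichmentResult(concept, float(res.statistic), float(res.pvalue),
                            gs.size, bg.size, "two-sample")


def enrich_concepts(
    weights: pd.DataFrame,
    geneset,
    reference: str = "background",
    exact: bool = False,
) -> pd.DataFrame:
    """Run ks_enrichment for every concept of a normalized weight table.

    ``reference="background"`` compares the gene set against all other
    measured genes of the same concept; ``reference="uniform"`` uses the
    one-sample test.  Returns one row per concept.
    """
    geneset = set(geneset)
    rows = []
    for concept, sub in weights.groupby("concept"):
        in_set = sub["gene_id"].isin(geneset)
        gs = sub.loc[in_set, "normalized_weight"].to_numpy()
        if reference == "background":
            ref = sub.loc[~in_set, "normalized_weight"].to_numpy()
        else:
            ref = "uniform"
        r = ks_enrichment(gs, ref, concept=concept, exact=exact)
        rows.append(
            {
                "concept": concept,
                "ks_d": r.ks_d,
                "p_value": r.p_value,
                "n_geneset": r.n_geneset,
                "n_background": r.n_background,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows).set_index("concept")
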