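"""Overlap and fold-change directionality agreement between two DE contrasts,
plus pathway-set overlap arithmetic."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    """Venn counts and directionality percentages for two significant sets.

    Percentages are ``None`` (not 0) when undefined: ``pct_same_direction``
    when the overlap is empty, ``pct_down_of_concordant`` when no overlapping
    gene agrees in direction.
    """

    n_a: int
    n_b: int
    n_overlap: int
    pct_same_direction: float | None
    pct_down_of_concordant: float | None
    genes_a: list = field(default_factory=list)
    genes_b: list = field(default_factory=list)
    genes_overlap: list = field(default_factory=list)
    genes_same_direction: list = field(default_factory=list)
    n_zero_fc_excluded: int = 0


def overlap_concordance(
    de_a: pd.DataFrame, de_b: pd.DataFrame, p_threshold: float = 0.01
) -> OverlapResult:
    """Intersect the significant genes of two DE tables and measure how often
    the fold change points the same way.

    A gene is significant when p <= p_threshold in its table.  Genes with a
    log2 fold change of exactly 0 in either table have no direction; they are
    excluded from the percentages and counted in ``n_zero_fc_excluded``.
    """
    sig_a = de_a.index[de_a["p"] <= p_threshold]
    sig_b = de_b.index[de_b["p"] <= p_threshold]
    overlap = sig_a.intersection(sig_b)

    fc_a = de_a.loc[overlap, "log2fc"]
    fc_b = de_b.loc[overlap, "log2fc"]
    nonzero = (fc_a != 0) & (fc_b != 0)
    n_zero_excluded = int((~nonzero).sum())
    if n_zero_excluded:
        logger.info("overlap_concordance: excluded %d zero-FC genes from direction percentages",
                    n_zero_excluded)
    same = nonzero & (np.sign(fc_a) == np.sign(fc_b))
    down = same & (fc_a < 0)

    directional = int(nonzero.sum())
    pct_same = 100.0 * same.sum() / directional if directional else None
    pct_down = 100.0 * down.sum() / same.sum() if same.sum() else None
    return OverlapResult(
        n_a=len(sig_a),
        n_b=len(sig_b),
        n_overlap=len(overlap),
        pct_same_direction=pct_same,
        pct_down_of_concordant=pct_down,
        genes_a=list(sig_a),
        genes_b=list(sig_b),
        genes_overlap=list(overlap),
        genes_same_direction=list(overlap[same.to_numpy()]),
        n_zero_fc_excluded=n_zero_excluded,
    )


def pathway_overlap_percent(n_reference: int, n_missing: int) -> float:
    """Percent of a reference pathway set recovered: 100*(ref-missing)/ref."""
    if n_reference <= 0:
        raise ValueError("n_reference must be > 0")
    if not 0 <= n_missing <= n_reference:
        raise ValueError("n_missing must lie in [0, n_reference]")
    return 100.0 * (n_reference - n_missing) / n_reference
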