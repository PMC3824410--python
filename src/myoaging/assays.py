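"""Deterministic calculators for the validation assays.

* ΔΔCt relative quantification: fold change = 2^(−ΔΔCt), with
  ΔCt = target Ct − housekeeping Ct and ΔΔCt measured against the mean ΔCt
  of a reference group (amplification efficiency fixed at 2).
* Myotube fusion index: the percentage of nuclei inside myosin-heavy-chain-
  positive (fused) objects; a nuclei-per-myotube ratio is provided as a
  secondary readout when myotube counts are available.
* JC-1 ratio: red (aggregate) to green (monomer) fluorescence per
  perinuclear compartment, a proxy for mitochondrial membrane potential.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def ddct_fold_change(
    qpcr: pd.DataFrame, reference_group: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample ΔΔCt fold changes against a reference group.

    ``qpcr`` needs columns sample_id, group, target_ct, housekeeping_ct.
    Returns (per_sample, per_group): the per-sample table adds delta_ct,
    ddct and fold_change; the per-group summary reports the group mean ΔΔCt,
    the group fold change 2^(−mean ΔΔCt) and the mean/SD of per-sample fold
    changes.
    """
    q = qpcr.copy()
    for col in ("target_ct", "housekeeping_ct"):
        vals = pd.to_numeric(q[col], errors="coerce")
        if vals.isna().any() or not np.isfinite(vals).all():
            bad = q.loc[~np.isfinite(vals), "sample_id"].tolist()
            raise ValueError(f"missing or non-finite {col} for samples: {bad}")
        q[col] = vals
    ref = q[q["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} is empty")

    q["delta_ct"] = q["target_ct"] - q["housekeeping_ct"]
    ref_mean = ref["target_ct"].mean() - ref["housekeeping_ct"].mean()
    q["ddct"] = q["delta_ct"] - ref_mean
    q["fold_change"] = 2.0 ** (-q["ddct"])

    summary = q.groupby("group").agg(
        n=("sample_id", "size"),
        mean_ddct=("ddct", "mean"),
        fc_mean=("fold_change", "mean"),
        fc_sd=("fold_change", "std"),
    )
    summary["fold_change"] = 2.0 ** (-summary["mean_ddct"])
    return q, summary


def fusion_index(counts: pd.DataFrame) -> pd.DataFrame:
    """Percent of nuclei inside fused, MHC-positive objects, per sample.

    ``counts`` needs columns sample_id, n_nuclei_total and
    n_nuclei_in_positive_objects; an optional n_myotubes column adds the
    secondary nuclei-per-myotube ratio.
    """
    c = counts.copy()
    if (c["n_nuclei_total"] <= 0).any():
        bad = c.loc[c["n_nuclei_total"] <= 0, "sample_id"].tolist()
        raise ValueError(f"zero total nuclei for samples: {bad}")
    if ((c["n_nuclei_in_positive_objects"] < 0)
            | (c["n_nuclei_in_positive_objects"] > c["n_nuclei_total"])).any():
        raise ValueError("positive-object nuclei counts must lie in [0, total]")
    c["fusion_index_pct"] = 100.0 * c["n_nuclei_in_positive_objects"] / c["n_nuclei_total"]
    if "n_myotubes" in c.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            c["nuclei_per_myotube"] = np.where(
                c["n_myotubes"] > 0,
                c["n_nuclei_in_positive_objects"] / c["n_myotubes"],
                np.nan,
            )
    return c


def jc1_ratio(
    compartments: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Red/green intensity ratio per perinuclear compartment and per-sample
    summary.

    Compartments with zero green (monomer) signal have an undefined ratio;
    they are excluded from the summary and counted.  ``compartments`` needs
    columns sample_id, red_intensity, green_intensity.
    """
    c = compartments.copy()
    if ((c["red_intensity"] < 0) | (c["green_intensity"] < 0)).any():
        raise ValueError("intensities must be >= 0")
    valid = c["green_intensity"] > 0
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("jc1_ratio: excluded %d zero-green compartments", n_excluded)
    if not valid.any():
        raise ValueError("every compartment has zero green signal; no ratio defined")
    c.loc[valid, "ratio"] = c.loc[valid, "red_intensity"] / c.loc[valid, "green_intensity"]

    summary = (
        c[valid]
        .groupby("sample_id")["ratio"]
        .agg(n="size", mean="mean", sd=lambda r: r.std(ddof=1) if len(r) > 1 else 0.0)
    )
    summary["n_excluded"] = (
        c[~valid].groupby("sample_id").size().reindex(summary.index, fill_value=0)
    )
    return c, summary
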