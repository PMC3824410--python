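"""Expression-bundle I/O, quantile normalization and probe-to-gene collapsing.

Conventions used throughout the package:

* an *expression matrix* is a :class:`pandas.DataFrame` of log2 intensities
  with one row per probe (or gene after collapsing) and one column per
  sample; index and columns are unique identifiers;
* *sample metadata* is a DataFrame with columns ``sample_id``, ``age_years``,
  ``sex`` (``male``/``female``), ``cohort`` (``control``/``carrier``),
  ``stage`` and ``tissue``;
* *probe annotation* is a DataFrame with columns ``probe_id``, ``gene_id``
  (stable numeric, Entrez-style) and ``symbol``.

All three are plain TSV files on disk (UTF-8, ``.`` decimal separator,
header row; the matrix carries probe ids in its first column).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("sample_id", "age_years", "sex", "cohort", "stage", "tissue")
ANNOTATION_COLUMNS = ("probe_id", "gene_id", "symbol")


class BundleError(ValueError):
    """Raised when an expression bundle violates its contract."""


def _check_unique(values, what: str) -> None:
    dup = pd.Index(values)[pd.Index(values).duplicated()].unique().tolist()
    if dup:
        raise BundleError(f"duplicated {what}: {dup}")


def validate_expression(expr: pd.DataFrame) -> None:
    """Check the expression-matrix invariants (unique ids, finite values)."""
    _check_unique(expr.index, "probe/gene identifiers")
    _check_unique(expr.columns, "sample identifiers")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.isfinite(values).all():
        bad = expr.index[~np.isfinite(expr.apply(pd.to_numeric, errors="coerce")).all(axis=1)]
        raise BundleError(f"non-finite or non-numeric expression values in rows: {list(bad[:10])}")


def read_expression_bundle(
    expr_path: str | Path,
    meta_path: str | Path,
    annot_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load a (matrix, metadata, annotation) TSV triple and cross-validate it.

    Rows of the matrix with unparseable numeric fields are rejected with an
    error naming them, never silently dropped.  Samples present in the matrix
    but absent from the metadata are an error listing the orphans.
    """
    for p in (expr_path, meta_path, annot_path):
        if not Path(p).is_file():
            raise FileNotFoundError(p)

    raw = pd.read_csv(expr_path, sep="\t", index_col=0, dtype=str)
    _check_unique(raw.index, "probe identifiers")
    _check_unique(raw.columns, "sample identifiers")
    expr = raw.apply(pd.to_numeric, errors="coerce")
    bad = expr.index[expr.isna().any(axis=1)]
    if len(bad):
        raise BundleError(f"unparseable numeric fields in matrix rows: {list(bad[:10])}")
    validate_expression(expr)

    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise BundleError(f"metadata missing columns: {missing_cols}")
    _check_unique(meta["sample_id"], "metadata sample_id")
    if not np.isfinite(pd.to_numeric(meta["age_years"], errors="coerce")).all():
        raise BundleError("metadata age_years contains non-finite values")

    orphans = sorted(set(expr.columns) - set(meta["sample_id"]))
    if orphans:
        raise BundleError(f"samples in matrix but absent from metadata: {orphans}")

    annot = pd.read_csv(annot_path, sep="\t", dtype={"probe_id": str, "symbol": str})
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in annot.columns]
    if missing_cols:
        raise BundleError(f"annotation missing columns: {missing_cols}")
    _check_unique(annot["probe_id"], "annotation probe_id")

    return expr, meta, annot


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common distribution of row-rank means.

    Each column is sorted, the reference distribution is the mean across
    columns at every rank, and each value is replaced by the reference value
    at its within-column rank.  Tied values within a column receive the mean
    of the tied positions' rank-means, which makes the transform deterministic
    and idempotent.
    """
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("quantile_normalize requires finite input values")
    n_rows, n_cols = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_cols):
        order = np.argsort(values[:, j], kind="stable")
        sorted_col = values[order, j]
        # mean of rank-means over each block of tied values
        tied_means = pd.Series(reference).groupby(pd.Series(sorted_col)).transform("mean")
        out[order, j] = tied_means.to_numpy()
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def collapse_to_genes(expr: pd.DataFrame, annot: pd.DataFrame) -> pd.DataFrame:
    """Collapse probes to genes, keeping per gene the probe with the highest
    mean expression (ties broken by lexicographically smallest probe id).

    Unannotated probes are dropped with a logged count.  The result is keyed
    by ``gene_id``.
    """
    mapping = annot.set_index("probe_id")["gene_id"]
    annotated = expr.index.intersection(mapping.index)
    if len(annotated) == 0:
        raise BundleError("no probe of the matrix is covered by the annotation")
    n_dropped = expr.shape[0] - len(annotated)
    if n_dropped:
        logger.info("collapse_to_genes: dropped %d unannotated probes", n_dropped)

    sub = expr.loc[annotated]
    means = sub.mean(axis=1)
    chooser = pd.DataFrame(
        {
            "gene_id": mapping.loc[annotated].to_numpy(),
            "mean": means.to_numpy(),
            "probe_id": annotated,
        }
    )
    # highest mean wins; ties resolved by smallest probe_id
    chooser = chooser.sort_values(["gene_id", "mean", "probe_id"], ascending=[True, False, True])
    winners = chooser.drop_duplicates("gene_id", keep="first")
    collapsed = sub.loc[winners["probe_id"]]
    collapsed.index = pd.Index(winners["gene_id"].to_numpy(), name="gene_id")
    return collapsed.sort_index()
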