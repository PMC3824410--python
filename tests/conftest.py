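import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def tiny_bundle(tmp_path):
    """Write a minimal consistent (expr, meta, annot) TSV triple to disk."""

    def _write(expr=None, meta=None, annot=None):
        if expr is None:
            expr = pd.DataFrame(
                {"s1": [1.0, 2.0, 3.0], "s2": [2.0, 4.0, 6.0]},
                index=pd.Index(["p1", "p2", "p3"], name="probe_id"),
            )
        if meta is None:
            meta = pd.DataFrame(
                {
                    "sample_id": list(expr.columns),
                    "age_years": np.linspace(30, 70, expr.shape[1]),
                    "sex": ["male", "female"][: expr.shape[1]],
                    "cohort": ["control"] * expr.shape[1],
                    "stage": ["none"] * expr.shape[1],
                    "tissue": ["vastus lateralis"] * expr.shape[1],
                }
            )
        if annot is None:
            annot = pd.DataFrame(
                {
                    "probe_id": list(expr.index),
                    "gene_id": range(101, 101 + expr.shape[0]),
                    "symbol": [f"G{i}" for i in range(expr.shape[0])],
                }
            )
        paths = (tmp_path / "expr.tsv", tmp_path / "meta.tsv", tmp_path / "annot.tsv")
        expr.to_csv(paths[0], sep="\t")
        meta.to_csv(paths[1], sep="\t", index=False)
        annot.to_csv(paths[2], sep="\t", index=False)
        return paths

    return _write


def make_de_table(entries):
    """Build a DE-shaped DataFrame from {gene: (log2fc, p)}."""
    genes = list(entries)
    fc = [entries[g][0] for g in genes]
    p = [entries[g][1] for g in genes]
    return pd.DataFrame(
        {
            "log2fc": fc,
            "t": fc,
            "p": p,
            "q": p,
            "mean_a": 0.0,
            "mean_b": 0.0,
        },
        index=pd.Index(genes, name="gene_id"),
    )
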