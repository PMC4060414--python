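"""RPKM computation and low/high expression binning.

RPKM = 1e9 * C / (N * L): reads per kilobase of exon model per million
mapped reads, for a gene with C mapped reads, exon-model length L bases and
a library of N mapped reads.  Genes are binned low (RPKM <= 1, including no
expression) versus high (RPKM > 1).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

LOW, HIGH = "low", "high"


def compute_rpkm(count: float, total_reads: float, exon_model_length: float) -> float:
    if total_reads <= 0:
        raise ValueError("total mapped reads must be > 0")
    if exon_model_length <= 0:
        raise ValueError("exon model length must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return 1e9 * count / (total_reads * exon_model_length)


def bin_expression(rpkm: float) -> str:
    """Low (RPKM <= 1, including zero) versus high (RPKM > 1)."""
    if rpkm < 0:
        raise ValueError("RPKM must be >= 0")
    return LOW if rpkm <= 1.0 else HIGH


def expression_table(
    counts: pd.DataFrame, total_reads: int | None = None
) -> pd.DataFrame:
    """Add RPKM and expression bin to a counts table.

    ``counts`` needs gene_id / count / exon_model_length columns.  The
    library size N defaults to the column total of mapped reads over the
    genes in the table (the per-library mapped total is rarely recoverable
    from a counts table alone); pass ``total_reads`` to override.
    """
    out = counts.copy()
    N = int(out["count"].sum()) if total_reads is None else int(total_reads)
    if N <= 0:
        raise ValueError("library has zero mapped reads")
    L = out["exon_model_length"].to_numpy(dtype=np.float64)
    if (L <= 0).any():
        raise ValueError("all exon model lengths must be > 0")
    out["rpkm"] = 1e9 * out["count"].to_numpy(dtype=np.float64) / (N * L)
    out["bin"] = np.where(out["rpkm"] > 1.0, HIGH, LOW)
    return out


def expression_summary(table: pd.DataFrame) -> dict:
    """Detected-gene count/fraction, medians and range of RPKM.

    "Detected" means RPKM > 0.  The median is reported both over all genes
    (zeros included) and over detected genes only.
    """
    if len(table) == 0:
        raise ValueError("empty expression table")
    rpkm = table["rpkm"].to_numpy()
    detected = rpkm > 0
    return {
        "n_genes": len(table),
        "n_detected": int(detected.sum()),
        "detected_fraction": float(detected.mean()),
        "median_rpkm_all": float(np.median(rpkm)),
        "median_rpkm_detected": float(np.median(rpkm[detected])) if detected.any() else 0.0,
        "min_rpkm": float(rpkm.min()),
        "max_rpkm": float(rpkm.max()),
    }
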