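"""Methylation-class x expression-bin contingency tables and the
chi-squared independence test.

For gene bodies, and separately for filtered promoters (>= 10 CpGs, no gene
overlap), each qualifying gene contributes one cell of a 3 x 2 table: rows
unmethylated / sparsely / heavily methylated, columns low (RPKM <= 1) and
high (RPKM > 1) expression.  The null of randomly distributed methylation is
operationalised as the standard independence expectation from the marginals;
the test statistic is Pearson's X^2 with df = (3-1)(2-1) = 2 and no
continuity correction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression_analysis import HIGH, LOW
from .methylation_summary import (
    REGION_CLASSES,
    REGION_HEAVY,
    REGION_NO_DATA,
    REGION_SPARSE,
    REGION_UNMETH,
)

ROW_ORDER = (REGION_UNMETH, REGION_SPARSE, REGION_HEAVY)
COL_ORDER = (LOW, HIGH)


@dataclass
class ContingencyTable:
    """3 x 2 table of gene counts: methylation class rows, expression bins
    columns, plus a record of how many genes were excluded and why."""

    observed: np.ndarray
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=np.int64)
        if self.observed.shape != (3, 2):
            raise ValueError("contingency table must be 3 rows x 2 columns")
        if (self.observed < 0).any():
            raise ValueError("cell counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.observed.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.observed.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.observed.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.observed, index=list(ROW_ORDER), columns=list(COL_ORDER))

    def proportions_by_bin(self) -> pd.DataFrame:
        """Per expression bin, the proportion of genes in each methylation
        class (columns sum to 1)."""
        totals = self.col_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.observed / totals
        return pd.DataFrame(p, index=list(ROW_ORDER), columns=list(COL_ORDER))


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def build_contingency(
    regions: pd.DataFrame,
    expression: pd.DataFrame,
    min_cpg: int = 0,
    region_id: str = "gene_id",
) -> ContingencyTable:
    """Cross gene-level methylation classes with expression bins.

    ``regions`` is a region-methylation table (region_class column,
    optionally n_cpg for the promoter CpG-content filter); ``expression``
    carries gene_id and bin.  Genes lacking either side, classed no_data, or
    failing the ``min_cpg`` filter are tallied in the exclusion record, not
    silently dropped.
    """
    excl: dict[str, int] = {}
    reg = regions.copy()
    if min_cpg > 0:
        if "n_cpg" not in reg.columns:
            raise ValueError("min_cpg filter requires an n_cpg column")
        drop = reg["n_cpg"] < min_cpg
        excl["below_min_cpg"] = int(drop.sum())
        reg = reg[~drop]
    nd = reg["region_class"] == REGION_NO_DATA
    excl["region_no_data"] = int(nd.sum())
    reg = reg[~nd]
    merged = reg[[region_id, "region_class"]].merge(
        expression[["gene_id", "bin"]], left_on=region_id, right_on="gene_id", how="left"
    )
    no_expr = merged["bin"].isna()
    excl["no_expression"] = int(no_expr.sum())
    excl["region_missing"] = int(
        (~expression["gene_id"].isin(reg[region_id])).sum()
    )
    merged = merged[~no_expr]
    if len(merged) == 0:
        raise ValueError("no genes remain after filtering")
    obs = np.zeros((3, 2), dtype=np.int64)
    for i, rc in enumerate(ROW_ORDER):
        for j, b in enumerate(COL_ORDER):
            obs[i, j] = int(((merged["region_class"] == rc) & (merged["bin"] == b)).sum())
    return ContingencyTable(obs, excl)


def chi_squared_test(table: ContingencyTable, alpha: float = 0.05) -> ChiSquareResult:
    """Pearson chi-squared test of independence on the 3 x 2 table.

    Expected cells come from the product of marginals over the grand total;
    df = 2; no continuity correction.  A zero row or column marginal makes
    an expected cell zero and raises (pool sparse classes before testing).
    """
    obs = table.observed
    if (table.row_totals == 0).any() or (table.col_totals == 0).any():
        raise ValueError(
            "zero marginal gives an expected cell of 0; pool rows/columns before testing"
        )
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p), alpha=alpha)


def association_report(
    gene_table: ContingencyTable,
    promoter_table: ContingencyTable,
    alpha: float = 0.05,
) -> dict:
    """Proportions of methylation classes per expression bin and the
    chi-squared results for gene bodies and promoters."""
    out = {}
    for scope, table in (("gene_body", gene_table), ("promoter", promoter_table)):
        res = chi_squared_test(table, alpha=alpha)
        out[scope] = {
            "observed": table.to_frame(),
            "proportions": table.proportions_by_bin(),
            "chi2": res,
            "n_genes": table.total,
            "exclusions": dict(table.exclusions),
        }
    return out
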