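"""Locus and region methylation classification and genome-wide summaries.

The classification rule: a CpG locus is considered methylated when it has at
least 5x (strand-combined) coverage and at least half of the reads remained
unconverted.  Covered loci below the 0.5 ratio split into sparsely
methylated (0 < ratio < 0.5) and unmethylated (ratio = 0); loci under the
coverage floor are "no data".  Regions (genes, promoters) are classified by
the fraction of their covered CpGs that are methylated, with the same 0 /
(0, 0.5) / >= 0.5 thresholds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_annotation import intersect

METHYLATED = "methylated"
SPARSE = "sparsely_methylated"
UNMETHYLATED = "unmethylated"
NO_DATA = "no_data"
LOCUS_CLASSES = (UNMETHYLATED, SPARSE, METHYLATED, NO_DATA)

REGION_HEAVY = "heavily"
REGION_SPARSE = "sparsely"
REGION_UNMETH = "unmethylated"
REGION_NO_DATA = "no_data"
REGION_CLASSES = (REGION_UNMETH, REGION_SPARSE, REGION_HEAVY)


@dataclass
class ClassificationThresholds:
    min_coverage: int = 5
    methylated_min_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0.0 < self.methylated_min_ratio <= 1.0:
            raise ValueError("methylated_min_ratio must be in (0, 1]")


def classify_locus(n: int, m: int, t: ClassificationThresholds | None = None) -> str:
    """Class of one strand-combined CpG locus from coverage n and
    unconverted count m ("at least" semantics at both thresholds)."""
    t = t or ClassificationThresholds()
    if n < 0 or m < 0 or m > n:
        raise ValueError(f"invalid counts n={n}, m={m}")
    if n < t.min_coverage:
        return NO_DATA
    r = m / n
    if r >= t.methylated_min_ratio:
        return METHYLATED
    if r == 0.0:
        return UNMETHYLATED
    return SPARSE


def classify_sites(
    sites: pd.DataFrame, t: ClassificationThresholds | None = None
) -> pd.DataFrame:
    """Vectorised :func:`classify_locus` over a CpG table (columns n, m,
    ratio); returns a copy with a ``locus_class`` column."""
    t = t or ClassificationThresholds()
    out = sites.copy()
    n = out["n"].to_numpy()
    r = out["m"].to_numpy() / np.maximum(n, 1)
    cls = np.full(len(out), NO_DATA, dtype=object)
    covered = n >= t.min_coverage
    cls[covered & (r >= t.methylated_min_ratio)] = METHYLATED
    cls[covered & (r > 0) & (r < t.methylated_min_ratio)] = SPARSE
    cls[covered & (r == 0)] = UNMETHYLATED
    out["locus_class"] = cls
    return out


def region_methylation(
    regions: pd.DataFrame,
    sites: pd.DataFrame,
    t: ClassificationThresholds | None = None,
    denominator: str = "covered",
    region_id: str = "gene_id",
) -> pd.DataFrame:
    """Per-region CpG tallies and methylation class.

    ``regions`` needs scaffold/start/end plus an identifier column; ``sites``
    is a (classified or raw) strand-combined CpG table.  The region ratio is
    the number of methylated CpGs over the denominator CpGs in the region:
    with ``denominator='covered'`` (default) only CpGs meeting the coverage
    floor count, with ``'all'`` every genomic CpG counts.  Regions whose
    denominator is zero are classed no_data.
    """
    t = t or ClassificationThresholds()
    if denominator not in ("covered", "all"):
        raise ValueError("denominator must be 'covered' or 'all'")
    if "locus_class" not in sites.columns:
        sites = classify_sites(sites, t)
    pts = pd.DataFrame(
        {
            "scaffold": sites["scaffold"],
            "start": sites["position"],
            "end": sites["position"] + 1,
        }
    )
    hits = intersect(pts, regions)
    n_total = np.zeros(len(regions), dtype=np.int64)
    n_meth = np.zeros(len(regions), dtype=np.int64)
    if len(hits):
        cls = sites["locus_class"].to_numpy()[hits["query_index"].to_numpy()]
        ridx = hits["subject_index"].to_numpy()
        in_denominator = cls != NO_DATA if denominator == "covered" else np.ones(len(cls), bool)
        np.add.at(n_total, ridx[in_denominator], 1)
        np.add.at(n_meth, ridx[cls == METHYLATED], 1)
    out = regions.reset_index(drop=True).copy()
    out["n_cpg_total"] = n_total
    out["n_methylated"] = n_meth
    with np.errstate(invalid="ignore"):
        out["meth_ratio"] = np.where(n_total > 0, n_meth / np.maximum(n_total, 1), np.nan)
    rc = np.full(len(out), REGION_NO_DATA, dtype=object)
    has = n_total > 0
    r = out["meth_ratio"].to_numpy()
    rc[has & (r >= t.methylated_min_ratio)] = REGION_HEAVY
    rc[has & (r > 0) & (r < t.methylated_min_ratio)] = REGION_SPARSE
    rc[has & (r == 0)] = REGION_UNMETH
    out["region_class"] = rc
    if region_id in out.columns:
        cols = [region_id] + [c for c in out.columns if c != region_id]
        out = out[cols]
    return out


def ratio_histogram(
    sites: pd.DataFrame,
    t: ClassificationThresholds | None = None,
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Binned counts of methylation ratios over sufficiently covered CpGs.

    Bins cover [0, 1] with the last bin closed on the right; the bin totals
    sum to the number of loci at or above the coverage floor.
    """
    t = t or ClassificationThresholds()
    covered = sites[sites["n"] >= t.min_coverage]
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    counts, _ = np.histogram(covered["ratio"].to_numpy(), bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def feature_distribution(
    classified: pd.DataFrame,
    tracks: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per-feature-track proportions of the four locus classes.

    Every CpG of the input table (including uncovered, no-data loci) is
    intersected with each track independently; a CpG lying in two tracks
    counts once in each (per-track accounting, not a partition).
    Proportions per track sum to 1.
    """
    pts = pd.DataFrame(
        {
            "scaffold": classified["scaffold"],
            "start": classified["position"],
            "end": classified["position"] + 1,
        }
    )
    cls = classified["locus_class"].to_numpy()
    rows = []
    for name, track in tracks.items():
        hits = intersect(pts, track)
        idx = np.unique(hits["query_index"].to_numpy()) if len(hits) else np.empty(0, int)
        sub = cls[idx]
        total = len(sub)
        row = {"track": name, "n_cpg": total}
        for c in LOCUS_CLASSES:
            row[c] = float((sub == c).sum() / total) if total else (1.0 if c == NO_DATA else 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
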