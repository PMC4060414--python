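"""CpG enumeration, intron/promoter derivation and interval intersection.

The feature tracks built here (exons, introns, 1 kb upstream promoters,
transposable elements) are what classified CpG loci get intersected against
to produce per-feature methylation landscapes, and what the promoter
filtering for the methylation-expression association relies on.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel, GenomicInterval


@dataclass
class PromoterConfig:
    """Promoter definition: the ``upstream_length`` bases immediately 5' of
    the transcription start site, strand-aware.

    ``min_cpg`` (default 10) is the minimum CpG content a promoter needs to
    enter the methylation-expression association; it is not applied here.
    ``exclude_gene_overlap`` drops promoters that overlap any annotated gene.
    ``keep_truncated`` keeps promoters clipped at scaffold edges (flagged).
    """

    upstream_length: int = 1000
    min_cpg: int = 10
    exclude_gene_overlap: bool = True
    keep_truncated: bool = True

    def __post_init__(self) -> None:
        if self.upstream_length <= 0:
            raise ValueError("upstream_length must be > 0")
        if self.min_cpg < 0:
            raise ValueError("min_cpg must be >= 0")


def enumerate_cpg(genome: dict[str, str]) -> dict[str, np.ndarray]:
    """Positions of every plus-strand CG dinucleotide per scaffold.

    Returns the 0-based position of the C.  A CpG is palindromic, so one
    record covers both strands; Ns never form part of a CpG.
    """
    out: dict[str, np.ndarray] = {}
    for scaf, seq in genome.items():
        a = np.frombuffer(seq.encode(), dtype=np.uint8)
        if a.size < 2:
            out[scaf] = np.empty(0, dtype=np.int64)
            continue
        hits = (a[:-1] == ord("C")) & (a[1:] == ord("G"))
        out[scaf] = np.nonzero(hits)[0].astype(np.int64)
    return out


def derive_introns(gene: GeneModel) -> list[GenomicInterval]:
    """Introns are exactly the gaps between consecutive exons."""
    introns: list[GenomicInterval] = []
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        if s2 < e1:
            raise ValueError(f"{gene.gene_id}: overlapping exons [{s1},{e1}) [{s2},{e2})")
        if s2 > e1:
            introns.append(
                GenomicInterval(gene.scaffold, e1, s2, gene.strand, "intron", gene.gene_id)
            )
    return introns


def feature_tracks(genes: list[GeneModel], tes: list[GenomicInterval]) -> dict[str, pd.DataFrame]:
    """Exon, intron, gene-span and TE tracks as interval DataFrames."""
    ex_rows, in_rows, gene_rows = [], [], []
    for g in genes:
        gene_rows.append((g.scaffold, g.start, g.end, g.strand, g.gene_id))
        for s, e in g.exons:
            ex_rows.append((g.scaffold, s, e, g.strand, g.gene_id))
        for iv in derive_introns(g):
            in_rows.append((iv.scaffold, iv.start, iv.end, iv.strand, g.gene_id))
    cols = ["scaffold", "start", "end", "strand", "gene_id"]
    tracks = {
        "exon": pd.DataFrame(ex_rows, columns=cols),
        "intron": pd.DataFrame(in_rows, columns=cols),
        "gene": pd.DataFrame(gene_rows, columns=cols),
    }
    tracks["TE"] = pd.DataFrame(
        [(t.scaffold, t.start, t.end, t.strand, None) for t in tes], columns=cols
    )
    return tracks


def build_promoters(
    genes: list[GeneModel],
    genome: dict[str, str],
    cfg: PromoterConfig | None = None,
) -> pd.DataFrame:
    """Derive strand-aware upstream promoter intervals with CpG counts.

    A plus-strand gene [s, e) gets promoter [s - U, s); a minus-strand gene
    gets [e, e + U).  Promoters are truncated at scaffold edges (kept and
    flagged by default).  With ``exclude_gene_overlap`` on, promoters
    overlapping any annotated gene interval are dropped — the conservative
    reading of "did not overlap with neighboring genes".

    Returns columns: gene_id, scaffold, start, end, strand, n_cpg, truncated.
    """
    cfg = cfg or PromoterConfig()
    cpgs = enumerate_cpg(genome)
    gene_df = pd.DataFrame(
        [(g.scaffold, g.start, g.end) for g in genes],
        columns=["scaffold", "start", "end"],
    )
    rows = []
    for g in genes:
        L = len(genome[g.scaffold])
        if g.strand == "+":
            start, end = g.start - cfg.upstream_length, g.start
        else:
            start, end = g.end, g.end + cfg.upstream_length
        truncated = start < 0 or end > L
        start, end = max(0, start), min(L, end)
        if start >= end:
            continue
        pos = cpgs.get(g.scaffold, np.empty(0, dtype=np.int64))
        n_cpg = int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
        rows.append((g.gene_id, g.scaffold, start, end, g.strand, n_cpg, truncated))
    prom = pd.DataFrame(
        rows,
        columns=["gene_id", "scaffold", "start", "end", "strand", "n_cpg", "truncated"],
    )
    if not cfg.keep_truncated and len(prom):
        prom = prom[~prom["truncated"]].reset_index(drop=True)
    if cfg.exclude_gene_overlap and len(prom):
        hits = intersect(prom, gene_df)
        prom = prom.drop(index=hits["query_index"].unique()).reset_index(drop=True)
    return prom


def intersect(query: pd.DataFrame, subject: pd.DataFrame) -> pd.DataFrame:
    """All (query, subject) interval pairs with >= 1 bp overlap.

    Both inputs need ``scaffold``/``start``/``end`` columns with 0-based
    half-open coordinates; a point locus is the interval [p, p + 1).
    Returns a DataFrame with ``query_index``, ``subject_index`` (positional
    row indices into the inputs) and ``overlap`` lengths.
    """
    trees: dict[str, IntervalTree] = {}
    subj = subject.reset_index(drop=True)
    for j, row in enumerate(subj.itertuples(index=False)):
        trees.setdefault(row.scaffold, IntervalTree()).addi(row.start, row.end, j)
    q = query.reset_index(drop=True)
    qi, si, ov = [], [], []
    for i, row in enumerate(q.itertuples(index=False)):
        tree = trees.get(row.scaffold)
        if tree is None:
            continue
        for hit in tree.overlap(row.start, row.end):
            qi.append(i)
            si.append(hit.data)
            ov.append(min(row.end, hit.end) - max(row.start, hit.begin))
    out = pd.DataFrame({"query_index": qi, "subject_index": si, "overlap": ov})
    return out.sort_values(["query_index", "subject_index"]).reset_index(drop=True)
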