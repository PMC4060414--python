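"""Bisulfite alignment -> per-cytosine counts -> strand-combined CpG ratios.

Reimplements the methratio-style extraction workflow: reads are placed only
where they match uniquely under the bisulfite-collapsed alphabet (C==T for
reads of the converted plus strand, G==A for the minus strand), every
covered reference cytosine is tallied (zero-methylation loci retained),
symmetric CpG counts are combined across strands before thresholding, and
conversion efficiency is estimated from a known-unmethylated control contig.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ReadAlignment, revcomp

_C, _G, _T, _A = ord("C"), ord("G"), ord("T"), ord("A")


@dataclass
class ConversionEfficiency:
    """Bisulfite conversion efficiency from a control contig: the fraction
    of cytosine read observations that were converted (read as T)."""

    converted: int
    total: int

    @property
    def efficiency(self) -> float:
        return self.converted / self.total

    @property
    def percent(self) -> float:
        return 100.0 * self.efficiency


@dataclass
class PlacementResult:
    alignments: list[ReadAlignment]
    n_placed: int
    n_ambiguous: int
    n_unmapped: int


def _collapse_ct(seq: str) -> str:
    return seq.replace("C", "T")


def _collapse_ga(seq: str) -> str:
    return seq.replace("G", "A")


class BisulfiteIndex:
    """k-mer prefix index over both bisulfite-collapsed genome strands.

    For each scaffold two collapsed strings are kept: C->T (matches reads of
    the converted Watson strand in plus orientation) and G->A (matches reads
    reporting on Crick-strand cytosines).  A read candidate position is any
    exact occurrence of its collapsed k-prefix, verified over the full read.
    """

    def __init__(self, genome: dict[str, str], k: int = 24):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("empty genome")
        self.genome = genome
        self.k = k
        self.ct = {s: _collapse_ct(seq) for s, seq in genome.items()}
        self.ga = {s: _collapse_ga(seq) for s, seq in genome.items()}
        self._idx_ct: dict[str, list[tuple[str, int]]] = {}
        self._idx_ga: dict[str, list[tuple[str, int]]] = {}
        for scaf in genome:
            for collapsed, idx in ((self.ct[scaf], self._idx_ct), (self.ga[scaf], self._idx_ga)):
                for p in range(len(collapsed) - k + 1):
                    idx.setdefault(collapsed[p : p + k], []).append((scaf, p))

    def candidates(self, read: str) -> set[tuple[str, int, str]]:
        """Unique-placement candidates (scaffold, pos, bs_strand) for a read
        across all four orientation/strand combinations."""
        out: set[tuple[str, int, str]] = set()
        rc = revcomp(read)
        # (oriented plus-strand sequence, collapsed genome dict, index, bs strand)
        modes = (
            (read, self.ct, self._idx_ct, "+"),
            (rc, self.ct, self._idx_ct, "+"),
            (read, self.ga, self._idx_ga, "-"),
            (rc, self.ga, self._idx_ga, "-"),
        )
        for oriented, coll, idx, bs in modes:
            q = _collapse_ct(oriented) if bs == "+" else _collapse_ga(oriented)
            if len(q) < self.k:
                for scaf, g in coll.items():
                    p = g.find(q)
                    while p != -1:
                        out.add((scaf, p, bs))
                        p = g.find(q, p + 1)
                continue
            for scaf, p in idx.get(q[: self.k], ()):
                if coll[scaf][p : p + len(q)] == q:
                    out.add((scaf, p, bs))
        return out


def place_reads(
    reads: list[tuple[str, str]],
    genome: dict[str, str],
    index: BisulfiteIndex | None = None,
) -> PlacementResult:
    """Place bisulfite reads by exact collapsed-alphabet matching.

    Mirrors unique-mapping-only semantics: a read with exactly one candidate
    locus across both bisulfite strands is placed; reads with several best
    placements are discarded as ambiguous and reads with none are counted
    unmapped.  Reads containing N never match (no N-tolerant matching).
    """
    if index is None:
        index = BisulfiteIndex(genome)
    alignments: list[ReadAlignment] = []
    n_amb = n_un = 0
    for rid, seq in reads:
        cands = index.candidates(seq)
        if len(cands) == 1:
            scaf, pos, bs = next(iter(cands))
            # orient the stored sequence to the plus strand
            q = _collapse_ct(seq) if bs == "+" else _collapse_ga(seq)
            coll = index.ct if bs == "+" else index.ga
            reverse = coll[scaf][pos : pos + len(seq)] != q
            oriented = revcomp(seq) if reverse else seq
            alignments.append(ReadAlignment(rid, scaf, pos, bs, oriented, reverse))
        elif len(cands) == 0:
            n_un += 1
        else:
            n_amb += 1
    return PlacementResult(alignments, len(alignments), n_amb, n_un)


def brute_force_candidates(read: str, genome: dict[str, str]) -> set[tuple[str, int, str]]:
    """All-positions scan oracle for :meth:`BisulfiteIndex.candidates`."""
    out: set[tuple[str, int, str]] = set()
    rc = revcomp(read)
    for scaf, seq in genome.items():
        for oriented, collapse, bs in (
            (read, _collapse_ct, "+"),
            (rc, _collapse_ct, "+"),
            (read, _collapse_ga, "-"),
            (rc, _collapse_ga, "-"),
        ):
            q, g = collapse(oriented), collapse(seq)
            for p in range(len(g) - len(q) + 1):
                if g[p : p + len(q)] == q:
                    out.add((scaf, p, bs))
    return out


class MethylationCounts:
    """Per-cytosine coverage/unconverted tallies for a genome.

    Holds, per scaffold, four arrays over all positions: coverage and
    unconverted counts for plus-strand cytosines (reference C) and for
    minus-strand cytosines (reference G).  Contexts (CG/CA/CT/CC) are always
    taken 5'->3' on the cytosine's own strand from the reference.
    """

    def __init__(self, genome: dict[str, str]):
        self.genome = genome
        self.n_plus: dict[str, np.ndarray] = {}
        self.m_plus: dict[str, np.ndarray] = {}
        self.n_minus: dict[str, np.ndarray] = {}
        self.m_minus: dict[str, np.ndarray] = {}
        self._isC: dict[str, np.ndarray] = {}
        self._isG: dict[str, np.ndarray] = {}
        for scaf, seq in genome.items():
            L = len(seq)
            a = np.frombuffer(seq.encode(), dtype=np.uint8)
            self._isC[scaf] = a == _C
            self._isG[scaf] = a == _G
            for d in (self.n_plus, self.m_plus, self.n_minus, self.m_minus):
                d[scaf] = np.zeros(L, dtype=np.uint32)

    def scaffolds(self) -> list[str]:
        return list(self.genome)

    def context_codes(self, scaffold: str) -> tuple[np.ndarray, np.ndarray]:
        """Downstream dinucleotide context for every position, as strings,
        for plus-strand Cs (next reference base) and minus-strand Cs
        (complement of the previous reference base).  Positions at scaffold
        edges or next to N get context 'C?'."""
        seq = self.genome[scaffold]
        a = np.frombuffer(seq.encode(), dtype=np.uint8)
        L = len(seq)
        plus = np.full(L, "C?", dtype="U2")
        minus = np.full(L, "C?", dtype="U2")
        nxt = a[1:]
        plus_ctx = np.full(L - 1, "C?", dtype="U2")
        for b, ctx in ((_G, "CG"), (_A, "CA"), (_T, "CT"), (_C, "CC")):
            plus_ctx[nxt == b] = ctx
        plus[:-1] = plus_ctx
        prv = a[:-1]
        minus_ctx = np.full(L - 1, "C?", dtype="U2")
        # complement of the upstream plus base is the minus strand's next base
        for b, ctx in ((_C, "CG"), (_T, "CA"), (_A, "CT"), (_G, "CC")):
            minus_ctx[prv == b] = ctx
        minus[1:] = minus_ctx
        return plus, minus

    def to_frame(self, min_coverage: int = 1) -> pd.DataFrame:
        """Methratio-style table of covered cytosines: scaffold, position,
        strand, context, ratio, total, methylated."""
        frames = []
        for scaf in self.genome:
            plus_ctx, minus_ctx = self.context_codes(scaf)
            for strand, n, m, mask, ctx in (
                ("+", self.n_plus[scaf], self.m_plus[scaf], self._isC[scaf], plus_ctx),
                ("-", self.n_minus[scaf], self.m_minus[scaf], self._isG[scaf], minus_ctx),
            ):
                sel = mask & (n >= min_coverage) & (n > 0)
                pos = np.nonzero(sel)[0]
                if pos.size == 0:
                    continue
                frames.append(
                    pd.DataFrame(
                        {
                            "scaffold": scaf,
                            "position": pos,
                            "strand": strand,
                            "context": ctx[pos],
                            "ratio": m[pos] / n[pos],
                            "total": n[pos].astype(np.int64),
                            "methylated": m[pos].astype(np.int64),
                        }
                    )
                )
        if not frames:
            return pd.DataFrame(
                columns=["scaffold", "position", "strand", "context", "ratio", "total", "methylated"]
            )
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(["scaffold", "position", "strand"]).reset_index(drop=True)


def accumulate_counts(
    alignments: list[ReadAlignment],
    genome: dict[str, str],
    no_mate_overlap_double_count: bool = False,
) -> MethylationCounts:
    """Tally read evidence at every reference cytosine.

    A plus-bisulfite alignment contributes at reference C positions: read C
    is an unconverted observation, read T a converted one.  A minus-strand
    alignment contributes symmetrically at reference G positions (read G
    unconverted, read A converted).  Other read bases — including N — count
    as neither.  Covered sites with zero unconverted reads are retained.

    With ``no_mate_overlap_double_count`` the overlapping part of a read
    pair is counted once (the second mate is clipped); the default double
    counts, the simple model.
    """
    counts = MethylationCounts(genome)
    seen_spans: dict[tuple[str, str], tuple[int, int]] = {}
    for aln in alignments:
        if aln.scaffold not in genome:
            raise ValueError(f"alignment references unknown scaffold {aln.scaffold!r}")
        L = len(genome[aln.scaffold])
        s, e = aln.pos, aln.pos + len(aln.seq)
        if s < 0 or e > L:
            raise ValueError(
                f"alignment {aln.read_id} at {aln.scaffold}:{s}-{e} outside scaffold bounds"
            )
        clip_lo, clip_hi = s, e
        if no_mate_overlap_double_count and aln.mate:
            key = (aln.read_id, aln.scaffold)
            if key in seen_spans:
                ms, me = seen_spans[key]
                if ms < clip_hi and clip_lo < me:  # overlap: keep only the part outside
                    if clip_lo < ms:
                        clip_hi = min(clip_hi, ms)
                    else:
                        clip_lo = max(clip_lo, me)
                if clip_lo >= clip_hi:
                    continue
            else:
                seen_spans[key] = (s, e)
        read = np.frombuffer(aln.seq.encode(), dtype=np.uint8)
        off_lo, off_hi = clip_lo - s, clip_hi - s
        r = read[off_lo:off_hi]
        if aln.bs_strand == "+":
            refmask = counts._isC[aln.scaffold][clip_lo:clip_hi]
            unconv = refmask & (r == _C)
            conv = refmask & (r == _T)
            nv = counts.n_plus[aln.scaffold][clip_lo:clip_hi]
            mv = counts.m_plus[aln.scaffold][clip_lo:clip_hi]
        else:
            refmask = counts._isG[aln.scaffold][clip_lo:clip_hi]
            unconv = refmask & (r == _G)
            conv = refmask & (r == _A)
            nv = counts.n_minus[aln.scaffold][clip_lo:clip_hi]
            mv = counts.m_minus[aln.scaffold][clip_lo:clip_hi]
        nv[unconv | conv] += 1
        mv[unconv] += 1
    return counts


def combine_cpg_strands(counts: MethylationCounts, genome: dict[str, str]) -> pd.DataFrame:
    """Strand-combined CpG table: for each reference CpG, coverage and
    unconverted counts are the sums over the plus-strand C and the paired
    minus-strand C at position + 1.

    All genomic CpGs are reported; uncovered sites carry n = 0 and a NaN
    ratio so downstream classification can flag them as no-data.  Non-CpG
    cytosines never enter this table.
    """
    from .feature_annotation import enumerate_cpg

    cpgs = enumerate_cpg(genome)
    frames = []
    for scaf, pos in cpgs.items():
        if scaf not in counts.genome:
            continue
        n = counts.n_plus[scaf][pos].astype(np.int64) + counts.n_minus[scaf][pos + 1].astype(np.int64)
        m = counts.m_plus[scaf][pos].astype(np.int64) + counts.m_minus[scaf][pos + 1].astype(np.int64)
        with np.errstate(invalid="ignore"):
            ratio = np.where(n > 0, m / np.maximum(n, 1), np.nan)
        frames.append(
            pd.DataFrame({"scaffold": scaf, "position": pos, "n": n, "m": m, "ratio": ratio})
        )
    if not frames:
        return pd.DataFrame(columns=["scaffold", "position", "n", "m", "ratio"])
    return pd.concat(frames, ignore_index=True)


def estimate_conversion_efficiency(
    counts: MethylationCounts, control_contig: str
) -> ConversionEfficiency:
    """e = converted / total over every cytosine observation (both strands)
    on the known-unmethylated control contig."""
    if control_contig not in counts.genome:
        raise ValueError(f"control contig {control_contig!r} not in genome")
    n_tot = int(counts.n_plus[control_contig].sum() + counts.n_minus[control_contig].sum())
    m_tot = int(counts.m_plus[control_contig].sum() + counts.m_minus[control_contig].sum())
    if n_tot == 0:
        raise ValueError(f"no covered cytosines on control contig {control_contig!r}")
    return ConversionEfficiency(converted=n_tot - m_tot, total=n_tot)


def context_methylation_summary(
    counts: MethylationCounts,
    min_coverage: int = 5,
    methylated_min_ratio: float = 0.5,
    exclude_scaffolds: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Fraction of sufficiently covered loci called methylated, per
    dinucleotide context (CG, CA, CT, CC).

    CG loci use strand-combined coverage (strand combination precedes
    thresholding); the other contexts are tallied per strand.  A locus is
    called methylated when coverage >= ``min_coverage`` and the unconverted
    ratio >= ``methylated_min_ratio``.
    """
    rows = []
    genome = {s: q for s, q in counts.genome.items() if s not in exclude_scaffolds}
    cg = combine_cpg_strands(counts, genome)
    cg_cov = cg[cg["n"] >= min_coverage]
    rows.append(
        ("CG", len(cg_cov), int((cg_cov["ratio"] >= methylated_min_ratio).sum()))
    )
    for ctx in ("CA", "CT", "CC"):
        n_loci = n_meth = 0
        for scaf in genome:
            plus_ctx, minus_ctx = counts.context_codes(scaf)
            for n, m, ctxarr in (
                (counts.n_plus[scaf], counts.m_plus[scaf], plus_ctx),
                (counts.n_minus[scaf], counts.m_minus[scaf], minus_ctx),
            ):
                sel = (ctxarr == ctx) & (n >= min_coverage)
                n_loci += int(sel.sum())
                n_meth += int((m[sel] >= methylated_min_ratio * n[sel]).sum())
        rows.append((ctx, n_loci, n_meth))
    df = pd.DataFrame(rows, columns=["context", "n_loci", "n_methylated"])
    df["fraction_methylated"] = np.where(
        df["n_loci"] > 0, df["n_methylated"] / df["n_loci"].clip(lower=1), 0.0
    )
    return df
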