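"""Synthetic genomes, methylomes, bisulfite reads and expression counts.

This module emulates the inputs of a whole-genome bisulfite sequencing +
RNA-Seq study of an invertebrate genome with intermediate, gene-centric CpG
methylation: a multi-scaffold nuclear genome with annotated gene models and
transposable-element intervals, a per-CpG ground-truth methylome with
feature-class-specific methylation rates, shotgun bisulfite read pairs with a
stated conversion-failure rate, an unmethylated lambda-like spike-in contig
(conversion-efficiency control), an unmethylated mitochondrial-like contig,
and per-gene RNA-Seq counts optionally coupled to gene-body methylation.

Everything is deterministic for a fixed seed, so downstream stages can be
tested for parameter recovery against the known truth without any downloads.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    CONTROL_CONTIG,
    MITO_CONTIG,
    GeneModel,
    GenomicInterval,
    ReadAlignment,
    TrueMethylome,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C, _G, _T, _A = ord("C"), ord("G"), ord("T"), ord("A")


class GenomePackingError(ValueError):
    """Raised when the requested gene models cannot fit on the scaffolds."""


@dataclass
class GenomeConfig:
    """Layout of the synthetic genome.

    Defaults give a 500 kb nuclear genome (two 250 kb scaffolds) at the
    AT-rich base composition typical of a mollusc draft assembly, 100
    multi-exon genes, ~10% of intergenic space as transposable elements, and
    both control contigs (48.5 kb lambda-like spike-in, 18 kb mitochondrial-
    like).
    """

    n_scaffolds: int = 2
    scaffold_length: int = 250_000
    gc_fraction: float = 0.33
    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (3, 7)
    exon_length: tuple[int, int] = (120, 300)
    intron_length: tuple[int, int] = (200, 600)
    te_fraction: float = 0.10
    include_control_contig: bool = True
    control_contig_length: int = 48_502
    include_mito_contig: bool = True
    mito_contig_length: int = 18_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if not 0.0 <= self.te_fraction <= 1.0:
            raise ValueError("te_fraction must be in [0, 1]")
        if self.n_scaffolds < 1 or self.scaffold_length < 1:
            raise ValueError("need at least one non-empty scaffold")
        for lo, hi in (self.exons_per_gene, self.exon_length, self.intron_length):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must satisfy 1 <= lo <= hi")


@dataclass
class MethylationRates:
    """Per-feature-class Bernoulli methylation probabilities.

    Defaults reproduce a gene-body-methylated landscape: exons most
    methylated, introns intermediate, everything else at a low background.
    ``control`` and ``mito`` are pinned to zero — both control contigs are
    unmethylated by definition.

    ``gene_mixture`` optionally makes methylation bimodal at the gene level:
    each gene draws one rate from the (weight, rate) components, and that
    rate replaces the exon/intron/promoter rates for all CpGs belonging to
    the gene (body and promoter).  This produces the observed coexistence of
    unmethylated, sparsely and heavily methylated genes; with ``None`` every
    CpG uses its feature-class rate independently.
    """

    exon: float = 0.30
    intron: float = 0.18
    promoter: float = 0.06
    te: float = 0.05
    intergenic: float = 0.05
    control: float = 0.0
    mito: float = 0.0
    gene_mixture: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        for name in ("exon", "intron", "promoter", "te", "intergenic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"rate {name}={v} outside [0, 1]")
        if self.control != 0.0 or self.mito != 0.0:
            raise ValueError("control and mito contig rates are fixed at 0")
        if self.gene_mixture is not None:
            w = sum(c[0] for c in self.gene_mixture)
            if not math.isclose(w, 1.0, rel_tol=1e-9):
                raise ValueError("gene_mixture weights must sum to 1")
            for _, r in self.gene_mixture:
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"gene_mixture rate {r} outside [0, 1]")


@dataclass
class ReadSimConfig:
    """Shotgun bisulfite read simulation parameters.

    Defaults model an Illumina-style library: 72 bp reads from fragments
    sheared to a 250 bp mean, paired-end, with bisulfite conversion
    efficiency 0.9972 (the probability an unmethylated cytosine reads out as
    thymine).  Methylated cytosines are fully protected.
    """

    read_length: int = 72
    mean_fragment: int = 250
    fragment_sd: float = 25.0
    depth: float = 20.0
    conversion_efficiency: float = 0.9972
    paired: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.conversion_efficiency <= 1.0:
            raise ValueError("conversion_efficiency must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.read_length > self.mean_fragment:
            raise ValueError("read_length must not exceed mean_fragment")


@dataclass
class ExpressionModel:
    """Log-normal/negative-binomial RNA-Seq count model.

    Expected relative expression of gene g is
    ``exp(Normal(log_mean, log_sd) + coupling * m_g)`` where ``m_g`` is the
    gene's true gene-body methylation ratio; expected counts are these
    weights normalised to ``total_library_reads``.  ``coupling = 0`` makes
    expression independent of methylation; positive coupling raises the
    expression of methylated genes.  ``dispersion`` is the negative-binomial
    overdispersion (variance = mu + dispersion * mu^2); 0 gives deterministic
    rounded expectations.

    Median RPKM scales as (1e9 / (n_genes * mean_exon_model)) * exp(-log_sd^2/2)
    regardless of library size, so a synthetic library with ~100 genes needs a
    wider log-sd than a ~28k-gene transcriptome to land the median near the
    realistic sub-1 range that splits genes roughly evenly across the
    RPKM <= 1 / > 1 bins.  The default 4.3 does that for the default genome;
    ~2.6 corresponds to a full-size transcriptome.
    """

    log_mean: float = 0.0
    log_sd: float = 4.3
    dispersion: float = 0.2
    coupling: float = 0.0
    total_library_reads: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_library_reads <= 0:
            raise ValueError("total_library_reads must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def _sample_gene_structure(
    rng: np.random.Generator, cfg: GenomeConfig
) -> tuple[list[int], list[int]]:
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    ex = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_ex)
    intr = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1, size=n_ex - 1)
    return list(map(int, ex)), list(map(int, intr))


def generate_genome(
    cfg: GenomeConfig,
) -> tuple[dict[str, str], list[GeneModel], list[GenomicInterval]]:
    """Generate sequences, gene models and TE intervals.

    Genes are distributed round-robin over the nuclear scaffolds and placed
    left to right with random intergenic gaps (a multinomial split of the
    free space), so models never overlap and always fit or an explicit
    :class:`GenomePackingError` is raised.  Introns are exactly the gaps
    between consecutive exons.  With ``n_genes >= 2`` both strands are
    guaranteed to be represented.  TE intervals cover ``te_fraction`` of each
    intergenic gap at a random offset.
    """
    rng = np.random.default_rng(cfg.seed)
    genome: dict[str, str] = {}
    scaffold_names = [f"scaffold_{i + 1}" for i in range(cfg.n_scaffolds)]
    for name in scaffold_names:
        genome[name] = _random_sequence(rng, cfg.scaffold_length, cfg.gc_fraction)

    strands = [str(s) for s in rng.choice(np.array(["+", "-"]), size=cfg.n_genes)]
    if cfg.n_genes >= 2 and len(set(strands)) == 1:
        strands[-1] = "-" if strands[-1] == "+" else "+"

    per_scaffold: dict[str, list[int]] = {n: [] for n in scaffold_names}
    for g in range(cfg.n_genes):
        per_scaffold[scaffold_names[g % cfg.n_scaffolds]].append(g)

    genes: list[GeneModel] = []
    tes: list[GenomicInterval] = []
    for scaf in scaffold_names:
        idxs = per_scaffold[scaf]
        structures = [_sample_gene_structure(rng, cfg) for _ in idxs]
        spans = [sum(ex) + sum(intr) for ex, intr in structures]
        free = cfg.scaffold_length - sum(spans)
        if free < 0:
            raise GenomePackingError(
                f"{scaf}: gene models need {sum(spans)} bp but the scaffold "
                f"has only {cfg.scaffold_length} bp"
            )
        n_gaps = len(idxs) + 1
        gaps = rng.multinomial(free, np.full(n_gaps, 1.0 / n_gaps))
        cursor = 0
        gene_spans: list[tuple[int, int]] = []
        for k, (g, (ex, intr)) in enumerate(zip(idxs, structures)):
            cursor += int(gaps[k])
            start = cursor
            exons = []
            pos = start
            for j, el in enumerate(ex):
                exons.append((pos, pos + el))
                pos += el
                if j < len(intr):
                    pos += intr[j]
            genes.append(
                GeneModel(
                    gene_id=f"gene_{g + 1:05d}",
                    scaffold=scaf,
                    start=start,
                    end=pos,
                    strand=strands[g],
                    exons=exons,
                )
            )
            gene_spans.append((start, pos))
            cursor = pos
        # TE placement inside each intergenic gap
        edges = [0] + [e for s, e in gene_spans]
        ends = [s for s, e in gene_spans] + [cfg.scaffold_length]
        for lo, hi in zip(edges, ends):
            gap = hi - lo
            te_len = int(round(cfg.te_fraction * gap))
            if te_len >= 30:
                off = int(rng.integers(0, gap - te_len + 1))
                tes.append(
                    GenomicInterval(scaf, lo + off, lo + off + te_len, None, "TE")
                )

    genes.sort(key=lambda g: (g.scaffold, g.start))
    if cfg.include_control_contig:
        genome[CONTROL_CONTIG] = _random_sequence(rng, cfg.control_contig_length, 0.5)
    if cfg.include_mito_contig:
        genome[MITO_CONTIG] = _random_sequence(
            rng, cfg.mito_contig_length, cfg.gc_fraction
        )
    return genome, genes, tes


# feature-class painting codes, ascending precedence
_CLS_INTERGENIC, _CLS_TE, _CLS_PROMOTER, _CLS_INTRON, _CLS_EXON = range(5)


def generate_methylome(
    genome: dict[str, str],
    genes: list[GeneModel],
    tes: list[GenomicInterval],
    rates: MethylationRates,
    seed: int,
    promoter_length: int = 1000,
    binary: bool = True,
) -> TrueMethylome:
    """Assign a true methylation level to every CpG of the genome.

    Each CpG is classified by feature with precedence
    exon > intron > promoter > TE > intergenic and drawn methylated (level 1)
    with its class probability, else 0 (all-or-none truth; ``binary=False``
    instead stores the class rate as a deterministic intermediate level).
    Control and mitochondrial contig CpGs are always level 0.  When
    ``rates.gene_mixture`` is set, each gene samples a single rate that
    overrides the exon/intron/promoter rates for its own CpGs.
    """
    from .feature_annotation import enumerate_cpg  # local import, no cycle

    rng = np.random.default_rng(seed)
    cpgs = enumerate_cpg(genome)

    gene_rate: dict[str, float] = {}
    if rates.gene_mixture is not None:
        weights = np.array([w for w, _ in rates.gene_mixture])
        comps = np.array([r for _, r in rates.gene_mixture])
        draws = rng.choice(len(comps), size=len(genes), p=weights)
        gene_rate = {g.gene_id: float(comps[d]) for g, d in zip(genes, draws)}

    levels: dict[str, dict[int, float]] = {}
    for scaf, seq in genome.items():
        pos = cpgs.get(scaf, np.empty(0, dtype=np.int64))
        if scaf in (CONTROL_CONTIG, MITO_CONTIG):
            levels[scaf] = {int(p): 0.0 for p in pos}
            continue
        L = len(seq)
        cls = np.full(L, _CLS_INTERGENIC, dtype=np.int8)
        rate = np.full(L, rates.intergenic, dtype=np.float64)
        for te in tes:
            if te.scaffold == scaf:
                cls[te.start : te.end] = _CLS_TE
                rate[te.start : te.end] = rates.te
        for g in genes:
            if g.scaffold != scaf:
                continue
            r_prom = gene_rate.get(g.gene_id, rates.promoter)
            r_intr = gene_rate.get(g.gene_id, rates.intron)
            r_exon = gene_rate.get(g.gene_id, rates.exon)
            if g.strand == "+":
                ps, pe = max(0, g.start - promoter_length), g.start
            else:
                ps, pe = g.end, min(L, g.end + promoter_length)
            if ps < pe:
                keep = cls[ps:pe] < _CLS_PROMOTER
                cls[ps:pe][keep] = _CLS_PROMOTER
                rate[ps:pe][keep] = r_prom
            cls[g.start : g.end] = _CLS_INTRON
            rate[g.start : g.end] = r_intr
            for es, ee in g.exons:
                cls[es:ee] = _CLS_EXON
                rate[es:ee] = r_exon
        site_rates = rate[pos]
        if binary:
            lv = (rng.random(pos.size) < site_rates).astype(np.float64)
        else:
            lv = site_rates
        levels[scaf] = {int(p): float(v) for p, v in zip(pos, lv)}
    return TrueMethylome(levels)


def simulate_bisulfite_reads(
    genome: dict[str, str],
    methylome: TrueMethylome,
    cfg: ReadSimConfig,
) -> tuple[list[tuple[str, str]], list[ReadAlignment]]:
    """Simulate bisulfite-converted reads and their truth alignments.

    Fragments are sampled uniformly on each scaffold with normal lengths
    (mean ``mean_fragment``, truncated below at ``read_length``), from the
    Watson or Crick strand with equal probability.  A cytosine on the
    sampled strand reads out as C with probability ``p + (1 - p)(1 - e)``
    where ``p`` is its true methylation level and ``e`` the conversion
    efficiency; otherwise it reads T (appearing as A on the plus strand for
    Crick-strand cytosines).  Both CpG strands share the symmetric truth
    level.  No sequencing-error or quality model is applied.

    Returns sequenced reads (id, sequence) in FASTQ order and one truth
    :class:`~methscape.models.ReadAlignment` per read with the plus-oriented
    sequence, true position and bisulfite strand.
    """
    rl = cfg.read_length
    eff = cfg.conversion_efficiency
    rng = np.random.default_rng(cfg.seed)
    reads: list[tuple[str, str]] = []
    alignments: list[ReadAlignment] = []

    for scaf, seq in genome.items():
        L = len(seq)
        if L < rl:
            continue
        a = np.frombuffer(seq.encode(), dtype=np.uint8)
        isC = a == _C
        isG = a == _G
        lvl_plus = np.zeros(L)
        lvl_minus = np.zeros(L)
        site_levels = methylome.scaffold_levels(scaf)
        if site_levels:
            p_arr = np.fromiter(site_levels.keys(), dtype=np.int64)
            l_arr = np.fromiter(site_levels.values(), dtype=np.float64)
            lvl_plus[p_arr] = l_arr
            inb = p_arr + 1 < L
            lvl_minus[p_arr[inb] + 1] = l_arr[inb]

        per_frag = 2 * rl if cfg.paired else rl
        n_frags = max(1, math.ceil(cfg.depth * L / per_frag))
        frag_lens = np.rint(
            rng.normal(cfg.mean_fragment, cfg.fragment_sd, n_frags)
        ).astype(np.int64)
        frag_lens = np.clip(frag_lens, rl, L)
        starts = (rng.random(n_frags) * (L - frag_lens + 1)).astype(np.int64)
        watson = rng.random(n_frags) < 0.5

        for i in range(n_frags):
            s = int(starts[i])
            e = s + int(frag_lens[i])
            frag = a[s:e].copy()
            if watson[i]:
                cpos = np.nonzero(isC[s:e])[0]
                lv = lvl_plus[s + cpos]
                keep = rng.random(cpos.size) < lv + (1.0 - lv) * (1.0 - eff)
                frag[cpos[~keep]] = _T
            else:
                gpos = np.nonzero(isG[s:e])[0]
                lv = lvl_minus[s + gpos]
                keep = rng.random(gpos.size) < lv + (1.0 - lv) * (1.0 - eff)
                frag[gpos[~keep]] = _A
            fragstr = frag.tobytes().decode()
            head, tail = fragstr[:rl], fragstr[-rl:]
            rid = f"sim:{scaf}:{i:07d}"
            bs = "+" if watson[i] else "-"
            if cfg.paired:
                if watson[i]:
                    r1_seq, r2_seq = head, revcomp(tail)
                    a1 = ReadAlignment(rid, scaf, s, bs, head, False, 1)
                    a2 = ReadAlignment(rid, scaf, e - rl, bs, tail, True, 2)
                else:
                    r1_seq, r2_seq = revcomp(tail), head
                    a1 = ReadAlignment(rid, scaf, e - rl, bs, tail, True, 1)
                    a2 = ReadAlignment(rid, scaf, s, bs, head, False, 2)
                reads.append((rid + "/1", r1_seq))
                reads.append((rid + "/2", r2_seq))
                alignments.extend((a1, a2))
            else:
                if watson[i]:
                    reads.append((rid, head))
                    alignments.append(ReadAlignment(rid, scaf, s, bs, head, False, 0))
                else:
                    reads.append((rid, revcomp(tail)))
                    alignments.append(
                        ReadAlignment(rid, scaf, e - rl, bs, tail, True, 0)
                    )
    return reads, alignments


def gene_methylation_ratios(
    genes: list[GeneModel], methylome: TrueMethylome
) -> pd.Series:
    """True gene-body methylation ratio: mean truth level over the CpGs of
    each gene span (0 for genes without CpGs)."""
    by_scaf: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    out = {}
    for g in genes:
        if g.scaffold not in by_scaf:
            d = methylome.scaffold_levels(g.scaffold)
            pos = np.fromiter(d.keys(), dtype=np.int64)
            lvl = np.fromiter(d.values(), dtype=np.float64)
            order = np.argsort(pos)
            by_scaf[g.scaffold] = (pos[order], lvl[order])
        pos, lvl = by_scaf[g.scaffold]
        lo, hi = np.searchsorted(pos, [g.start, g.end])
        out[g.gene_id] = float(lvl[lo:hi].mean()) if hi > lo else 0.0
    return pd.Series(out, name="true_methylation")


def simulate_expression(
    genes: list[GeneModel],
    model: ExpressionModel,
    methylome: TrueMethylome,
) -> pd.DataFrame:
    """Simulate per-gene RNA-Seq read counts.

    Returns a DataFrame with columns ``gene_id``, ``count``,
    ``exon_model_length`` and ``true_methylation``; counts sum to
    approximately ``total_library_reads``.
    """
    if not genes:
        raise ValueError("simulate_expression requires at least one gene")
    for g in genes:
        if g.exon_model_length <= 0:
            raise ValueError(f"{g.gene_id} has non-positive exon model length")
    rng = np.random.default_rng(model.seed)
    ratios = gene_methylation_ratios(genes, methylome)
    n = len(genes)
    z = rng.normal(model.log_mean, model.log_sd, n)
    z = z + model.coupling * ratios.to_numpy()
    w = np.exp(z)
    lam = model.total_library_reads * w / w.sum()
    if model.dispersion == 0:
        counts = np.rint(lam).astype(np.int64)
    else:
        r = 1.0 / model.dispersion
        counts = rng.negative_binomial(r, r / (r + lam)).astype(np.int64)
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "count": counts,
            "exon_model_length": [g.exon_model_length for g in genes],
            "true_methylation": ratios.to_numpy(),
        }
    )
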