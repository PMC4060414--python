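# Methods

## Scope and data flow

methscape analyses shotgun bisulfite sequencing of a draft genome together
with per-gene RNA-Seq counts. The stages are: (1) read placement under the
bisulfite-collapsed alphabet, (2) per-cytosine tallying and strand-combined
CpG ratio extraction, (3) CpG enumeration and feature-track derivation,
(4) locus/region classification, (5) RPKM computation and binning,
(6) the methylation × expression contingency test. A simulator provides
every input with known ground truth, so each stage is validated by
parameter recovery.

Internally all coordinates are 0-based half-open; GFF3 output is 1-based
inclusive and BED stays 0-based half-open, as those formats define.

## Simulator

**Genome.** Nuclear scaffolds are i.i.d. sequences with a configurable GC
fraction (default 0.33, AT-rich as in mollusc assemblies). Genes are
placed non-overlapping, round-robin across scaffolds, with exon/intron
counts and lengths drawn uniformly from configured ranges and intergenic
gaps drawn as a multinomial split of the free space; an explicit error is
raised when the models cannot fit. Introns are exactly the inter-exon
gaps. TE intervals cover a configurable fraction (default 10%) of each
intergenic gap at a random offset. Two reserved contigs are appended: a
48.5 kb lambda-like spike-in at GC 0.5 and an 18 kb mitochondrial-like
contig. The mitochondrial contig's circularity is represented only by its
reserved name and its all-unmethylated truth; fragments are sampled without
origin wrap-around, which leaves a few terminal bases undercovered and has
no effect on methylation negativity.

**Truth methylome.** Every CpG is classified by feature with precedence
exon > intron > promoter > TE > intergenic and drawn methylated (level 1)
with its class probability, else 0. Default class rates (exon 0.30, intron
0.18, promoter 0.06, TE 0.05, intergenic 0.05) reproduce a gene-body-
methylated landscape in which roughly 15% of all CpGs are methylated.
Control and mitochondrial CpGs are always level 0. The all-or-none default
reflects the strongly bimodal ratio histograms such landscapes produce;
intermediate deterministic levels are supported but not default.

An optional per-gene mixture (`MethylationRates.gene_mixture`) draws one
rate per gene that overrides the exon/intron/promoter rates for that gene's
CpGs. This models the empirical bimodality *between* genes — unmethylated,
sparsely and heavily methylated genes coexisting — without which every
gene's region ratio concentrates at its class rate and the 3 × 2
association table degenerates. The mixture used throughout the tests,
weights (0.47, 0.28, 0.25) on rates (0.0, 0.85, 0.2), keeps ~47% of genes
free of methylated CpGs and populates all three region classes.

**Reads.** Fragments are uniform on each scaffold with Normal(250, 25)
lengths truncated below at the read length (shearing to a mean fragment
size; only the mean is well constrained, the spread is a modelling choice),
sampled from Watson or Crick with equal probability, 72 bp from each end
when paired. A cytosine of the sampled strand with true level `p` reads C
with probability `p + (1 − p)(1 − e)` (default `e = 0.9972`): methylated
cytosines are fully protected, and both CpG strands share the symmetric
truth level — which is what makes strand combination meaningful. No
sequencing-error, quality, adapter or duplicate model is applied, so
placement is exact-match; consequently passing recovery tests demonstrate
correctness of the ratio arithmetic and thresholds, not robustness to
sequencing noise or mapping ambiguity in repetitive real genomes.

**Expression.** Gene weights are log-normal,
`w_g = exp(Normal(log_mean, log_sd) + coupling · m_g)` with `m_g` the true
gene-body methylation ratio; expected counts are `N · w_g / Σw` and counts
are negative-binomial with dispersion 0.2 (dispersion 0 gives rounded
expectations). `coupling = 0` makes expression exactly independent of
methylation — the null of the association test; positive coupling produces
the positive-association alternative. Because
`median RPKM ≈ (10⁹ / (n_genes · L̄)) · exp(−log_sd² / 2)` independently of
`N`, a desk-scale gene count inflates RPKM relative to a ~28k-gene
transcriptome; the default `log_sd = 4.3` compensates so that the default
synthetic library lands its median RPKM near the realistic sub-1 range and
populates both expression bins, with ~2.6 corresponding to a full-size
transcriptome.

## Extraction

Reads are placed where they match the reference exactly under the collapsed
alphabet: C≡T for reads reporting on the converted plus strand, G≡A for the
minus strand, trying both orientations of both modes. Only reads with
exactly one candidate (scaffold, position, bisulfite strand) are kept;
ambiguous and unmapped reads are counted. The production path uses a
24-mer prefix index over the two collapsed genome strings with full-read
verification; reads shorter than k fall back to a full scan, and the index
is checked against a brute-force all-positions oracle in the tests.

Counting follows the methratio conventions: every covered reference
cytosine appears (including zero-methylation sites); plus-strand evidence
is read C (unconverted) or T (converted), minus-strand evidence G or A; N
and unexpected bases count as neither. Mate overlaps are double-counted by
default (the simple model — default fragments of 250 bp rarely overlap at
72 bp reads); `no_mate_overlap_double_count` clips the second mate.
Dinucleotide context is always taken 5′→3′ on the cytosine's own strand
from the reference. CpG coverage for the 5× rule is strand-combined
(combination precedes thresholding); non-CpG contexts are thresholded per
strand. Conversion efficiency is the converted fraction of all cytosine
observations on the control contig, with an explicit error at zero
coverage.

## Classification and summaries

Thresholds default to min coverage 5 and methylated ratio 0.5, both with
"at least" semantics (coverage exactly 5 is called; ratio exactly 0.5 is
methylated). The sparse class is open at both ends (0 < r < 0.5) so the
three called classes partition covered loci. Region ratios use covered
CpGs as denominator by default — regions with no covered CpG are reported
as no-data rather than ratio 0 — with `denominator="all"` available since
either convention is defensible. The ratio histogram uses 0.1-wide bins by
default (configurable). Feature distributions are per-track: a CpG in both
an exon and a TE counts once in each track, so tracks are reported
independently rather than partitioning the genome.

## Promoters and the association set

Promoters are the 1 kb strand-aware upstream of the gene start (the
single-isoform annotation's TSS). Scaffold-edge promoters are truncated,
kept and flagged by default (droppable). With gene-overlap exclusion on
(default), a promoter overlapping *any* annotated gene is removed — the
most conservative reading of excluding neighbouring-gene overlap; the
association additionally requires ≥ 10 promoter CpGs. Genes excluded at
any step (no data, too few CpGs, missing expression) are tallied in an
exclusion record attached to the contingency table rather than silently
dropped.

The independence null is the standard marginal-product expectation; the
statistic is Pearson's X² with df = 2 and no continuity correction (the
correction is a 2 × 2 device and nothing suggests one here). A zero
marginal raises with advice to pool, since an expected cell of zero makes
the statistic undefined.

## Numerical and design choices

- Placement ties (same locus reachable as both bisulfite strands, possible
  only for reads without any C/G evidence) count as non-unique and are
  discarded.
- CpGs containing N are never sites; no sequence masking is applied.
- Uncovered CpGs carry NaN ratios and are excluded from ratio-based
  summaries but retained in tables so no-data accounting stays exact.
- Expected recovery tolerances in the tests are 4 standard errors of the
  relevant binomial quantity wherever a closed form exists.

## Problem sizes

The recovery experiments use 500 kb nuclear genomes (two 250 kb scaffolds,
100 genes, ~13–14k CpGs) at 20× with the 48.5 kb spike-in at the same
depth, and 200× on the spike-in for the conversion-efficiency experiment
(~2.4 M control cytosine observations, binomial SE ≈ 0.008 percentage
points). The type-I-error suite redraws 500 independent expression
libraries over a fixed 300-gene bimodal methylome with coupling 0 and
checks the rejection rate at α = 0.05. These sizes give standard errors
comfortably inside the stated tolerances (e.g. ≈ 0.3 points for the 15%
genome-wide fraction, ≈ 0.9 points for the 30% exonic fraction).

## Known limitations

- No sequencing-error or quality model; the placer requires exact collapsed
  matches and is not a general bisulfite aligner (real alignments should be
  supplied as SAM).
- Single gene model per locus: no isoforms, UTRs or alternative TSSs.
- Truth methylation is independent across CpGs given the class/gene rate —
  no spatial autocorrelation along the genome.
- The expression model couples expression to gene-body methylation only;
  promoter methylation correlates with it through the shared gene mixture
  rather than an independent mechanism.
- No differential methylation, smoothing or imputation.
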