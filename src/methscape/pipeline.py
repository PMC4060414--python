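"""End-to-end orchestration: simulate -> place -> extract -> annotate ->
summarize -> express -> associate.

This is the programmatic counterpart of the `run-all` CLI command and the
workhorse behind the parameter-recovery experiments: it wires the module
stages together on in-memory objects and returns every intermediate result.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import bisulfite_extraction as bx
from . import expression_analysis as xa
from . import feature_annotation as fa
from . import methylation_summary as ms
from . import synthetic_data as sd
from .association import ContingencyTable, build_contingency, association_report
from .models import CONTROL_CONTIG, MITO_CONTIG, GeneModel, GenomicInterval, TrueMethylome


@dataclass
class PipelineResult:
    genome: dict[str, str]
    genes: list[GeneModel]
    tes: list[GenomicInterval]
    methylome: TrueMethylome
    placement: bx.PlacementResult | None
    counts: bx.MethylationCounts
    conversion: bx.ConversionEfficiency | None
    cpg_sites: pd.DataFrame          # classified strand-combined CpG table
    promoters: pd.DataFrame
    gene_regions: pd.DataFrame
    promoter_regions: pd.DataFrame
    expression: pd.DataFrame
    gene_contingency: ContingencyTable | None = None
    promoter_contingency: ContingencyTable | None = None
    report: dict = field(default_factory=dict)

    def nuclear_sites(self) -> pd.DataFrame:
        """Classified CpG table restricted to nuclear scaffolds (control and
        mitochondrial contigs excluded)."""
        return self.cpg_sites[
            ~self.cpg_sites["scaffold"].isin([CONTROL_CONTIG, MITO_CONTIG])
        ]


def run_pipeline(
    genome_cfg: sd.GenomeConfig | None = None,
    rates: sd.MethylationRates | None = None,
    read_cfg: sd.ReadSimConfig | None = None,
    expr_model: sd.ExpressionModel | None = None,
    thresholds: ms.ClassificationThresholds | None = None,
    promoter_cfg: fa.PromoterConfig | None = None,
    use_true_alignments: bool = False,
    run_association: bool = True,
) -> PipelineResult:
    """Run the whole synthetic-data analysis chain.

    With ``use_true_alignments`` the simulator's truth placements feed the
    extractor directly (no read mapping); otherwise reads go through the
    collapsed-alphabet unique placer.  Association is skipped (tables left
    None) when ``run_association`` is false or degenerate marginals make the
    chi-squared test undefined.
    """
    genome_cfg = genome_cfg or sd.GenomeConfig()
    rates = rates or sd.MethylationRates()
    read_cfg = read_cfg or sd.ReadSimConfig(seed=genome_cfg.seed + 1)
    expr_model = expr_model or sd.ExpressionModel(seed=genome_cfg.seed + 2)
    thresholds = thresholds or ms.ClassificationThresholds()
    promoter_cfg = promoter_cfg or fa.PromoterConfig()

    genome, genes, tes = sd.generate_genome(genome_cfg)
    methylome = sd.generate_methylome(
        genome, genes, tes, rates, seed=genome_cfg.seed + 10,
        promoter_length=promoter_cfg.upstream_length,
    )
    reads, truth = sd.simulate_bisulfite_reads(genome, methylome, read_cfg)

    placement = None
    if use_true_alignments:
        alignments = truth
    else:
        placement = bx.place_reads(reads, genome)
        alignments = placement.alignments
    counts = bx.accumulate_counts(alignments, genome)
    conversion = None
    if CONTROL_CONTIG in genome:
        conversion = bx.estimate_conversion_efficiency(counts, CONTROL_CONTIG)

    cpg = bx.combine_cpg_strands(counts, genome)
    cpg = ms.classify_sites(cpg, thresholds)

    promoters = fa.build_promoters(genes, genome, promoter_cfg)
    tracks = fa.feature_tracks(genes, tes)
    gene_regions = ms.region_methylation(tracks["gene"], cpg, thresholds)
    promoter_regions = ms.region_methylation(promoters, cpg, thresholds)

    expr = sd.simulate_expression(genes, expr_model, methylome)
    expr = xa.expression_table(expr)

    result = PipelineResult(
        genome=genome, genes=genes, tes=tes, methylome=methylome,
        placement=placement, counts=counts, conversion=conversion,
        cpg_sites=cpg, promoters=promoters, gene_regions=gene_regions,
        promoter_regions=promoter_regions, expression=expr,
    )
    if run_association:
        gene_tab = build_contingency(gene_regions, expr)
        prom_tab = build_contingency(
            promoter_regions, expr, min_cpg=promoter_cfg.min_cpg
        )
        result.gene_contingency = gene_tab
        result.promoter_contingency = prom_tab
        result.report = association_report(gene_tab, prom_tab)
    return result


def methylated_fraction(
    sites: pd.DataFrame, thresholds: ms.ClassificationThresholds | None = None
) -> tuple[float, int]:
    """Fraction of sufficiently covered CpGs called methylated, and the
    number of covered CpGs it is computed over."""
    thresholds = thresholds or ms.ClassificationThresholds()
    covered = sites[sites["n"] >= thresholds.min_coverage]
    if len(covered) == 0:
        return 0.0, 0
    frac = float((covered["locus_class"] == ms.METHYLATED).mean())
    return frac, len(covered)


def feature_methylated_fractions(
    sites: pd.DataFrame,
    tracks: dict[str, pd.DataFrame],
    thresholds: ms.ClassificationThresholds | None = None,
) -> pd.DataFrame:
    """Per feature track: covered-CpG count and methylated fraction."""
    thresholds = thresholds or ms.ClassificationThresholds()
    covered = sites[sites["n"] >= thresholds.min_coverage].reset_index(drop=True)
    pts = pd.DataFrame(
        {
            "scaffold": covered["scaffold"],
            "start": covered["position"],
            "end": covered["position"] + 1,
        }
    )
    rows = []
    for name, track in tracks.items():
        hits = fa.intersect(pts, track)
        idx = hits["query_index"].unique() if len(hits) else []
        sub = covered.iloc[idx]
        n = len(sub)
        frac = float((sub["locus_class"] == ms.METHYLATED).mean()) if n else 0.0
        rows.append({"track": name, "n_covered_cpg": n, "fraction_methylated": frac})
    return pd.DataFrame(rows)
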