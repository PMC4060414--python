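"""Structural, statistical and determinism checks of the simulator."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methscape as m
from methscape.models import CONTROL_CONTIG, MITO_CONTIG, GeneModel, TrueMethylome
from methscape import io as mio


def small_cfg(**kw) -> m.GenomeConfig:
    base = dict(
        n_scaffolds=1, scaffold_length=60_000, n_genes=12,
        control_contig_length=8_000, mito_contig_length=4_000, seed=7,
    )
    base.update(kw)
    return m.GenomeConfig(**base)


class TestGenerateGenome:
    def test_empty_annotation(self):
        cfg = m.GenomeConfig(
            n_scaffolds=1, scaffold_length=10_000, n_genes=0, te_fraction=0.0,
            include_control_contig=False, include_mito_contig=False, seed=1,
        )
        genome, genes, tes = m.generate_genome(cfg)
        assert list(genome) == ["scaffold_1"] and len(genome["scaffold_1"]) == 10_000
        assert genes == [] and tes == []

    def test_gene_structure_partition_and_strands(self):
        genome, genes, tes = m.generate_genome(small_cfg())
        assert {g.strand for g in genes} == {"+", "-"}
        for g in genes:
            assert 0 <= g.start < g.end <= len(genome[g.scaffold])
            for s, e in g.exons:
                assert g.start <= s < e <= g.end
            # introns are exactly the inter-exon gaps: exon+intron = span
            intron_len = sum(
                s2 - e1 for (_, e1), (s2, _) in zip(g.exons, g.exons[1:])
            )
            assert g.exon_model_length + intron_len == g.end - g.start
        # genes never overlap
        by_scaf: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_scaf.setdefault(g.scaffold, []).append(g)
        for gs in by_scaf.values():
            gs.sort(key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                assert a.end <= b.start

    def test_cpg_frequency_matches_iid_expectation(self):
        cfg = m.GenomeConfig(
            n_scaffolds=1, scaffold_length=100_000, gc_fraction=0.5, n_genes=0,
            include_control_contig=False, include_mito_contig=False, seed=3,
        )
        genome, _, _ = m.generate_genome(cfg)
        n_pos = 100_000 - 1
        observed = len(m.enumerate_cpg(genome)["scaffold_1"])
        p = 0.25 * 0.25  # P(C) * P(G) at gc = 0.5
        se = np.sqrt(n_pos * p * (1 - p))
        assert abs(observed - n_pos * p) < 4 * se

    def test_infeasible_packing_raises(self):
        cfg = small_cfg(scaffold_length=5_000, n_genes=20)
        with pytest.raises(m.GenomePackingError):
            m.generate_genome(cfg)

    def test_fixed_seed_outputs_byte_identical(self, tmp_path):
        files = []
        for run in ("a", "b"):
            genome, genes, tes = m.generate_genome(small_cfg())
            meth = m.generate_methylome(genome, genes, tes, m.MethylationRates(), seed=9)
            reads, truth = m.simulate_bisulfite_reads(
                genome, meth, m.ReadSimConfig(depth=2, seed=11)
            )
            d = tmp_path / run
            d.mkdir()
            mio.write_fasta(genome, d / "g.fasta")
            mio.write_gff3(genes, d / "g.gff3")
            mio.write_bed(tes, d / "te.bed")
            mio.write_fastq(reads, d / "r.fastq")
            files.append(d)
        for name in ("g.fasta", "g.gff3", "te.bed", "r.fastq"):
            assert (files[0] / name).read_bytes() == (files[1] / name).read_bytes()


class TestGenerateMethylome:
    def test_rate_extremes(self):
        genome, genes, tes = m.generate_genome(small_cfg())
        zero = m.generate_methylome(
            genome, genes, tes,
            m.MethylationRates(exon=0, intron=0, promoter=0, te=0, intergenic=0),
            seed=5,
        )
        assert all(lvl == 0.0 for _, lvl in zero.items())
        full_exon = m.generate_methylome(
            genome, genes, tes, m.MethylationRates(exon=1.0), seed=5
        )
        for g in genes:
            for s, e in g.exons:
                for pos in m.enumerate_cpg({g.scaffold: genome[g.scaffold]})[g.scaffold]:
                    if s <= pos < e:
                        assert full_exon.level(g.scaffold, pos) == 1.0

    def test_exonic_rate_recovered_binomially(self):
        cfg = m.GenomeConfig(seed=13)  # default 500 kb genome, 100 genes
        genome, genes, tes = m.generate_genome(cfg)
        meth = m.generate_methylome(
            genome, genes, tes, m.MethylationRates(exon=0.3), seed=17
        )
        cpgs = m.enumerate_cpg(genome)
        levels = []
        for g in genes:
            pos = cpgs[g.scaffold]
            for s, e in g.exons:
                for p in pos[(pos >= s) & (pos < e)]:
                    levels.append(meth.level(g.scaffold, int(p)))
        n = len(levels)
        assert n >= 1000
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(np.mean(levels) - 0.3) < 4 * se

    def test_keys_are_exactly_the_genome_cpgs(self):
        genome, genes, tes = m.generate_genome(small_cfg())
        meth = m.generate_methylome(genome, genes, tes, m.MethylationRates(), seed=5)
        cpgs = m.enumerate_cpg(genome)
        assert meth.n_sites() == sum(len(p) for p in cpgs.values())
        for scaf, pos in cpgs.items():
            assert set(meth.scaffold_levels(scaf)) == set(map(int, pos))

    def test_control_and_mito_truth_is_zero(self):
        genome, genes, tes = m.generate_genome(small_cfg())
        meth = m.generate_methylome(
            genome, genes, tes,
            m.MethylationRates(exon=1, intron=1, promoter=1, te=1, intergenic=1),
            seed=5,
        )
        for scaf in (CONTROL_CONTIG, MITO_CONTIG):
            assert all(lvl == 0.0 for lvl in meth.scaffold_levels(scaf).values())

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            m.MethylationRates(exon=1.2)
        with pytest.raises(ValueError):
            m.MethylationRates(control=0.1)


class TestSimulateReads:
    def test_full_conversion_leaves_no_cytosines(self):
        genome, genes, tes = m.generate_genome(small_cfg(n_genes=4))
        meth = m.generate_methylome(
            genome, genes, tes,
            m.MethylationRates(exon=0, intron=0, promoter=0, te=0, intergenic=0),
            seed=5,
        )
        reads, truth = m.simulate_bisulfite_reads(
            genome, meth, m.ReadSimConfig(depth=2, conversion_efficiency=1.0, seed=3)
        )
        for aln in truth:
            ref = genome[aln.scaffold][aln.pos : aln.pos + len(aln.seq)]
            for rb, qb in zip(ref, aln.seq):
                if aln.bs_strand == "+" and rb == "C":
                    assert qb == "T"
                if aln.bs_strand == "-" and rb == "G":
                    assert qb == "A"

    def test_protected_site_reads_fully_methylated(self):
        genome = {"chr": "AT" * 100 + "ACGA" + "TA" * 100}
        pos = 201  # the C of the single CpG
        assert genome["chr"][pos : pos + 2] == "CG"
        meth = TrueMethylome({"chr": {pos: 1.0}})
        reads, truth = m.simulate_bisulfite_reads(
            genome, meth, m.ReadSimConfig(
                read_length=50, mean_fragment=100, depth=50,
                conversion_efficiency=1.0, seed=2,
            )
        )
        counts = m.accumulate_counts(truth, genome)
        cpg = m.combine_cpg_strands(counts, genome)
        site = cpg[cpg["position"] == pos].iloc[0]
        assert site["n"] > 0 and site["ratio"] == 1.0

    def test_intermediate_level_matches_closed_form(self):
        # P(read C) = p + (1 - p)(1 - e) = 0.5 + 0.5 * 0.0028 = 0.5014
        genome = {"chr": "AT" * 100 + "ACGA" + "TA" * 100}
        meth = TrueMethylome({"chr": {201: 0.5}})
        reads, truth = m.simulate_bisulfite_reads(
            genome, meth, m.ReadSimConfig(
                read_length=50, mean_fragment=100, depth=2000,
                conversion_efficiency=0.9972, seed=4,
            )
        )
        counts = m.accumulate_counts(truth, genome)
        cpg = m.combine_cpg_strands(counts, genome)
        site = cpg[cpg["position"] == 201].iloc[0]
        assert site["n"] >= 2000
        se = np.sqrt(0.5014 * (1 - 0.5014) / site["n"])
        assert abs(site["ratio"] - 0.5014) < 4 * se

    def test_depth_must_be_positive(self):
        with pytest.raises(ValueError):
            m.ReadSimConfig(depth=0)


def fabricate_genes(n: int, gene_len: int = 1000, gap: int = 200) -> list[GeneModel]:
    genes = []
    pos = 0
    for i in range(n):
        genes.append(
            GeneModel(f"g{i:04d}", "chr1", pos, pos + gene_len, "+", [(pos, pos + gene_len)])
        )
        pos += gene_len + gap
    return genes


class TestSimulateExpression:
    def test_coupling_zero_is_independent(self):
        rng = np.random.default_rng(0)
        genes = fabricate_genes(2000)
        meth = TrueMethylome(
            {"chr1": {g.start + 10: float(rng.random() < 0.5) for g in genes}}
        )
        table = m.simulate_expression(
            genes, m.ExpressionModel(coupling=0.0, seed=1), meth
        )
        table = m.expression_table(table)
        rho = stats.spearmanr(table["true_methylation"], table["rpkm"]).statistic
        assert abs(rho) < 0.1

    def test_zero_dispersion_gives_rounded_expectations(self):
        genes = fabricate_genes(10)
        meth = TrueMethylome({"chr1": {}})
        model = m.ExpressionModel(
            log_sd=0.0, dispersion=0.0, coupling=0.0,
            total_library_reads=100_000, seed=1,
        )
        table = m.simulate_expression(genes, model, meth)
        # identical means: every gene gets exactly round(N / n) reads
        assert (table["count"] == 10_000).all()

    def test_positive_coupling_raises_expression_of_methylated_genes(self):
        rng = np.random.default_rng(2)
        genes = fabricate_genes(900)
        meth = TrueMethylome(
            {"chr1": {g.start + 10: float(rng.random() < 0.5) for g in genes}}
        )
        table = m.simulate_expression(
            genes, m.ExpressionModel(coupling=3.0, seed=3), meth
        )
        table = m.expression_table(table)
        tert = table["true_methylation"].rank(pct=True)
        top = table.loc[tert > 2 / 3, "rpkm"].median()
        bottom = table.loc[tert <= 1 / 3, "rpkm"].median()
        assert top > bottom

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            m.simulate_expression([], m.ExpressionModel(), TrueMethylome({}))
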