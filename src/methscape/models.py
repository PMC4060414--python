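"""Shared genomic containers used across the pipeline stages.

Coordinates are 0-based half-open throughout the library; the GFF writer
converts to 1-based inclusive on output and BED stays 0-based half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, field

# Reserved scaffold names for the two spike-in style contigs.  The lambda-like
# contig is fully unmethylated exogenous DNA used to estimate bisulfite
# conversion efficiency; the mitochondrial-like contig is an endogenous
# unmethylated control.
CONTROL_CONTIG = "lambda_spikein"
MITO_CONTIG = "mtDNA"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A scaffold-anchored half-open interval with an optional strand."""

    scaffold: str
    start: int
    end: int
    strand: str | None = None
    feature_class: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A single-isoform gene model: span, strand and sorted exon blocks."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.exons:
            if self.exons != sorted(self.exons):
                raise ValueError(f"{self.gene_id}: exons must be sorted")
            if self.exons[0][0] != self.start or self.exons[-1][1] != self.end:
                raise ValueError(f"{self.gene_id}: exons must span the gene")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start (position of the first
        transcribed base; for minus-strand genes this is ``end - 1``)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def exon_model_length(self) -> int:
        """Total exonic bases (exons are non-overlapping by construction)."""
        return sum(e - s for s, e in self.exons)

    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.scaffold, self.start, self.end, self.strand, "gene", self.gene_id
        )


@dataclass(frozen=True)
class ReadAlignment:
    """A uniquely placed bisulfite read, oriented to the plus strand.

    ``bs_strand`` records which bisulfite-converted strand the read reports
    on: '+' means the read is C-depleted in plus orientation and informs
    plus-strand cytosines; '-' means it is G-depleted and informs the
    cytosines of the minus strand (reference G positions).  ``reverse`` is
    true when the read as sequenced is the reverse complement of ``seq``.
    """

    read_id: str
    scaffold: str
    pos: int
    bs_strand: str
    seq: str
    reverse: bool = False
    mate: int = 0


class TrueMethylome:
    """Simulator ground truth: per-CpG methylation level in [0, 1].

    Keyed by (scaffold, plus-strand position of the CpG's C).  Both strands
    of a CpG inherit the same level (symmetric methylation), so the minus
    strand cytosine at position + 1 shares the entry.
    """

    def __init__(self, levels: dict[str, dict[int, float]]):
        for scaf, d in levels.items():
            for pos, lvl in d.items():
                if not 0.0 <= lvl <= 1.0:
                    raise ValueError(
                        f"methylation level {lvl} at {scaf}:{pos} outside [0, 1]"
                    )
        self._levels = levels

    def level(self, scaffold: str, pos: int) -> float:
        return self._levels.get(scaffold, {}).get(pos, 0.0)

    def scaffold_levels(self, scaffold: str) -> dict[int, float]:
        return self._levels.get(scaffold, {})

    def items(self):
        for scaf in self._levels:
            for pos, lvl in self._levels[scaf].items():
                yield (scaf, pos), lvl

    def n_sites(self) -> int:
        return sum(len(d) for d in self._levels.values())
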