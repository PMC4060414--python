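"""Readers and writers for the standard formats the pipeline touches.

Writers are deterministic (fixed seed upstream implies byte-identical
files).  Coordinates: GFF3 is 1-based inclusive, BED is 0-based half-open,
SAM is handled through pysam.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

from .models import GeneModel, GenomicInterval, ReadAlignment, revcomp


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append((header.strip()[1:], seq))
    return reads


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Gene/exon features, 1-based inclusive per the GFF3 standard."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold}\tmethscape\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold}\tmethscape\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{k};Parent={g.gene_id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            scaf, _, ftype, start, end, _, strand, _, attrs = f[:9]
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = attr["ID"]
                genes[gid] = {
                    "scaffold": scaf,
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand,
                    "exons": [],
                }
                order.append(gid)
            elif ftype == "exon":
                gid = attr.get("Parent") or attr["ID"].rsplit(".", 1)[0]
                genes[gid]["exons"].append((int(start) - 1, int(end)))
    out = []
    for gid in order:
        d = genes[gid]
        out.append(
            GeneModel(gid, d["scaffold"], d["start"], d["end"], d["strand"], sorted(d["exons"]))
        )
    return out


def write_bed(intervals: list[GenomicInterval] | pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        if isinstance(intervals, pd.DataFrame):
            for row in intervals.itertuples(index=False):
                name = getattr(row, "name", None) or getattr(row, "gene_id", None) or "."
                fh.write(f"{row.scaffold}\t{row.start}\t{row.end}\t{name}\n")
        else:
            for iv in intervals:
                fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{iv.name or iv.feature_class or '.'}\n")


def read_bed(path: str | Path, feature_class: str | None = None) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3].strip() if len(f) > 3 else None
            out.append(
                GenomicInterval(f[0], int(f[1]), int(f[2]), None, feature_class, name)
            )
    return out


def _sam_header(genome: dict[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
        }
    )


def write_sam(
    alignments: list[ReadAlignment], genome: dict[str, str], path: str | Path
) -> None:
    """SAM with mandatory fields; the bisulfite strand a read reports on is
    kept in the XB tag ('+' or '-').  SEQ is stored plus-oriented per the
    SAM convention, with the reverse flag set when the read was sequenced
    from the other orientation."""
    header = _sam_header(genome)
    tid = {name: i for i, name in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alignments:
            a = pysam.AlignedSegment(header)
            a.query_name = aln.read_id
            a.reference_id = tid[aln.scaffold]
            a.reference_start = aln.pos
            a.mapping_quality = 60
            a.cigarstring = f"{len(aln.seq)}M"
            flag = 0
            if aln.reverse:
                flag |= 0x10
            if aln.mate:
                flag |= 0x1 | (0x40 if aln.mate == 1 else 0x80)
            a.flag = flag
            a.query_sequence = aln.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(aln.seq))
            a.set_tag("XB", aln.bs_strand)
            fh.write(a)


def read_sam(path: str | Path, genome: dict[str, str] | None = None) -> list[ReadAlignment]:
    """Load bisulfite alignments from SAM.

    The bisulfite strand comes from the XB tag when present (written by this
    package), from a BSMAP-style ZS tag otherwise, and as a last resort is
    inferred from the mismatch pattern against the reference (C->T implies
    plus, G->A implies minus; ties default to plus).
    """
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.query_sequence is None:
                continue
            seq = a.query_sequence  # pysam returns SEQ as stored: plus-oriented
            if a.has_tag("XB"):
                bs = str(a.get_tag("XB"))
            elif a.has_tag("ZS"):
                bs = "+" if str(a.get_tag("ZS")).startswith("+") else "-"
            else:
                bs = "+"
                if genome is not None:
                    ref = genome[a.reference_name][
                        a.reference_start : a.reference_start + len(seq)
                    ]
                    ct = sum(1 for rb, qb in zip(ref, seq) if rb == "C" and qb == "T")
                    ga = sum(1 for rb, qb in zip(ref, seq) if rb == "G" and qb == "A")
                    bs = "-" if ga > ct else "+"
            mate = 1 if a.is_read1 else (2 if a.is_read2 else 0)
            out.append(
                ReadAlignment(
                    a.query_name,
                    a.reference_name,
                    a.reference_start,
                    bs,
                    seq,
                    a.is_reverse,
                    mate,
                )
            )
    return out


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "count", "exon_model_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return df
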