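"""File-format boundaries: FASTA, GTF (own dialect), GFF3/BED annotations, SAM.

The transcriptome GTF uses source ``piratrue`` and feature ``small_rna`` with
1-based inclusive coordinates; the entry sequence and genomic hit count are
carried in the attribute column so write->read round-trips losslessly.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .types import (
    AlignmentRecord,
    AnnotationFeature,
    DbEntry,
    GenomicInterval,
    PlacedEntry,
    normalize_sequence,
)

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) FASTA file into an ordered name -> sequence dict."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_db_fasta(path: str | Path) -> list[DbEntry]:
    """Read a small-RNA database FASTA; header is ``>accession [alias]``."""
    entries = []
    with open(path) as fh:
        name, alias, chunks = None, "", []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    entries.append(
                        DbEntry(name, normalize_sequence("".join(chunks)), alias)
                    )
                parts = line[1:].split()
                name = parts[0]
                alias = parts[1] if len(parts) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line)
        if name is not None:
            entries.append(DbEntry(name, normalize_sequence("".join(chunks)), alias))
    return entries


# ---------------------------------------------------------------------------
# Transcriptome GTF (piratrue dialect)

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def write_transcriptome_gtf(placed: Iterable[PlacedEntry], path: str | Path) -> None:
    """Write placements as GTF (1-based inclusive). Duplicate accessions error."""
    placed = list(placed)
    seen: set[str] = set()
    for p in placed:
        if p.accession in seen:
            raise ValueError(f"duplicate accession in transcriptome: {p.accession}")
        seen.add(p.accession)
    with open(path, "w") as fh:
        fh.write("#gtf: piratrue small-RNA transcriptome\n")
        for p in placed:
            iv = p.interval
            attrs = (
                f'gene_id "{p.accession}"; alias "{p.entry.alias}"; '
                f'sequence "{p.entry.sequence}"; n_genomic_hits "{p.n_genomic_hits}";'
            )
            fh.write(
                f"{iv.chrom}\tpiratrue\tsmall_rna\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


def read_transcriptome_gtf(path: str | Path) -> list[PlacedEntry]:
    placed = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(_ATTR_RE.findall(f[8]))
            entry = DbEntry(
                attrs["gene_id"], attrs["sequence"], attrs.get("alias", "")
            )
            iv = GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6])
            placed.append(PlacedEntry(entry, iv, int(attrs["n_genomic_hits"])))
    return placed


# ---------------------------------------------------------------------------
# Annotations (GFF3 1-based inclusive; BED 0-based half-open)


def read_annotation_gff3(path: str | Path, feature_class: str) -> list[AnnotationFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            iv = GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6])
            feats.append(AnnotationFeature(iv, feature_class, name=f[8]))
    return feats


def read_annotation_bed(path: str | Path, feature_class: str) -> list[AnnotationFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "."
            name = f[3] if len(f) > 3 else ""
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), strand)
            feats.append(AnnotationFeature(iv, feature_class, name=name))
    return feats


def write_annotation_gff3(feats: Iterable[AnnotationFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ft in feats:
            iv = ft.interval
            fh.write(
                f"{iv.chrom}\tpiratrue_sim\t{ft.feature_class}\t{iv.start + 1}\t"
                f"{iv.end}\t.\t{iv.strand}\t.\tID={ft.name}\n"
            )


def write_annotation_bed(feats: Iterable[AnnotationFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ft in feats:
            iv = ft.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ft.name}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# SAM


def sam_header(genome: dict[str, str]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
    }


def read_sam(path: str | Path, sample_id: str | None = None) -> Iterator[AlignmentRecord]:
    """Stream alignment records from SAM/BAM (unmapped reads skipped)."""
    if sample_id is None:
        sample_id = Path(path).stem
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            iv = GenomicInterval(
                aln.reference_name, aln.reference_start, aln.reference_end, strand
            )
            yield AlignmentRecord(
                read_id=aln.query_name,
                sample_id=sample_id,
                interval=iv,
                is_primary=not (aln.is_secondary or aln.is_supplementary),
                mapq=aln.mapping_quality,
                read_length=aln.query_length or aln.infer_read_length() or iv.length,
                read_sequence=aln.query_sequence or "",
            )


def write_sam(
    records: Iterable[AlignmentRecord], genome: dict[str, str], path: str | Path
) -> None:
    header = pysam.AlignmentHeader.from_dict(sam_header(genome))
    names = list(genome)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec.read_id
            a.flag = (0 if rec.interval.strand != "-" else 16) | (
                0 if rec.is_primary else 256
            )
            a.reference_id = names.index(rec.interval.chrom)
            a.reference_start = rec.interval.start
            a.mapping_quality = rec.mapq
            a.cigartuples = [(0, rec.interval.length)]
            a.query_sequence = rec.read_sequence or None
            out.write(a)
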