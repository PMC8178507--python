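"""Core coordinate and record types shared across the pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)`` internally.
GTF/GFF3 i/o converts to and from 1-based inclusive at the file boundary;
BED stays 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
VALID_STRANDS = frozenset({"+", "-", "."})
DNA_ALPHABET = frozenset("ACGT")


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA U to DNA T (database entries are RNA-space)."""
    return seq.strip().upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class DbEntry:
    """One small-RNA database record (accession-keyed, DNA-normalized)."""

    accession: str
    sequence: str
    alias: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")

    @property
    def is_valid_alphabet(self) -> bool:
        return set(self.sequence) <= DNA_ALPHABET


@dataclass(frozen=True)
class PlacedEntry:
    """A database entry anchored to its single retained genomic location."""

    entry: DbEntry
    interval: GenomicInterval
    n_genomic_hits: int

    def __post_init__(self) -> None:
        if self.n_genomic_hits < 1:
            raise ValueError("placed entry must have >=1 genomic hit")
        if self.interval.length != len(self.entry.sequence):
            raise ValueError(
                f"{self.entry.accession}: interval length "
                f"{self.interval.length} != sequence length {len(self.entry.sequence)}"
            )

    @property
    def accession(self) -> str:
        return self.entry.accession

    @property
    def five_prime_pos(self) -> int:
        """Genomic coordinate of the entry's 5' end (strand-dependent)."""
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


FEATURE_CLASSES = frozenset({"mito", "sncRNA", "tRNA", "miRNA_primary", "repeat"})


@dataclass(frozen=True)
class AnnotationFeature:
    """One blacklist-candidate annotation interval (ncRNA / repeat / mito)."""

    interval: GenomicInterval
    feature_class: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature_class: {self.feature_class!r}")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned single-end read.

    ``interval`` is the aligned reference span; ``read_length`` is the full
    read length (may exceed the span when clipping is present).
    """

    read_id: str
    sample_id: str
    interval: GenomicInterval
    is_primary: bool
    mapq: int
    read_length: int
    read_sequence: str = ""

    @property
    def five_prime_pos(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start
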