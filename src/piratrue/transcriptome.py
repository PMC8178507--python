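"""Database-sequence placement: anchor each small-RNA entry to one genomic locus.

Placement is exact-match (edit distance 0) substring search over both strands.
Entries hitting the genome more than ``max_hits`` times, or not at all, are
dropped and reported; for retained entries exactly one location is kept, the
first under (chrom lexicographic, start ascending, '+' before '-') ordering.
Overlapping occurrences each count as a hit.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import io
from .types import DbEntry, GenomicInterval, PlacedEntry, revcomp

logger = logging.getLogger(__name__)

STATUS_PLACED = "placed"
STATUS_NO_HIT = "no_hit"
STATUS_TOO_MANY = "too_many_hits"
STATUS_INVALID = "invalid_alphabet"


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    """Yield every (possibly overlapping) start position of needle."""
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def find_genomic_hits(
    genome: Mapping[str, str], sequence: str
) -> list[GenomicInterval]:
    """All exact occurrences of ``sequence`` on either strand, in canonical order.

    A '-' strand hit means the reverse complement of ``sequence`` occurs at the
    reported forward-strand coordinates. Order: (chrom, start, '+' before '-').
    """
    rc = revcomp(sequence)
    hits: list[GenomicInterval] = []
    for chrom in sorted(genome):
        contig = genome[chrom].upper()
        L = len(sequence)
        fwd = set(_find_all(contig, sequence))
        rev = set(_find_all(contig, rc))
        for pos in sorted(fwd | rev):
            if pos in fwd:
                hits.append(GenomicInterval(chrom, pos, pos + L, "+"))
            if pos in rev and (rc != sequence or pos not in fwd):
                hits.append(GenomicInterval(chrom, pos, pos + L, "-"))
    return hits


def place_sequences(
    db: Iterable[DbEntry],
    genome: Mapping[str, str],
    max_hits: int = 10,
) -> tuple[list[PlacedEntry], pd.DataFrame]:
    """Place database entries on the genome, enforcing the multi-map cap.

    Returns the retained placements and a per-entry report DataFrame with
    columns ``accession, n_hits, status``. Entries with zero hits or more
    than ``max_hits`` hits are absent from the placements but reported.
    Entries with non-ACGT/U characters are rejected per-entry.
    """
    genome = dict(genome)
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    placed: list[PlacedEntry] = []
    rows = []
    for entry in db:
        if not entry.is_valid_alphabet:
            logger.warning("%s: non-ACGTU characters, rejected", entry.accession)
            rows.append((entry.accession, 0, STATUS_INVALID))
            continue
        hits = find_genomic_hits(genome, entry.sequence)
        n = len(hits)
        if n == 0:
            status = STATUS_NO_HIT
        elif n > max_hits:
            status = STATUS_TOO_MANY
        else:
            status = STATUS_PLACED
            placed.append(PlacedEntry(entry, hits[0], n))
        rows.append((entry.accession, n, status))
        if status != STATUS_PLACED:
            logger.info("%s: %s (%d hits)", entry.accession, status, n)
    report = pd.DataFrame(rows, columns=["accession", "n_hits", "status"])
    return placed, report


def write_transcriptome(placed: Iterable[PlacedEntry], path: str | Path) -> None:
    """Write the one-location-per-entry transcriptome as GTF."""
    io.write_transcriptome_gtf(placed, path)


def read_transcriptome(path: str | Path) -> list[PlacedEntry]:
    return io.read_transcriptome_gtf(path)


def placement_sequence_check(
    placed: Iterable[PlacedEntry], genome: Mapping[str, str]
) -> bool:
    """True iff every retained interval's strand-adjusted sequence equals the entry."""
    for p in placed:
        sub = genome[p.interval.chrom][p.interval.start : p.interval.end].upper()
        if p.interval.strand == "-":
            sub = revcomp(sub)
        if sub != p.entry.sequence:
            return False
    return True
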