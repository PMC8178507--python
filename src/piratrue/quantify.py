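"""Fractional-overlap read counting, presence tiers, and authenticity evidence.

A primary alignment with MAPQ >= ``min_mapq`` is counted to a transcriptome
entry when its overlap with the entry reaches
``max(min_overlap_nt, ceil(frac_overlap * read_length))`` reference bases
(defaults 15 nt and 80%). A read qualifying for several entries is assigned
to exactly one: the largest overlap, ties broken by (chrom, start, accession).
Counting is strand-agnostic.

Presence tiers implement the detection criterion: "present" needs at least
``min_reads`` counted reads in at least ``min_samples`` samples (defaults
2/10); otherwise "secondary" needs >=1 read in >=25 samples; otherwise
"absent". Stack profiles and sequence evidence formalize the genome-browser
inspection (5' end concentration, containment in the entry interval, 5'U,
full reverse-complement matches).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import AlignmentRecord, PlacedEntry, revcomp

logger = logging.getLogger(__name__)


def required_overlap(read_length: int, min_overlap_nt: int, frac_overlap: float) -> int:
    """Smallest integer overlap satisfying both the absolute and fractional bound."""
    # round() guards against float artifacts like 0.80 * 20 -> 16.000000000000004
    frac_bound = math.ceil(round(frac_overlap * read_length, 9))
    return max(min_overlap_nt, frac_bound)


def count_reads(
    alignments: Iterable[AlignmentRecord],
    transcriptome: Sequence[PlacedEntry],
    min_overlap_nt: int = 15,
    frac_overlap: float = 0.80,
    min_mapq: int = 1,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Count filtered primary alignments against the transcriptome.

    Returns an entries x samples integer DataFrame (rows ordered as the
    transcriptome, columns as ``samples`` or sorted observed sample ids).
    """
    transcriptome = list(transcriptome)
    if not transcriptome:
        raise ValueError("empty transcriptome")
    trees: dict[str, IntervalTree] = {}
    for p in transcriptome:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, p
        )

    counts: Counter[tuple[str, str]] = Counter()
    seen_samples: set[str] = set()
    for aln in alignments:
        seen_samples.add(aln.sample_id)
        if not aln.is_primary or aln.mapq < min_mapq:
            continue
        if aln.read_length <= 0:
            logger.warning("read %s has length 0; rejected", aln.read_id)
            continue
        tree = trees.get(aln.interval.chrom)
        if tree is None:
            continue
        need = required_overlap(aln.read_length, min_overlap_nt, frac_overlap)
        best = None
        for hit in tree.overlap(aln.interval.start, aln.interval.end):
            entry: PlacedEntry = hit.data
            ov = entry.interval.overlap_length(aln.interval)
            if ov < need:
                continue
            key = (-ov, entry.interval.chrom, entry.interval.start, entry.accession)
            if best is None or key < best[0]:
                best = (key, entry)
        if best is not None:
            counts[(best[1].accession, aln.sample_id)] += 1

    if samples is None:
        samples = sorted(seen_samples)
    accs = [p.accession for p in transcriptome]
    mat = pd.DataFrame(0, index=accs, columns=list(samples), dtype=int)
    for (acc, sample), n in counts.items():
        if sample in mat.columns:
            mat.loc[acc, sample] = n
    mat.index.name = "accession"
    return mat


def call_presence(
    counts: pd.DataFrame,
    min_reads: int = 2,
    min_samples: int = 10,
    sec_min_reads: int = 1,
    sec_min_samples: int = 25,
) -> pd.DataFrame:
    """Assign presence tiers to every entry of the count matrix."""
    n = counts.shape[1]
    if min_samples > n or sec_min_samples > n:
        raise ValueError(
            f"presence thresholds ({min_samples}/{sec_min_samples} samples) "
            f"exceed the {n} samples in the matrix"
        )
    n_primary = (counts >= min_reads).sum(axis=1)
    n_secondary = (counts >= sec_min_reads).sum(axis=1)
    tier = np.where(
        n_primary >= min_samples,
        "present",
        np.where(n_secondary >= sec_min_samples, "secondary", "absent"),
    )
    return pd.DataFrame(
        {
            "accession": counts.index,
            "tier": tier,
            "n_samples_meeting_primary": n_primary.to_numpy(),
            "n_samples_meeting_secondary": n_secondary.to_numpy(),
        }
    ).set_index("accession")


@dataclass
class StackProfile:
    """Read-stack summary at one entry locus."""

    accession: str
    n_reads: int
    modal_start_offset: int | None
    uniformity_score: float | None
    containment_score: float | None


def stack_profile(
    alignments: Iterable[AlignmentRecord],
    entry: PlacedEntry,
    window_nt: int = 2,
) -> StackProfile:
    """Concentration of read 5' ends at the modal position, plus containment.

    uniformity = fraction of reads whose 5' position lies within
    +/- ``window_nt`` of the modal 5' position (modal ties -> smallest
    coordinate); containment = mean fraction of read bases inside the entry
    interval. Scores are missing when no reads are given.
    """
    alns = list(alignments)
    if not alns:
        return StackProfile(entry.accession, 0, None, None, None)
    fps = [a.five_prime_pos for a in alns]
    freq = Counter(fps)
    top = max(freq.values())
    modal = min(pos for pos, c in freq.items() if c == top)
    uniform = sum(abs(fp - modal) <= window_nt for fp in fps) / len(fps)
    contain = float(
        np.mean(
            [
                entry.interval.overlap_length(a.interval) / a.read_length
                for a in alns
            ]
        )
    )
    if entry.interval.strand == "-":
        offset = entry.five_prime_pos - modal
    else:
        offset = modal - entry.five_prime_pos
    return StackProfile(entry.accession, len(alns), offset, uniform, contain)


@dataclass
class SequenceEvidence:
    """5' nucleotide and full reverse-complement matches for one entry."""

    accession: str
    five_prime_nt: str
    is_5pU: bool
    rc_hits: list[tuple[str, int]]


def sequence_evidence(
    entry: PlacedEntry, targets: Sequence[tuple[str, str]] = ()
) -> SequenceEvidence:
    """5' nucleotide (RNA alphabet) and exact reverse-complement occurrences.

    ``targets`` are (target_id, sequence) pairs; every position where the full
    reverse complement of the entry sequence occurs is reported.
    """
    seq = entry.entry.sequence
    if not seq:
        raise ValueError(f"{entry.accession}: empty sequence")
    first = seq[0].replace("T", "U")
    rc = revcomp(seq)
    hits: list[tuple[str, int]] = []
    for target_id, tseq in targets:
        tseq = tseq.upper().replace("U", "T")
        i = tseq.find(rc)
        while i != -1:
            hits.append((target_id, i))
            i = tseq.find(rc, i + 1)
    return SequenceEvidence(entry.accession, first, first == "U", hits)


def nominate(
    profile: StackProfile,
    min_uniformity: float = 0.5,
    min_containment: float = 0.8,
) -> bool:
    """Declared operationalization of the visual stack inspection."""
    return (
        profile.uniformity_score is not None
        and profile.uniformity_score >= min_uniformity
        and profile.containment_score >= min_containment
    )
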