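"""Blacklist construction and alignment filtering.

The blacklist is the strand-agnostic merged union of: the entire mitochondrial
contig, all sncRNA / tRNA / miRNA-primary-transcript intervals, and repeat
intervals strictly longer than 24 bp. An alignment is removed iff it lies on
the mitochondrial contig or overlaps any blacklist interval by >= 1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .types import FEATURE_CLASSES, AlignmentRecord, AnnotationFeature


@dataclass
class Blacklist:
    """Merged per-chromosome interval set plus the mito contig name."""

    intervals: dict[str, list[tuple[int, int]]]
    mito_chrom: str | None = None
    # unmerged features kept for attributing removals to a feature class
    features: list[AnnotationFeature] = field(default_factory=list)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._trees = {
            chrom: IntervalTree.from_tuples(ivs)
            for chrom, ivs in self.intervals.items()
            if ivs
        }

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if self.mito_chrom is not None and chrom == self.mito_chrom:
            return True
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def first_overlap_class(self, chrom: str, start: int, end: int) -> str | None:
        """Feature class of the lowest-start overlapping annotation (mito wins)."""
        if self.mito_chrom is not None and chrom == self.mito_chrom:
            return "mito"
        best: tuple[int, int, str] | None = None
        for ft in self.features:
            iv = ft.interval
            if iv.chrom == chrom and iv.start < end and start < iv.end:
                key = (iv.start, iv.end, ft.feature_class)
                if best is None or key < best:
                    best = key
        return best[2] if best else None

    @property
    def total_bp(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)


def build_blacklist(
    features: Sequence[AnnotationFeature],
    mito_chrom: str | None = None,
    repeat_min_len_exclusive: int = 24,
) -> Blacklist:
    """Merge blacklist-eligible annotation intervals.

    Repeats contribute only when strictly longer than
    ``repeat_min_len_exclusive`` (default 24 bp: a 24-bp repeat is kept out of
    the blacklist, a 25-bp one goes in). The merge ignores strand.
    """
    eligible: list[AnnotationFeature] = []
    for ft in features:
        if ft.feature_class not in FEATURE_CLASSES:  # defensive; type also checks
            raise ValueError(f"unknown feature_class: {ft.feature_class!r}")
        if ft.feature_class == "repeat" and ft.length <= repeat_min_len_exclusive:
            continue
        eligible.append(ft)

    trees: dict[str, IntervalTree] = {}
    for ft in eligible:
        trees.setdefault(ft.interval.chrom, IntervalTree()).addi(
            ft.interval.start, ft.interval.end
        )
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, tree in trees.items():
        tree.merge_overlaps(strict=False)
        merged[chrom] = sorted((iv.begin, iv.end) for iv in tree)
    return Blacklist(intervals=merged, mito_chrom=mito_chrom, features=eligible)


@dataclass
class FilterStats:
    """Read accounting for blacklist filtering."""

    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)
    removed_by_class: dict[tuple[str, str], int] = field(default_factory=dict)

    def _bump(self, sample: str, key: str) -> None:
        d = self.per_sample.setdefault(
            sample, {"input": 0, "removed": 0, "retained": 0}
        )
        d[key] += 1

    @property
    def n_input(self) -> int:
        return sum(d["input"] for d in self.per_sample.values())

    @property
    def n_removed(self) -> int:
        return sum(d["removed"] for d in self.per_sample.values())

    @property
    def n_retained(self) -> int:
        return sum(d["retained"] for d in self.per_sample.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, **d} for s, d in sorted(self.per_sample.items())
        ]
        return pd.DataFrame(rows, columns=["sample_id", "input", "removed", "retained"])


def filter_alignments(
    alignments: Iterable[AlignmentRecord],
    blacklist: Blacklist,
    valid_chroms: Iterable[str] | None = None,
) -> tuple[list[AlignmentRecord], FilterStats]:
    """Remove alignments touching the blacklist (>=1 bp, strand-agnostic).

    Returns the retained records (input order preserved) and per-sample /
    per-class accounting. With ``valid_chroms`` given, an alignment on an
    unknown contig raises.
    """
    valid = set(valid_chroms) if valid_chroms is not None else None
    retained: list[AlignmentRecord] = []
    stats = FilterStats()
    for aln in alignments:
        iv = aln.interval
        if valid is not None and iv.chrom not in valid:
            raise ValueError(f"alignment on unknown contig: {iv.chrom}")
        stats._bump(aln.sample_id, "input")
        if blacklist.overlaps(iv.chrom, iv.start, iv.end):
            stats._bump(aln.sample_id, "removed")
            cls = blacklist.first_overlap_class(iv.chrom, iv.start, iv.end) or "?"
            key = (aln.sample_id, cls)
            stats.removed_by_class[key] = stats.removed_by_class.get(key, 0) + 1
        else:
            stats._bump(aln.sample_id, "retained")
            retained.append(aln)
    return retained, stats
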