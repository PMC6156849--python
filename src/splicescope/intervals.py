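"""Genomic interval primitives shared by the splicing graph and event matching.

Coordinates are 0-based, half-open throughout the package; GTF input/output
converts from/to the 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on a given chromosome/strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge an interval collection into sorted, disjoint intervals.

    Abutting intervals ([a,b) and [b,c)) are fused. Chromosomes are kept
    separate; the strand of a merged run is taken from its first member.
    """
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_pos:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total genomic span covered (intervals are merged first)."""
    return sum(iv.length for iv in merge_intervals(intervals))


def region_subset(x: Sequence[GenomicInterval], y: Sequence[GenomicInterval]) -> bool:
    """True iff every base of ``x`` is covered by the union of ``y``.

    Regions on different chromosomes are never subsets of one another;
    an empty ``x`` is vacuously contained.
    """
    ym = merge_intervals(y)
    for iv in merge_intervals(x):
        covered = any(
            m.chrom == iv.chrom and m.start <= iv.start and iv.end <= m.end for m in ym
        )
        if not covered:
            return False
    return True


def regions_overlap(x: Sequence[GenomicInterval], y: Sequence[GenomicInterval]) -> bool:
    """True iff some base belongs to both interval unions."""
    for a in merge_intervals(x):
        for b in merge_intervals(y):
            if a.overlaps(b):
                return True
    return False
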