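"""Genomic interval primitives.

All internal coordinates are 0-based half-open ``[start, end)``. Conversion
from 1-based inclusive formats (SEG-like TSV, printed locus coordinates)
happens at I/O time, never here.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple


class GenomicInterval(NamedTuple):
    """A half-open genomic interval on one chromosome."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def validate(self) -> "GenomicInterval":
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )
        return self


def merge_intervals(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping ``(start, end)`` spans into a disjoint union.

    Empty spans are dropped. Touching spans (end == next start) are merged.
    """
    spans = sorted((s, e) for s, e in spans if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def union_overlap_length(
    start: int, end: int, spans: Iterable[tuple[int, int]]
) -> int:
    """Total number of bases of ``[start, end)`` covered by the union of spans.

    Overlapping spans are not double-counted.
    """
    clipped = (
        (max(start, s), min(end, e)) for s, e in spans if e > start and s < end
    )
    return sum(e - s for s, e in merge_intervals(clipped))
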