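"""Genomic interval primitives shared by every pipeline stage.

All internal coordinates are 0-based, half-open ``[start, end)``, the BED
convention. GFF3 input (1-based, inclusive) is converted on read and never
carried around internally, so every downstream operation can assume a single
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "ArmMask",
    "merge_intervals",
    "complement_intervals",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome.

    ``strand`` is one of ``+``, ``-`` or ``.`` (strand-less).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.overlap_len(other) > 0

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = f"{self.chrom}:{self.start}-{self.end}"
        return s if self.strand == "." else f"{s}({self.strand})"


def merge_intervals(
    intervals: Iterable[GenomicInterval], bookended: bool = False
) -> list[GenomicInterval]:
    """Merge overlapping intervals into a sorted, pairwise-disjoint list.

    With ``bookended=False`` (default) only intervals sharing >=1 bp are
    merged; abutting intervals ([0,5) and [5,9)) stay separate.  Strand is
    dropped on output.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            joined = iv.start <= cur_end if bookended else iv.start < cur_end
            if joined:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def complement_intervals(
    intervals: Sequence[GenomicInterval], span: GenomicInterval
) -> list[GenomicInterval]:
    """Gaps of ``span`` not covered by ``intervals`` (zero-length gaps dropped)."""
    covered = merge_intervals(
        [iv for iv in intervals if iv.chrom == span.chrom and iv.overlap_len(span) > 0],
        bookended=True,
    )
    out: list[GenomicInterval] = []
    cursor = span.start
    for iv in covered:
        lo, hi = max(iv.start, span.start), min(iv.end, span.end)
        if lo > cursor:
            out.append(GenomicInterval(span.chrom, cursor, lo))
        cursor = max(cursor, hi)
    if cursor < span.end:
        out.append(GenomicInterval(span.chrom, cursor, span.end))
    return out


class ArmMask:
    """Excluded regions (centromere / telomere / rDNA) normalized per chromosome.

    Peaks and sites overlapping the mask by >=1 bp are discarded, and
    chromosome "arms" are the per-chromosome complement of the mask.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self.intervals = merge_intervals(list(intervals), bookended=True)
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)

    def overlaps(self, interval: GenomicInterval) -> bool:
        return any(interval.overlaps(iv) for iv in self._by_chrom.get(interval.chrom, ()))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return any(iv.contains(pos) for iv in self._by_chrom.get(chrom, ()))

    def arms(self, chrom_lengths: dict[str, int]) -> dict[str, list[GenomicInterval]]:
        """Unmasked intervals per chromosome."""
        return {
            chrom: complement_intervals(
                self._by_chrom.get(chrom, []), GenomicInterval(chrom, 0, length)
            )
            for chrom, length in chrom_lengths.items()
        }

    def __len__(self) -> int:
        return len(self.intervals)
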