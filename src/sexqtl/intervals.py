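"""Genomic coordinate primitives.

All coordinates are 0-based half-open (BED convention).  Every overlap,
intersection and distance rule in the pipeline — peak sharing, variant
containment, eQTL/TAD narrowing — reduces to the ``>= 1 bp overlap``
semantics defined here, so the conventions are fixed in one place:

* two intervals overlap iff they share at least one base
  (``max(starts) < min(ends)`` on the same chromosome);
* an interval never contains its exclusive ``end`` coordinate;
* distances across chromosomes are a typed sentinel (``None``), never a
  large magic number.

Strand is carried on gene records but deliberately ignored by distance
logic: TSS-to-region distances are unstranded.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff ``pos`` (0-based) lies inside the half-open span."""
        return chrom == self.chrom and self.start <= pos < self.end

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class GeneRecord:
    """A gene anchored by its TSS; strand stored but unused for distances."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class TadRecord:
    tad_id: str
    interval: GenomicInterval


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Share >= 1 bp?  Half-open: adjacency is not overlap."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def intersect(a: GenomicInterval, b: GenomicInterval) -> Optional[GenomicInterval]:
    """Maximal shared span, or None when the intervals are disjoint."""
    if not overlaps(a, b):
        return None
    return GenomicInterval(a.chrom, max(a.start, b.start), min(a.end, b.end))


def tss_distance(gene: GeneRecord, region: GenomicInterval) -> Optional[int]:
    """Unstranded distance from a gene's TSS to a region.

    0 when the TSS falls inside the region; otherwise the gap to the
    nearest contained base.  ``None`` across chromosomes.
    """
    if gene.chrom != region.chrom:
        return None
    if region.start <= gene.tss < region.end:
        return 0
    return min(abs(gene.tss - region.start), abs(gene.tss - (region.end - 1)))


class TadMap:
    """Non-overlapping TADs indexed for point lookup.

    Raises ``ValueError`` at construction if any two TADs on the same
    chromosome overlap — overlapping domains would make point assignment
    ambiguous.
    """

    def __init__(self, tads: Iterable[TadRecord]):
        by_chrom: dict[str, list[TadRecord]] = {}
        for t in tads:
            by_chrom.setdefault(t.interval.chrom, []).append(t)
        self._starts: dict[str, list[int]] = {}
        self._tads: dict[str, list[TadRecord]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda t: t.interval.start)
            for prev, cur in zip(recs, recs[1:]):
                if overlaps(prev.interval, cur.interval):
                    raise ValueError(
                        f"overlapping TADs on {chrom}: "
                        f"{prev.tad_id} and {cur.tad_id}"
                    )
            self._tads[chrom] = recs
            self._starts[chrom] = [t.interval.start for t in recs]

    def __iter__(self):
        for recs in self._tads.values():
            yield from recs

    def __len__(self) -> int:
        return sum(len(v) for v in self._tads.values())

    def assign(self, chrom: str, pos: int) -> Optional[TadRecord]:
        """The unique TAD containing ``pos`` (half-open), else None."""
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = bisect.bisect_right(starts, pos) - 1
        if i < 0:
            return None
        tad = self._tads[chrom][i]
        return tad if tad.interval.contains(chrom, pos) else None

    def overlapping(self, region: GenomicInterval) -> list[TadRecord]:
        """All TADs sharing >= 1 bp with ``region``."""
        recs = self._tads.get(region.chrom, [])
        return [t for t in recs if overlaps(t.interval, region)]
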