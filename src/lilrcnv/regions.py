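"""Locus geometry: genomic intervals and the region registry.

All coordinates are 0-based, half-open (BED convention) everywhere in the
package; 1-based formats (GFF3, VCF) are converted on read/write.

The region registry (:class:`RegionSet`) captures the anatomy the caller
relies on:

* ``core_b3`` / ``core_a6`` -- paralog-specific subintervals unique enough
  for reads to map with high MAPQ, distinguishing LILRB3 from LILRA6;
* ``body`` -- the combined footprint of both paralog units, where reads are
  counted regardless of mapping ambiguity so the total copy number is
  preserved;
* ``control`` -- presumed-diploid intervals used for depth normalization;
* ``unit_length`` -- the reference footprint of one paralog unit in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List

from .errors import LilrError

__all__ = ["GenomicInterval", "RegionSet", "total_length"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> int:
        """Overlap length in bp (0 when disjoint or on another chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # samtools-style, 1-based display
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)


def _covered(inner: GenomicInterval, outer: List[GenomicInterval]) -> bool:
    """True if `inner` is fully covered by the union of `outer` intervals."""
    pos = inner.start
    for iv in sorted(o for o in outer if o.chrom == inner.chrom):
        if iv.start > pos:
            break
        pos = max(pos, iv.end)
        if pos >= inner.end:
            return True
    return pos >= inner.end


@dataclass
class RegionSet:
    """Named regions of the LILR locus plus the paralog unit length."""

    core_b3: List[GenomicInterval] = field(default_factory=list)
    core_a6: List[GenomicInterval] = field(default_factory=list)
    body: List[GenomicInterval] = field(default_factory=list)
    control: List[GenomicInterval] = field(default_factory=list)
    unit_length: int = 8000

    ROLES = ("core_b3", "core_a6", "body", "control")

    def validate(self) -> None:
        if self.unit_length <= 0:
            raise LilrError(f"unit_length must be positive, got {self.unit_length}")
        for a in self.core_b3:
            for b in self.core_a6:
                if a.overlaps(b):
                    raise LilrError(f"core regions overlap: {a} / {b}")
        for core in (*self.core_b3, *self.core_a6):
            if not _covered(core, self.body):
                raise LilrError(f"core region {core} not contained in body")
        for c in self.control:
            for b in self.body:
                if c.overlaps(b):
                    raise LilrError(f"control region {c} overlaps body {b}")

    def by_role(self, role: str) -> List[GenomicInterval]:
        if role not in self.ROLES:
            raise LilrError(f"unknown region role {role!r}; expected one of {self.ROLES}")
        return getattr(self, role)

    def chroms(self) -> List[str]:
        seen: List[str] = []
        for role in self.ROLES:
            for iv in self.by_role(role):
                if iv.chrom not in seen:
                    seen.append(iv.chrom)
        return seen
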