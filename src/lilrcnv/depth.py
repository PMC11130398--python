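"""Binned read depth, copy-number normalization, and cluster coordinates.

The normalization scheme: a robust diploid baseline ``c`` (median per-base
depth over presumed-diploid control regions) converts read depth into
normalized copy numbers,

    cn(region)  = 2 * mean per-base depth(region) / c
    cn_sum      = 2 * total read-bases(body) / (c * unit_length)

Paralog-specific core regions are counted at MAPQ >= 30 so only uniquely
mapped reads contribute, while the combined gene-body footprint is counted
at MAPQ >= 0 so reads from the ~5 kb LILRB3/LILRA6 homology tract -- which
map ambiguously but land somewhere inside the body -- are counted exactly
once. That split is what keeps the sum informative where the paralogs are
indistinguishable.

The cluster plot places each sample at x = cn_sum and y = cn_b3core /
cn_a6core; when LILRA6 is absent the ratio diverges, so y is pinned to the
conventional placeholder 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .alignments import AlignmentRecord
from .errors import LilrError
from .regions import GenomicInterval, RegionSet

__all__ = [
    "DepthProfile",
    "NormalizedCN",
    "ClusterPoint",
    "QCMetrics",
    "bin_depth",
    "control_depth",
    "region_cn",
    "cn_sum",
    "cluster_coordinates",
    "qc_cnv2_ratio",
    "sample_cn",
]

ZERO_COPY_PLACEHOLDER = 4.0


@dataclass(frozen=True)
class NormalizedCN:
    cn_b3core: float
    cn_a6core: float
    cn_sum: float

    def __post_init__(self) -> None:
        if min(self.cn_b3core, self.cn_a6core, self.cn_sum) < 0:
            raise ValueError(f"normalized CNs must be >= 0: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.cn_b3core, self.cn_a6core, self.cn_sum])


@dataclass(frozen=True)
class ClusterPoint:
    x: float
    y: float


@dataclass(frozen=True)
class QCMetrics:
    cnv2_ratio: float
    passed: bool


@dataclass
class DepthProfile:
    """Per-sample binned read-base counts over a set of intervals.

    ``bins`` tile their source intervals without overlap; counts are
    read-bases (aligned bases falling in the bin), so per-base depth of a
    bin is count / bin width. Counts are floats so the simulator's exact
    expected-depth mode can reuse the container.
    """

    sample_id: str
    bin_size: int
    bins: List[Tuple[GenomicInterval, float]]
    mapq_min: int

    def __post_init__(self) -> None:
        for iv, count in self.bins:
            if count < 0:
                raise LilrError(f"negative bin count at {iv}")

    def restrict(self, intervals: Sequence[GenomicInterval]) -> "DepthProfile":
        """Profile over bins overlapping any of `intervals`, counts scaled by
        overlap fraction (exact when bins nest inside the intervals)."""
        out: List[Tuple[GenomicInterval, float]] = []
        for iv, count in self.bins:
            ov = sum(iv.intersection(r) for r in intervals)
            if ov > 0:
                out.append((iv, count * ov / iv.length))
        return DepthProfile(self.sample_id, self.bin_size, out, self.mapq_min)

    def per_base_depths(self) -> np.ndarray:
        return np.array([count / iv.length for iv, count in self.bins])

    def total_bases(self) -> float:
        return float(sum(count for _, count in self.bins))


def tile(intervals: Sequence[GenomicInterval], bin_size: int) -> List[GenomicInterval]:
    """Tile each interval with bins of `bin_size` (last bin may be short)."""
    bins = []
    for iv in intervals:
        for s in range(iv.start, iv.end, bin_size):
            bins.append(GenomicInterval(iv.chrom, s, min(s + bin_size, iv.end)))
    return bins


def bin_depth(
    alignments: Iterable[AlignmentRecord],
    intervals: Sequence[GenomicInterval],
    bin_size: int = 100,
    mapq_min: int = 0,
    sample_id: str = "sample",
) -> DepthProfile:
    """Count aligned read-bases per bin for reads with MAPQ >= `mapq_min`.

    Alignments must be coordinate-sorted per chromosome is NOT required here
    (counting is positional), but unknown chromosomes are a hard error so a
    mismatched reference does not silently yield zero depth.
    """
    if bin_size < 10:
        raise LilrError(f"bin_size must be >= 10, got {bin_size}")
    if not intervals:
        raise LilrError("empty interval list")
    known = {iv.chrom for iv in intervals}
    bins = tile(intervals, bin_size)
    counts = np.zeros(len(bins))
    # index: chrom -> sorted bin starts (bins within one interval are contiguous)
    by_chrom: dict = {}
    for i, b in enumerate(bins):
        by_chrom.setdefault(b.chrom, []).append(i)

    for rec in alignments:
        if rec.chrom not in known:
            raise LilrError(f"alignment on unknown chromosome {rec.chrom!r}")
        if rec.mapq < mapq_min:
            continue
        for bs, be in rec.reference_blocks():
            for i in by_chrom[rec.chrom]:
                ov = max(0, min(be, bins[i].end) - max(bs, bins[i].start))
                if ov:
                    counts[i] += ov
    return DepthProfile(sample_id, bin_size, list(zip(bins, counts.tolist())), mapq_min)


def control_depth(profile: DepthProfile) -> float:
    """Robust diploid per-base baseline: median of per-bin per-base depths.

    The median tolerates occasional CNVs or mapping dropouts inside the
    control regions, which a mean would not.
    """
    if len(profile.bins) < 10:
        raise LilrError(f"need >= 10 control bins, got {len(profile.bins)}")
    c = float(np.median(profile.per_base_depths()))
    if c <= 0:
        raise LilrError("no coverage in control regions")
    return c


def region_cn(profile: DepthProfile, region: Sequence[GenomicInterval], c: float) -> float:
    """Normalized CN of a region: 2 x mean per-base depth / baseline."""
    if c <= 0:
        raise LilrError(f"baseline depth must be positive, got {c}")
    length = sum(iv.length for iv in region)
    if length == 0:
        raise LilrError("zero-length region")
    sub = profile.restrict(region)
    return 2.0 * sub.total_bases() / length / c


def cn_sum(profile: DepthProfile, c: float, unit_length: int) -> float:
    """Total paralog copies from the gene-body footprint.

    2 x (read-bases over body) / (c x unit_length); for a genotype with b3
    copies of LILRB3 and a6 of LILRA6 the expectation is b3 + a6, because
    each unit contributes unit_length bases of footprint per copy.
    """
    if unit_length <= 0:
        raise LilrError(f"unit_length must be positive, got {unit_length}")
    if c <= 0:
        raise LilrError(f"baseline depth must be positive, got {c}")
    return 2.0 * profile.total_bases() / (c * unit_length)


def cluster_coordinates(n: NormalizedCN, zero_threshold: float = 0.3) -> ClusterPoint:
    """Map normalized CNs to the (sum, ratio) cluster-plot coordinates.

    Below `zero_threshold` the LILRA6 core CN is treated as zero copies and
    the unstable ratio is replaced by the placeholder y = 4. Total function:
    never NaN or infinite.
    """
    if n.cn_a6core < zero_threshold:
        return ClusterPoint(x=n.cn_sum, y=ZERO_COPY_PLACEHOLDER)
    y = n.cn_b3core / n.cn_a6core
    if not math.isfinite(y):  # pragma: no cover - guarded by threshold
        y = ZERO_COPY_PLACEHOLDER
    return ClusterPoint(x=n.cn_sum, y=y)


def qc_cnv2_ratio(
    control_profile: DepthProfile,
    c: float,
    threshold: float = 0.85,
    band: Tuple[float, float] = (1.5, 2.5),
) -> QCMetrics:
    """Fraction of control bins whose normalized CN sits in the diploid band.

    A sample passes when that fraction exceeds `threshold` (default 0.85).
    """
    if len(control_profile.bins) < 10:
        raise LilrError(f"need >= 10 control bins, got {len(control_profile.bins)}")
    cns = 2.0 * control_profile.per_base_depths() / c
    ratio = float(np.mean((cns >= band[0]) & (cns <= band[1])))
    return QCMetrics(cnv2_ratio=ratio, passed=ratio > threshold)


def sample_cn(
    profile_core: DepthProfile,
    profile_body: DepthProfile,
    regions: RegionSet,
    zero_threshold: float = 0.3,
    cnv2_threshold: float = 0.85,
) -> Tuple[NormalizedCN, ClusterPoint, QCMetrics]:
    """Full per-sample summary from the two MAPQ views.

    `profile_core` is the high-MAPQ view (core regions), `profile_body` the
    MAPQ-0 view (control + body). Returns the normalized CN triple, its
    cluster-plot coordinates, and the cnv2 QC metric.
    """
    ctrl = profile_body.restrict(regions.control)
    c = control_depth(ctrl)
    n = NormalizedCN(
        cn_b3core=region_cn(profile_core, regions.core_b3, c),
        cn_a6core=region_cn(profile_core, regions.core_a6, c),
        cn_sum=cn_sum(profile_body.restrict(regions.body), c, regions.unit_length),
    )
    point = cluster_coordinates(n, zero_threshold=zero_threshold)
    qc = qc_cnv2_ratio(ctrl, c, threshold=cnv2_threshold)
    return n, point, qc
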