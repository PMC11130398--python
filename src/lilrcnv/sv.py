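"""Large-deletion calling from long-read alignments.

HiFi-scale reads spanning a multi-kilobase deletion show up in two ways
after alignment: a single record whose CIGAR carries a long D operation, or
a primary + supplementary split pair adjacent in read coordinates with a
reference gap. Candidates from both channels are pooled, single-linkage
clustered on (start, end), summarized by median breakpoints, left-aligned
against the reference when available (deletions inside an identity tract --
the NAHR substrate -- are only defined up to a shift within the tract), and
genotyped from the variant allele fraction of breakpoint-spanning reads.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .alignments import AlignmentRecord
from .errors import LilrError
from .regions import GenomicInterval

__all__ = [
    "DeletionCandidate",
    "DeletionCall",
    "cigar_deletions",
    "split_read_deletions",
    "cluster_calls",
    "genotype_call",
    "call_deletions",
    "write_vcf",
    "read_vcf",
]

MIN_DEL_LENGTH = 50
POS_TOL = 50
MIN_SUPPORT = 3


@dataclass(frozen=True)
class DeletionCandidate:
    interval: GenomicInterval
    source: str  # "cigar" | "split"
    read_id: str


@dataclass
class DeletionCall:
    interval: GenomicInterval
    support: int
    spanning_ref: int = 0
    vaf: float = 0.0
    genotype: Optional[str] = None  # "het" | "hom" | None (filtered)
    breakpoint_stddev: float = 0.0
    read_ids: List[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.interval.length


def cigar_deletions(a: AlignmentRecord, min_del_length: int = MIN_DEL_LENGTH) -> List[DeletionCandidate]:
    """One candidate per D/N operation of at least `min_del_length` bp."""
    out = []
    ref = a.pos
    for op, n in a.ops:
        if op in ("M", "=", "X"):
            ref += n
        elif op in ("D", "N"):
            if n >= min_del_length:
                out.append(
                    DeletionCandidate(GenomicInterval(a.chrom, ref, ref + n), "cigar", a.read_id)
                )
            ref += n
    return out


def split_read_deletions(
    records: Sequence[AlignmentRecord],
    min_del_length: int = MIN_DEL_LENGTH,
    max_query_gap: int = 100,
) -> List[DeletionCandidate]:
    """Deletion candidates from split (primary + supplementary) alignments.

    For same-chromosome, same-strand record pairs of one read that are
    adjacent in read coordinates (query gap <= `max_query_gap`) with a
    reference gap of at least `min_del_length`, emit a candidate of length
    (reference gap - query gap). Opposite-strand pairs signal inversions and
    are ignored.
    """
    ids = {r.read_id for r in records}
    if len(ids) > 1:
        raise LilrError(f"split_read_deletions got records from several reads: {sorted(ids)}")
    if len(records) < 2:
        return []
    segs = sorted(records, key=lambda r: r.query_start)
    out = []
    for left, right in zip(segs, segs[1:]):
        if left.chrom != right.chrom or left.strand != right.strand:
            continue
        query_gap = right.query_start - left.query_end
        if abs(query_gap) > max_query_gap:
            continue
        ref_gap = right.pos - left.reference_end
        length = ref_gap - max(query_gap, 0)
        if length >= min_del_length:
            start = left.reference_end
            out.append(
                DeletionCandidate(
                    GenomicInterval(left.chrom, start, start + length), "split", left.read_id
                )
            )
    return out


def _single_linkage(cands: List[DeletionCandidate], pos_tol: int) -> List[List[int]]:
    """Single-linkage clusters: candidates link when both breakpoints agree
    within `pos_tol`. Input is sorted first, so clustering is order-independent."""
    n = len(cands)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = cands[i].interval, cands[j].interval
            if b.start - a.start > pos_tol:  # sorted by start: no later j can link to i
                break
            if (
                a.chrom == b.chrom
                and abs(a.start - b.start) <= pos_tol
                and abs(a.end - b.end) <= pos_tol
            ):
                parent[find(i)] = find(j)
    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def cluster_calls(
    candidates: Iterable[DeletionCandidate], pos_tol: int = POS_TOL
) -> List[DeletionCall]:
    """Cluster candidates into consensus calls (median breakpoints).

    Support counts distinct reads, so a read contributing both a CIGAR and
    a split candidate is not double counted.
    """
    cands = sorted(candidates, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    calls = []
    for group in _single_linkage(cands, pos_tol):
        members = [cands[i] for i in group]
        starts = np.array([m.interval.start for m in members])
        ends = np.array([m.interval.end for m in members])
        start = int(np.median(starts))
        end = int(np.median(ends))
        reads = sorted({m.read_id for m in members})
        stddev = float(np.sqrt((np.var(starts) + np.var(ends)) / 2))
        calls.append(
            DeletionCall(
                interval=GenomicInterval(members[0].interval.chrom, start, end),
                support=len(reads),
                breakpoint_stddev=stddev,
                read_ids=reads,
            )
        )
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return calls


def left_align(call: DeletionCall, reference: Dict[str, str]) -> DeletionCall:
    """Shift the deletion to the smallest start consistent with the sequence.

    Standard VCF normalization: while the base before the deletion equals
    the last deleted base, the interval can slide left without changing the
    alternate sequence (exactly the ambiguity created by the identity tract
    at an NAHR junction).
    """
    seq = reference.get(call.interval.chrom)
    if seq is None:
        return call
    s, e = call.interval.start, call.interval.end
    while s > 0 and e - 1 < len(seq) and seq[s - 1] == seq[e - 1]:
        s -= 1
        e -= 1
    if s != call.interval.start:
        call.interval = GenomicInterval(call.interval.chrom, s, e)
    return call


def genotype_call(
    call: DeletionCall,
    spanning_ref: int,
    min_support: int = MIN_SUPPORT,
    het_band: Tuple[float, float] = (0.2, 0.8),
) -> Optional[DeletionCall]:
    """Assign het/hom from the variant allele fraction.

    vaf = support / (support + spanning_ref); het inside `het_band`, hom
    above it. Calls below `min_support` or below the het band are dropped
    (returned as None) with a log line on stderr.
    """
    if call.support < min_support:
        print(
            f"[lilrcnv] dropped {call.interval} ({call.length} bp): "
            f"support {call.support} < {min_support}",
            file=sys.stderr,
        )
        return None
    call.spanning_ref = spanning_ref
    call.vaf = call.support / (call.support + spanning_ref)
    if call.vaf > het_band[1]:
        call.genotype = "hom"
    elif call.vaf >= het_band[0]:
        call.genotype = "het"
    else:
        print(
            f"[lilrcnv] dropped {call.interval}: VAF {call.vaf:.3f} below "
            f"{het_band[0]}",
            file=sys.stderr,
        )
        return None
    return call


def _count_spanning_ref(
    records: Sequence[AlignmentRecord], call: DeletionCall, margin: int = 20
) -> int:
    """Reads covering the left breakpoint contiguously without the deletion."""
    window = (call.interval.start - margin, call.interval.start + margin)
    supporting = set(call.read_ids)
    spanning = set()
    for rec in records:
        if rec.chrom != call.interval.chrom or rec.read_id in supporting:
            continue
        for bs, be in rec.reference_blocks():
            if bs <= window[0] and window[1] <= be:
                spanning.add(rec.read_id)
                break
    return len(spanning)


def call_deletions(
    records: Sequence[AlignmentRecord],
    min_del_length: int = MIN_DEL_LENGTH,
    pos_tol: int = POS_TOL,
    min_support: int = MIN_SUPPORT,
    region: Optional[GenomicInterval] = None,
    reference: Optional[Dict[str, str]] = None,
) -> List[DeletionCall]:
    """End-to-end deletion calling: candidates -> clusters -> genotypes."""
    if region is not None:
        records = [
            r
            for r in records
            if r.chrom == region.chrom and r.pos < region.end and r.reference_end > region.start
        ]
    candidates: List[DeletionCandidate] = []
    by_read: Dict[str, List[AlignmentRecord]] = {}
    for rec in records:
        by_read.setdefault(rec.read_id, []).append(rec)
        candidates.extend(cigar_deletions(rec, min_del_length))
    for read_records in by_read.values():
        candidates.extend(split_read_deletions(read_records, min_del_length))
    calls = cluster_calls(candidates, pos_tol)
    if reference is not None:
        calls = [left_align(c, reference) for c in calls]
    out = []
    for call in calls:
        spanning = _count_spanning_ref(records, call)
        genotyped = genotype_call(call, spanning, min_support)
        if genotyped is not None:
            out.append(genotyped)
    return out


# -- VCF 4.2 ------------------------------------------------------------

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=lilrcnv
##ALT=<ID=DEL,Description="Deletion">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Difference in length between REF and ALT alleles">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Number of supporting reads">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">
##INFO=<ID=STDDEV,Number=1,Type=Float,Description="Breakpoint standard deviation (bp)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    calls: Sequence[DeletionCall],
    path,
    reference: Optional[Dict[str, str]] = None,
    contig_lengths: Optional[Dict[str, int]] = None,
    sample: str = "SAMPLE",
) -> None:
    """Write deletion calls as VCF 4.2 with symbolic <DEL> alleles.

    POS is the 1-based base before the deleted segment when an anchor base
    is available; SVLEN is negative by the VCF deletion convention.
    """
    lengths = dict(contig_lengths or {})
    for c in calls:
        lengths.setdefault(c.interval.chrom, max(c.interval.end + 1, 10**6))
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for chrom, ln in lengths.items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for i, c in enumerate(sorted(calls, key=lambda c: (c.interval.chrom, c.interval.start)), 1):
            pos = c.interval.start  # 1-based anchor = 0-based start
            ref_base = "N"
            if reference and c.interval.chrom in reference and pos >= 1:
                ref_base = reference[c.interval.chrom][pos - 1]
            gt = {"het": "0/1", "hom": "1/1"}.get(c.genotype or "", "./.")
            info = (
                f"SVTYPE=DEL;END={c.interval.end};SVLEN={-c.length};"
                f"SUPPORT={c.support};VAF={c.vaf:.6g};STDDEV={c.breakpoint_stddev:.6g}"
            )
            fh.write(
                f"{c.interval.chrom}\t{pos}\tDEL{i}\t{ref_base}\t<DEL>\t.\tPASS\t{info}\tGT\t{gt}\n"
            )


def read_vcf(path) -> List[DeletionCall]:
    """Parse deletion calls back from a VCF (via pysam)."""
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.info.get("SVTYPE") != "DEL":
                continue
            start = rec.pos  # pysam .pos is 1-based anchor; 0-based start = pos
            end = int(rec.stop)  # INFO/END (pysam reserves it as .stop)
            sample = rec.samples[0] if rec.samples else None
            gt = None
            if sample is not None and sample.get("GT") is not None:
                alleles = sample["GT"]
                if alleles == (0, 1) or alleles == (1, 0):
                    gt = "het"
                elif alleles == (1, 1):
                    gt = "hom"
            calls.append(
                DeletionCall(
                    interval=GenomicInterval(rec.chrom, start, end),
                    support=int(rec.info.get("SUPPORT", 0)),
                    vaf=float(rec.info.get("VAF", 0.0)),
                    genotype=gt,
                    breakpoint_stddev=float(rec.info.get("STDDEV", 0.0)),
                )
            )
    return calls
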