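"""Synthetic LILR-like locus and data generator with planted ground truth.

The toy locus emulates the anatomy that makes the real LILRB3/LILRA6 region
hard: a presumed-diploid control segment followed by a three-gene cluster
(B5 - A6 - B3) in which the two paralog units share a ~5 kb verbatim
homology tract (so short reads cannot be assigned to either paralog there),
plus a 269 bp identity tract copied into B5 intron 12 and B3 intron 11 (the
NAHR substrate). The planted hybrid-forming deletion joins B5 intron 12 to
B3 intron 11, removing B5 exon 13, all of A6, and B3 exons 1-11 -- exactly
the fusion geometry the analysis modules must recover.

Design notes baked into the construction:

* every exon length is a multiple of 3, so each exon is frame-neutral and
  planted ITIM codons stay in frame in both the native and fused
  transcripts;
* the A6/B3 exon-intron period is identical (600 bp) and the homology copy
  is phase-aligned, so copying the tract preserves gene structure;
* exonic stop codons and tyrosines outside the planted ITIMs are scrubbed,
  so motif counts on translated products are exact by construction;
* the bases flanking both identity-tract copies are forced to differ, so
  the longest common substring is exactly ``identity_tract`` bp and the
  planted deletion is already left-aligned;
* sequence content is otherwise random, GC-neutral DNA -- no attempt to
  mimic real LILR sequence.

All randomness flows from ``SimulationConfig.seed`` through one generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .alignments import AlignmentRecord
from .caller import HaplotypeCNType
from .depth import DepthProfile, sample_cn
from .errors import LilrError
from .regions import GenomicInterval, RegionSet

__all__ = [
    "SimulationConfig",
    "ToyLocus",
    "TruthRecord",
    "Haplotype",
    "build_toy_locus",
    "make_haplotype",
    "events_for",
    "simulate_depth",
    "simulate_long_reads",
    "simulate_cohort",
    "draw_diplotypes",
]

CHROM = "chrS"

# fixed gene architecture of the toy locus (bp)
B5_EXON, B5_INTRON, N_EXONS = 120, 600, 13
PARA_EXON, PARA_INTRON = 102, 498  # A6/B3; period 600, exon length % 3 == 0
PARA_SPAN = N_EXONS * PARA_EXON + (N_EXONS - 1) * PARA_INTRON  # 7302
B5_SPAN = N_EXONS * B5_EXON + (N_EXONS - 1) * B5_INTRON        # 8760

STOPS = {"TAA", "TAG", "TGA"}
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "AGC", "T": "ACT", "V": "GTG",
    "W": "TGG", "Y": "TAT",
}

# planted ITIM hexamers: three on B5 exon 13 (lost in the hybrid), four on
# B3 -- one on exon 11 (lost) and three on exons 12-13 (retained), so the
# fused protein carries 3 of the 4 B3 ITIMs
B5_EX13_ITIMS = ["VTYAQL", "ITYAGL", "LHYASV"]
B3_ITIMS = {11: ["SVYATL"], 12: ["VTYAEL"], 13: ["SIYATL", "LTYAKV"]}


@dataclass
class SimulationConfig:
    seed: int
    control_length: int = 50_000
    unit_length: int = 8_000
    homology_tract: int = 5_000
    identity_tract: int = 269
    hybrid_del_length: int = 33_692
    mean_depth: float = 30.0
    read_length_mean: int = 15_000
    read_length_sd: int = 3_000
    error_rate: float = 0.0
    bin_size: int = 100
    p_dop: float = 0.5  # P(deletion-crossing read reported as one D-op record)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise LilrError("SimulationConfig.seed is mandatory")
        for name in (
            "control_length", "unit_length", "homology_tract",
            "identity_tract", "hybrid_del_length",
        ):
            if getattr(self, name) <= 0:
                raise LilrError(f"{name} must be positive")
        if self.homology_tract > self.unit_length:
            raise LilrError("homology_tract exceeds unit_length")
        if self.unit_length < PARA_SPAN + 350:
            raise LilrError(f"unit_length must be >= {PARA_SPAN + 350}")
        if self.identity_tract > 400:
            raise LilrError("identity_tract must fit the breakpoint introns (<= 400 bp)")


def _gene_exons(chrom: str, start: int, exon: int, intron: int) -> List[GenomicInterval]:
    return [
        GenomicInterval(chrom, start + i * (exon + intron), start + i * (exon + intron) + exon)
        for i in range(N_EXONS)
    ]


@dataclass
class ToyLocus:
    """The built synthetic locus: reference, regions, genes, planted truth."""

    cfg: SimulationConfig
    reference: str
    regions: RegionSet
    genes: List  # GeneModel list (B5, A6, B3)
    a6_unit: GenomicInterval = None
    b3_unit: GenomicInterval = None
    a6_tract: GenomicInterval = None
    b3_tract: GenomicInterval = None
    del_start: int = 0
    del_end: int = 0

    @property
    def chrom(self) -> str:
        return CHROM

    @property
    def b5(self):
        return self.genes[0]

    @property
    def a6(self):
        return self.genes[1]

    @property
    def b3(self):
        return self.genes[2]

    def genome(self) -> Dict[str, str]:
        return {CHROM: self.reference}

    def write(self, outdir: Union[str, Path]) -> None:
        from . import formats

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        formats.write_fasta({CHROM: self.reference}, outdir / "reference.fa")
        formats.write_bed(self.regions, outdir / "regions.bed")
        formats.write_gff3(self.genes, outdir / "genes.gff3")


@dataclass
class TruthRecord:
    sample_id: str
    h1: HaplotypeCNType
    h2: HaplotypeCNType
    deletions: List[List[GenomicInterval]] = field(default_factory=lambda: [[], []])


@dataclass
class Haplotype:
    """A haplotype sequence plus its piecewise-colinear map to the reference.

    ``segments`` is a list of (hap_start, hap_end, ref_start): each segment
    maps hap coordinates to reference coordinates with identity offsets.
    """

    sequence: str
    segments: List[Tuple[int, int, int]]
    events: Tuple = ()

    def __len__(self) -> int:
        return len(self.sequence)


def build_toy_locus(cfg: SimulationConfig):
    """Deterministic synthetic locus for a given config (byte-identical per seed)."""
    from .hybrid import GeneModel

    rng = np.random.default_rng(cfg.seed)

    b5_start = cfg.control_length + 2000
    b5_exons = _gene_exons(CHROM, b5_start, B5_EXON, B5_INTRON)
    b5_end = b5_start + B5_SPAN
    # breakpoint + identity-tract source: 60 bp into B5 intron 12
    del_start = b5_exons[11].end + 60
    del_end = del_start + cfg.hybrid_del_length

    a6_unit = GenomicInterval(CHROM, b5_end + 1240, b5_end + 1240 + cfg.unit_length)
    a6_exons = _gene_exons(CHROM, a6_unit.start + 350, PARA_EXON, PARA_INTRON)
    a6_tract = GenomicInterval(CHROM, a6_unit.end - cfg.homology_tract, a6_unit.end)

    b3_unit = GenomicInterval(CHROM, del_end - cfg.unit_length, del_end)
    if b3_unit.start < a6_unit.end:
        raise LilrError(
            "hybrid_del_length too short: the B3 unit would overlap the A6 unit"
        )
    # del_end lands 90 bp into B3 intron 11: exon-11 end is gene_start + 6102
    b3_gene_start = del_end - (10 * (PARA_EXON + PARA_INTRON) + PARA_EXON + 90)
    b3_exons = _gene_exons(CHROM, b3_gene_start, PARA_EXON, PARA_INTRON)
    assert b3_exons[10].end + 90 == del_end
    b3_tract = GenomicInterval(
        CHROM, b3_gene_start - 350, b3_gene_start - 350 + cfg.homology_tract
    )
    if b3_tract.end > b3_unit.end or b3_tract.start < b3_unit.start:
        raise LilrError("homology tract does not fit inside the B3 unit")

    # generous downstream flank: reads from a deletion haplotype need room
    # to anchor beyond the junction, as they would on a real chromosome
    ref_len = b3_exons[-1].end + 23_098
    seq = np.frombuffer(
        rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=ref_len).tobytes(), dtype="S1"
    ).copy()

    def put(pos: int, s: str) -> None:
        seq[pos : pos + len(s)] = np.frombuffer(s.encode(), dtype="S1")

    def get(a: int, b: int) -> str:
        return seq[a:b].tobytes().decode()

    genes_exons = [b5_exons, a6_exons, b3_exons]
    nagnag = {(0, 8), (2, 12)}  # (gene index, 1-based exon no): B5 exon 8, B3 exon 12
    for gi, exons in enumerate(genes_exons):
        for no, exon in enumerate(exons, start=1):
            if no > 1:
                put(exon.start - 2, "AG")  # canonical acceptor
            if no < N_EXONS:
                put(exon.end, "GT")        # canonical donor
            # scrub accidental tandem acceptors; the designated ones are planted below
            if no > 1 and get(exon.start + 1, exon.start + 3) == "AG":
                put(exon.start + 2, "C")
            # frame-neutral exon: scrub stops (middle base) and stray tyrosines
            for p in range(exon.start, exon.end, 3):
                codon = get(p, p + 3)
                if codon in STOPS:
                    put(p + 1, "C")
                    codon = get(p, p + 3)
                if codon in ("TAT", "TAC"):
                    put(p, "C")
    for gi, no in nagnag:
        put(genes_exons[gi][no - 1].start, "CAG")  # exon starts nAG -> acceptor also at +3

    def plant_itims(exon: GenomicInterval, hexamers: Sequence[str], offsets: Sequence[int]) -> None:
        for hexamer, off in zip(hexamers, offsets):
            put(exon.start + off, "".join(CODON[a] for a in hexamer))

    plant_itims(b5_exons[12], B5_EX13_ITIMS, [12, 42, 72])
    for exon_no, hexamers in B3_ITIMS.items():
        plant_itims(b3_exons[exon_no - 1], hexamers, [12, 48])

    # paralog homology: B3 5' region is a verbatim, phase-aligned copy of the A6 3' region
    seq[b3_tract.start : b3_tract.end] = seq[a6_tract.start : a6_tract.end]
    # NAHR substrate: identity tract copied from B5 intron 12 into B3 intron 11
    seq[del_end : del_end + cfg.identity_tract] = seq[del_start : del_start + cfg.identity_tract]
    # force mismatching flanks: the tract is *exactly* identity_tract long and
    # the planted deletion is already left-aligned
    for src, dst in ((del_start - 1, del_end - 1), (del_start + cfg.identity_tract, del_end + cfg.identity_tract)):
        if seq[dst] == seq[src]:
            options = [b for b in b"ACGT" if bytes([b]) != seq[src]]
            put(dst, chr(options[0]))

    core_a6 = GenomicInterval(CHROM, a6_unit.start + 200, a6_tract.start - 200)
    core_b3 = GenomicInterval(CHROM, b3_tract.end + 50, del_end - 100)
    regions = RegionSet(
        core_b3=[core_b3],
        core_a6=[core_a6],
        body=[a6_unit, b3_unit],
        control=[GenomicInterval(CHROM, 0, cfg.control_length)],
        unit_length=cfg.unit_length,
    )
    regions.validate()

    genes = [
        GeneModel("B5", "+", b5_exons),
        GeneModel("A6", "+", a6_exons),
        GeneModel("B3", "+", b3_exons),
    ]
    return ToyLocus(
        cfg=cfg,
        reference=seq.tobytes().decode(),
        regions=regions,
        genes=genes,
        a6_unit=a6_unit,
        b3_unit=b3_unit,
        a6_tract=a6_tract,
        b3_tract=b3_tract,
        del_start=del_start,
        del_end=del_end,
    )


# -- haplotype construction ---------------------------------------------

Event = Union[str, Tuple[str, int]]


def _normalize_events(events: Sequence[Event]) -> List[Tuple[str, int]]:
    out = []
    for ev in events:
        if isinstance(ev, str):
            out.append((ev, 1))
        else:
            out.append((ev[0], int(ev[1])))
    names = [e[0] for e in out]
    for name, _k in out:
        if name not in ("hybrid_del", "delA6", "dupA6"):
            raise LilrError(f"unknown event {name!r}")
    if len(set(names)) != len(names):
        raise LilrError(f"duplicate events: {names}")
    if "hybrid_del" in names and len(names) > 1:
        raise LilrError("hybrid_del conflicts with A6 events (overlapping edits)")
    if "delA6" in names and "dupA6" in names:
        raise LilrError("delA6 conflicts with dupA6")
    return out


def make_haplotype(locus: ToyLocus, events: Sequence[Event]) -> Haplotype:
    """Apply structural events to the reference and keep the coordinate map."""
    evs = _normalize_events(events)
    ref = locus.reference
    pieces: List[Tuple[int, int]] = []  # (ref_start, ref_end) in haplotype order
    if ("hybrid_del", 1) in evs:
        pieces = [(0, locus.del_start), (locus.del_end, len(ref))]
    elif ("delA6", 1) in evs:
        pieces = [(0, locus.a6_unit.start), (locus.a6_unit.end, len(ref))]
    else:
        dup = next((k for name, k in evs if name == "dupA6"), 0)
        pieces = [(0, locus.a6_unit.end)]
        pieces += [(locus.a6_unit.start, locus.a6_unit.end)] * dup
        pieces.append((locus.a6_unit.end, len(ref)))
    seq_parts, segments, pos = [], [], 0
    for rs, re_ in pieces:
        if re_ > rs:
            seq_parts.append(ref[rs:re_])
            if segments and segments[-1][2] + (segments[-1][1] - segments[-1][0]) == rs:
                hs, he, prev_rs = segments[-1]  # merge colinear neighbors
                segments[-1] = (hs, he + (re_ - rs), prev_rs)
            else:
                segments.append((pos, pos + (re_ - rs), rs))
            pos += re_ - rs
    return Haplotype(sequence="".join(seq_parts), segments=segments, events=tuple(evs))


def events_for(hap: HaplotypeCNType) -> List[Event]:
    """Events realizing a haplotype CN type at sequence level."""
    if hap == HaplotypeCNType(1, 1):
        return []
    if hap == HaplotypeCNType(0, 0):
        return ["hybrid_del"]
    if hap == HaplotypeCNType(1, 0):
        return ["delA6"]
    if hap.h_b3 == 1 and hap.h_a6 >= 2:
        return [("dupA6", hap.h_a6 - 1)]
    raise LilrError(
        f"haplotype {hap.label} is not constructible at sequence level on the toy locus"
    )


# -- short-read depth (bin level) ----------------------------------------

def _multiplicity(locus: ToyLocus, hap: HaplotypeCNType) -> np.ndarray:
    """Per-base copy multiplicity of the reference under one haplotype."""
    m = np.ones(len(locus.reference))
    m[locus.b3_unit.start : locus.b3_unit.end] = hap.h_b3
    m[locus.a6_unit.start : locus.a6_unit.end] = hap.h_a6
    if hap.h_b3 == 0 and hap.h_a6 == 0:  # the hybrid deletion spans beyond the units
        m[locus.del_start : locus.del_end] = 0
    return m


def simulate_depth(
    locus: ToyLocus,
    diplotype: Tuple[HaplotypeCNType, HaplotypeCNType],
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "sample",
    exact: bool = False,
) -> Tuple[DepthProfile, DepthProfile]:
    """Binned read-base counts for one sample, in two MAPQ views.

    Per-base counts are Poisson with mean (depth per copy) x (copies
    covering the base). Bases inside the paralog homology tract are
    ambiguous: their reads appear in the MAPQ-0 view only, split uniformly
    at random between the two paralog positions. `exact=True` replaces
    draws with expectations (the noise-free infinite-depth mode).

    Returns (mapq30 profile, mapq0 profile).
    """
    cfg = locus.cfg
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    per_copy = cfg.mean_depth / 2.0
    lam = per_copy * (_multiplicity(locus, diplotype[0]) + _multiplicity(locus, diplotype[1]))

    n = len(locus.reference)
    counts0 = lam.copy() if exact else rng.poisson(lam).astype(float)
    ta, tb = locus.a6_tract, locus.b3_tract
    lam_pair = lam[ta.start : ta.end] + lam[tb.start : tb.end]
    if exact:
        tot = lam_pair
        a_share = tot / 2.0
    else:
        tot = rng.poisson(lam_pair).astype(float)
        a_share = rng.binomial(tot.astype(int), 0.5).astype(float)
    counts0[ta.start : ta.end] = a_share
    counts0[tb.start : tb.end] = tot - a_share
    counts30 = counts0.copy()
    counts30[ta.start : ta.end] = 0.0
    counts30[tb.start : tb.end] = 0.0

    # bin edges honor region and tract boundaries so restriction stays exact
    breakpoints = {0, ta.start, ta.end, tb.start, tb.end}
    for role in locus.regions.ROLES:
        for iv in locus.regions.by_role(role):
            breakpoints.update((iv.start, iv.end))
    edges = np.array(sorted(set(range(0, n, cfg.bin_size)) | {b for b in breakpoints if b < n}))
    bins = [
        GenomicInterval(CHROM, int(s), int(e))
        for s, e in zip(edges, list(edges[1:]) + [n])
    ]
    per_bin0 = np.add.reduceat(counts0, edges)
    per_bin30 = np.add.reduceat(counts30, edges)
    p30 = DepthProfile(sample_id, cfg.bin_size, list(zip(bins, per_bin30.tolist())), mapq_min=30)
    p0 = DepthProfile(sample_id, cfg.bin_size, list(zip(bins, per_bin0.tolist())), mapq_min=0)
    return p30, p0


# -- long reads ----------------------------------------------------------

def _project(hap: Haplotype, start: int, end: int) -> List[Tuple[int, int, int]]:
    """Map a haplotype interval onto reference pieces (q0, q1, ref_start)."""
    pieces = []
    for hs, he, rs in hap.segments:
        lo, hi = max(start, hs), min(end, he)
        if lo < hi:
            pieces.append((lo - start, hi - start, rs + (lo - hs)))
    return pieces


def _records_for_read(
    read_id: str,
    pieces: List[Tuple[int, int, int]],
    read_len: int,
    rng: np.random.Generator,
    p_dop: float,
    min_anchor: int = 30,
) -> List[AlignmentRecord]:
    pieces = [p for p in pieces if p[1] - p[0] >= min_anchor]
    if not pieces:
        return []
    # group pieces: consecutive pieces with a forward reference gap may stay
    # in one record as a D op; backward jumps (duplication junctions) split
    groups: List[List[Tuple[int, int, int]]] = [[pieces[0]]]
    for prev, cur in zip(pieces, pieces[1:]):
        prev_ref_end = prev[2] + (prev[1] - prev[0])
        gap = cur[2] - prev_ref_end
        if gap > 0 and rng.random() < p_dop:
            groups[-1].append(cur)
        else:
            groups.append([cur])
    records = []
    for gi, group in enumerate(groups):
        cigar = []
        if group[0][0] > 0:
            cigar.append(f"{group[0][0]}S")
        ref_pos = group[0][2]
        cursor = group[0][2]
        for j, (q0, q1, rs) in enumerate(group):
            if j > 0:
                cigar.append(f"{rs - cursor}D")
            cigar.append(f"{q1 - q0}M")
            cursor = rs + (q1 - q0)
        if read_len - group[-1][1] > 0:
            cigar.append(f"{read_len - group[-1][1]}S")
        records.append(
            AlignmentRecord(
                read_id=read_id,
                chrom=CHROM,
                pos=ref_pos,
                mapq=60,
                cigar="".join(cigar),
                is_supplementary=gi > 0,
                strand="+",
            )
        )
    return records


def simulate_long_reads(
    locus: ToyLocus,
    diplotype: Tuple[HaplotypeCNType, HaplotypeCNType],
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "sample",
    depth: Optional[float] = None,
) -> Tuple[List[AlignmentRecord], Dict[str, str]]:
    """HiFi-like reads as alignments (plus read sequences).

    Read starts are uniform on each haplotype; a read crossing a planted
    deletion is reported either as one record with a D operation
    (probability `p_dop`) or as a primary + supplementary split pair.
    Substitution errors (``error_rate``) do not perturb the alignments.
    """
    cfg = locus.cfg
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    depth = cfg.mean_depth if depth is None else depth
    records: List[AlignmentRecord] = []
    reads: Dict[str, str] = {}
    for hi, hap_type in enumerate(diplotype):
        hap = make_haplotype(locus, events_for(hap_type))
        n_reads = max(1, int(round((depth / 2.0) * len(hap) / cfg.read_length_mean)))
        for ri in range(n_reads):
            L = int(np.clip(rng.normal(cfg.read_length_mean, cfg.read_length_sd), 500, len(hap)))
            start = int(rng.integers(0, len(hap) - L + 1))
            read_id = f"{sample_id}_h{hi}_r{ri}"
            seq = hap.sequence[start : start + L]
            if cfg.error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                hits = np.flatnonzero(rng.random(L) < cfg.error_rate)
                for p in hits:
                    arr[p] = rng.choice(
                        [b for b in (b"A", b"C", b"G", b"T") if b != bytes(arr[p])]
                    )
                seq = arr.tobytes().decode()
            reads[read_id] = seq
            records.extend(
                _records_for_read(read_id, _project(hap, start, start + L), L, rng, cfg.p_dop)
            )
    records.sort(key=lambda r: (r.pos, r.read_id))
    return records, reads


# -- cohorts -------------------------------------------------------------

def draw_diplotypes(
    freqs: Dict[HaplotypeCNType, float], n: int, rng: np.random.Generator
) -> List[Tuple[HaplotypeCNType, HaplotypeCNType]]:
    """n diplotypes drawn under Hardy-Weinberg (two independent haplotypes)."""
    haps = sorted(freqs)
    p = np.array([freqs[h] for h in haps], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(haps), size=(n, 2), p=p)
    return [(haps[i], haps[j]) for i, j in idx]


def simulate_cohort(
    locus: ToyLocus,
    freqs: Dict[HaplotypeCNType, float],
    n: int,
    rng: Optional[np.random.Generator] = None,
    exact: bool = False,
):
    """Cohort of samples with truth records and a normalized-CN table.

    Returns (truth list, pandas DataFrame with the depth-module TSV columns).
    """
    import pandas as pd

    cfg = locus.cfg
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    diplos = draw_diplotypes(freqs, n, rng)
    truths, rows = [], []
    for i, (h1, h2) in enumerate(diplos):
        sid = f"S{i:04d}"
        p30, p0 = simulate_depth(locus, (h1, h2), rng, sample_id=sid, exact=exact)
        ncn, point, qc = sample_cn(p30, p0, locus.regions)
        dels = [
            [GenomicInterval(CHROM, locus.del_start, locus.del_end)] if h == HaplotypeCNType(0, 0) else []
            for h in (h1, h2)
        ]
        truths.append(TruthRecord(sid, h1, h2, dels))
        rows.append(
            {
                "sample_id": sid,
                "cn_b3core": ncn.cn_b3core,
                "cn_a6core": ncn.cn_a6core,
                "cn_sum": ncn.cn_sum,
                "x": point.x,
                "y": point.y,
                "cnv2_ratio": qc.cnv2_ratio,
            }
        )
    return truths, pd.DataFrame(rows)
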