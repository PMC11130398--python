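"""Interpreting a deletion against gene models: hybrid-gene construction,
fused transcripts, NAGNAG acceptor isoforms, ITIM scanning, in-silico PCR,
and identity-tract search.

A deletion whose breakpoints fall in introns of two same-strand genes fuses
the upstream gene's 5' exons to the downstream gene's 3' exons. For the
LILR locus, the 33,692 bp deletion joins LILRB5 intron 12 to LILRB3 intron
11, yielding a receptor with the LILRB5 extracellular/transmembrane portion
and the distal LILRB3 cytoplasmic tail -- inhibitory ITIMs grafted onto a
receptor that natively signals differently.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from Bio.Seq import Seq

from .errors import LilrError
from .regions import GenomicInterval
from .sv import DeletionCall

__all__ = [
    "GeneModel",
    "GeneEffect",
    "HybridGeneModel",
    "TranscriptIsoform",
    "ITIMHit",
    "PrimerPair",
    "IdentityTract",
    "intersect_genes",
    "build_hybrid",
    "splice_transcript",
    "splice_gene",
    "find_tandem_acceptors",
    "scan_itims",
    "insilico_pcr",
    "longest_identity_tract",
    "translate_cdna",
]

ITIM_CONSENSUS = re.compile(r"(?=([SIVL].Y..[IVL]))")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY*")


@dataclass
class GeneModel:
    """A gene as an ordered exon list (transcription order) plus strand.

    `exons` are genomic intervals; for minus-strand genes exon 1 is the
    rightmost interval. `cds_start_offset` is the offset of the CDS start
    within the spliced transcript.
    """

    name: str
    strand: str
    exons: List[GenomicInterval]
    cds_start_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise LilrError(f"gene {self.name}: bad strand {self.strand!r}")
        if not self.exons:
            raise LilrError(f"gene {self.name}: no exons")
        genomic = sorted(self.exons)
        for a, b in zip(genomic, genomic[1:]):
            if a.overlaps(b):
                raise LilrError(f"gene {self.name}: overlapping exons {a}, {b}")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if self.exons != expected:
            raise LilrError(f"gene {self.name}: exons not in transcription order")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    def introns(self) -> List[GenomicInterval]:
        """Introns in transcription order (index i between exons i+1, i+2)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            lo, hi = (a.end, b.start) if self.strand == "+" else (b.end, a.start)
            out.append(GenomicInterval(self.chrom, lo, hi))
        return out


@dataclass
class GeneEffect:
    gene: str
    exons_deleted: List[int]    # 1-based exon numbers fully inside the deletion
    exons_truncated: List[int]  # partially overlapped
    fully_deleted: bool


@dataclass
class HybridGeneModel:
    five_prime_gene: str
    three_prime_gene: str
    retained_5p_exons: List[int]  # 1-based, transcription order
    retained_3p_exons: List[int]
    junction: Tuple[GenomicInterval, GenomicInterval]
    fused_name: str


@dataclass
class TranscriptIsoform:
    name: str
    cdna: str
    acceptor_shifts: Dict[int, int] = field(default_factory=dict)


@dataclass(frozen=True)
class ITIMHit:
    protein_position: int  # 1-based position of the hexamer start
    matched_hexamer: str


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if len(p) < 15:
                raise LilrError(f"primer {p!r} shorter than 15 nt")


@dataclass(frozen=True)
class IdentityTract:
    length: int
    pos_a: int
    pos_b: int


def intersect_genes(call: DeletionCall, models: Sequence[GeneModel]) -> List[GeneEffect]:
    """Per-gene exon loss report for a deletion call."""
    out = []
    dele = call.interval
    for gene in models:
        deleted, truncated = [], []
        for i, exon in enumerate(gene.exons, start=1):
            if dele.contains(exon):
                deleted.append(i)
            elif dele.overlaps(exon):
                truncated.append(i)
        if deleted or truncated:
            out.append(
                GeneEffect(
                    gene=gene.name,
                    exons_deleted=deleted,
                    exons_truncated=truncated,
                    fully_deleted=len(deleted) == len(gene.exons),
                )
            )
    return out


def _intron_index(gene: GeneModel, pos: int) -> Optional[int]:
    """0-based transcription-order intron index containing `pos`, else None."""
    for i, intron in enumerate(gene.introns()):
        if intron.start <= pos < intron.end:
            return i
    return None


def build_hybrid(
    call: DeletionCall, models: Sequence[GeneModel]
) -> Optional[HybridGeneModel]:
    """Fused gene model when both deletion breakpoints are intronic.

    Returns None (with a warning for the exonic case) when the deletion does
    not create a hybrid: breakpoints in the same gene, different strands, or
    inside an exon (truncating, not hybrid-forming).
    """
    import warnings

    s, e = call.interval.start, call.interval.end
    chrom_models = [g for g in models if g.chrom == call.interval.chrom]
    left_gene = next((g for g in chrom_models if g.start < s < g.end), None)
    right_gene = next((g for g in chrom_models if g.start < e < g.end), None)
    if left_gene is None or right_gene is None or left_gene.name == right_gene.name:
        return None
    if left_gene.strand != right_gene.strand:
        return None
    for gene, pos in ((left_gene, s), (right_gene, e - 1)):
        for i, exon in enumerate(gene.exons, start=1):
            if exon.start <= pos < exon.end:
                warnings.warn(
                    f"breakpoint inside {gene.name} exon {i}: truncating, not hybrid-forming"
                )
                return None

    if left_gene.strand == "+":
        five, five_bp = left_gene, s
        three, three_bp = right_gene, e - 1
    else:
        five, five_bp = right_gene, e - 1
        three, three_bp = left_gene, s
    i5 = _intron_index(five, five_bp)
    i3 = _intron_index(three, three_bp)
    if i5 is None or i3 is None:
        return None

    retained_5p = list(range(1, i5 + 2))             # exons upstream of the breakpoint intron
    retained_3p = list(range(i3 + 2, len(three.exons) + 1))
    suffix = three.name[-1] if three.name[:-1] and three.name[-1].isdigit() else three.name
    return HybridGeneModel(
        five_prime_gene=five.name,
        three_prime_gene=three.name,
        retained_5p_exons=retained_5p,
        retained_3p_exons=retained_3p,
        junction=(five.introns()[i5], three.introns()[i3]),
        fused_name=f"{five.name}-{suffix}",
    )


def _exon_seq(genome: Dict[str, str], chrom: str, exon: GenomicInterval, strand: str, shift: int) -> str:
    if chrom not in genome or exon.end > len(genome[chrom]):
        raise LilrError(f"exon {exon} outside the supplied genome")
    s, e = exon.start, exon.end
    if strand == "+":
        s += shift
    else:
        e -= shift
    seq = genome[chrom][s:e]
    return seq if strand == "+" else str(Seq(seq).reverse_complement())


def splice_transcript(
    hybrid: HybridGeneModel,
    models: Sequence[GeneModel],
    genome: Dict[str, str],
    shifts: Optional[Dict[int, int]] = None,
    name: Optional[str] = None,
) -> TranscriptIsoform:
    """Spliced cDNA of the fused gene.

    Exons are concatenated in transcription order (5'-gene retained exons,
    then 3'-gene retained exons), reverse-complemented for minus-strand
    genes. `shifts` maps the *fused* 1-based exon index to 0 or +3; a +3
    exon starts 3 nt downstream (NAGNAG distal acceptor).
    """
    shifts = shifts or {}
    by_name = {g.name: g for g in models}
    five = by_name[hybrid.five_prime_gene]
    three = by_name[hybrid.three_prime_gene]
    parts = []
    fused_index = 0
    for gene, retained in ((five, hybrid.retained_5p_exons), (three, hybrid.retained_3p_exons)):
        for exon_no in retained:
            fused_index += 1
            shift = shifts.get(fused_index, 0)
            if shift not in (0, 3):
                raise LilrError(f"acceptor shift must be 0 or +3, got {shift}")
            parts.append(
                _exon_seq(genome, gene.chrom, gene.exons[exon_no - 1], gene.strand, shift)
            )
    return TranscriptIsoform(
        name=name or hybrid.fused_name,
        cdna="".join(parts),
        acceptor_shifts={i: s for i, s in shifts.items() if s},
    )


def splice_gene(
    gene: GeneModel,
    genome: Dict[str, str],
    shifts: Optional[Dict[int, int]] = None,
    exons: Optional[Sequence[int]] = None,
    name: Optional[str] = None,
) -> TranscriptIsoform:
    """Spliced cDNA of a single (non-fused) gene; same shift semantics."""
    shifts = shifts or {}
    use = list(exons) if exons is not None else list(range(1, len(gene.exons) + 1))
    parts = []
    for exon_no in use:
        shift = shifts.get(exon_no, 0)
        if shift not in (0, 3):
            raise LilrError(f"acceptor shift must be 0 or +3, got {shift}")
        parts.append(_exon_seq(genome, gene.chrom, gene.exons[exon_no - 1], gene.strand, shift))
    return TranscriptIsoform(
        name=name or gene.name,
        cdna="".join(parts),
        acceptor_shifts={i: s for i, s in shifts.items() if s},
    )


def find_tandem_acceptors(
    genome: Dict[str, str], gene: GeneModel, exon_no: int
) -> Set[int]:
    """Allowed acceptor shifts {0} or {0, 3} for a gene's exon.

    A NAGNAG (tandem) acceptor exists when, on the coding strand, the
    annotated acceptor is preceded by AG (canonical intron end) and a second
    AG sits at exon offsets 1-2, so a legal acceptor also exists 3 nt
    downstream: intron...AG | n A G rest-of-exon.
    """
    if exon_no < 1 or exon_no > len(gene.exons):
        raise LilrError(f"gene {gene.name} has no exon {exon_no}")
    if exon_no == 1:
        return {0}  # no acceptor upstream of the first exon
    exon = gene.exons[exon_no - 1]
    seq = genome[gene.chrom]
    if gene.strand == "+":
        if exon.start < 6:
            return {0}
        upstream = seq[exon.start - 2 : exon.start]
        internal = seq[exon.start + 1 : exon.start + 3]
    else:
        upstream = str(Seq(seq[exon.end : exon.end + 2]).reverse_complement())
        internal = str(Seq(seq[exon.end - 3 : exon.end - 1]).reverse_complement())
    return {0, 3} if upstream == "AG" and internal == "AG" else {0}


def scan_itims(protein: str) -> List[ITIMHit]:
    """All ITIM consensus hits [S/I/V/L]-x-Y-x-x-[I/V/L], overlapping allowed.

    The consensus is the standard immunoreceptor tyrosine-based inhibitory
    motif definition; positions are 1-based, ordered.
    """
    bad = set(protein) - AA_ALPHABET
    if bad:
        raise LilrError(f"non-amino-acid characters in protein: {sorted(bad)}")
    return [
        ITIMHit(protein_position=m.start() + 1, matched_hexamer=m.group(1))
        for m in ITIM_CONSENSUS.finditer(protein)
    ]


def translate_cdna(iso: TranscriptIsoform, cds_start_offset: int = 0) -> str:
    """Translate a transcript from its CDS start, trimming the 3' remainder."""
    cds = iso.cdna[cds_start_offset:]
    cds = cds[: len(cds) - len(cds) % 3]
    return str(Seq(cds).translate())


def _primer_sites(template: str, primer: str, core: int = 15) -> List[Tuple[int, int]]:
    """(start, end) template matches of `primer`, anchored on its 3' core.

    The 3'-most `core` nt must match exactly; the match is then extended
    5'-ward as far as the primer and template agree, and the full extension
    (the primer minus any unmatched 5' tail, e.g. a restriction-site tag)
    must be contiguous identity.
    """
    anchor = primer[-core:].upper()
    t = template.upper()
    p = primer.upper()
    sites = []
    start = 0
    while True:
        i = t.find(anchor, start)
        if i < 0:
            break
        # extend 5'-ward
        k = 0
        while (
            k < len(p) - core
            and i - k - 1 >= 0
            and t[i - k - 1] == p[len(p) - core - k - 1]
        ):
            k += 1
        sites.append((i - k, i + core))
        start = i + 1
    return sites


def insilico_pcr(template: str, primers: PrimerPair, max_product: Optional[int] = None) -> List[Tuple[int, str]]:
    """Predicted PCR products: (length, sequence) for every forward site
    paired with every downstream reverse-complemented reverse site.

    Matching is exact over the primer cores (validation-grade stringency);
    5' tails that do not match the template (cloning tags) are ignored by
    the 3'-anchored matching. The product runs from the forward primer's
    5'-most matched base to the reverse primer's 5'-most matched base.
    """
    rc = str(Seq(primers.reverse).reverse_complement())
    fwd_sites = _primer_sites(template, primers.forward)
    # reverse primer binds the minus strand; on the plus strand its site is
    # revcomp(reverse), whose *end* corresponds to the primer's 5' end, and
    # the 3' core sits at the site start
    rev_sites = _rc_sites(template, rc, len(primers.reverse))
    products = []
    for fs, _fe in fwd_sites:
        for rs, re_ in rev_sites:
            if re_ <= fs:
                continue
            if rs < fs:
                continue
            seq = template[fs:re_]
            if max_product and len(seq) > max_product:
                continue
            products.append((len(seq), seq))
    products.sort(key=lambda p: p[0])
    return products


def _rc_sites(template: str, rc_primer: str, primer_len: int, core: int = 15) -> List[Tuple[int, int]]:
    """Plus-strand sites of the reverse primer (given as its revcomp).

    The primer's 3' core maps to the *start* of the plus-strand site; any
    unmatched 5' tail would extend past the site end, so extension runs
    3'-ward on the plus strand.
    """
    anchor = rc_primer[:core].upper()
    t = template.upper()
    p = rc_primer.upper()
    sites = []
    start = 0
    while True:
        i = t.find(anchor, start)
        if i < 0:
            break
        k = 0
        while core + k < len(p) and i + core + k < len(t) and t[i + core + k] == p[core + k]:
            k += 1
        sites.append((i, i + core + k))
        start = i + 1
    return sites


def longest_identity_tract(seq_a: str, seq_b: str) -> IdentityTract:
    """Longest common substring of two sequences (leftmost-in-a tie-break).

    The quantity of interest for NAHR: the longest perfectly identical
    tract shared by two introns bounds where the recombination junction can
    lie.
    """
    if not seq_a or not seq_b:
        raise LilrError("longest_identity_tract needs two non-empty sequences")
    sm = difflib.SequenceMatcher(a=seq_a, b=seq_b, autojunk=False)
    m = sm.find_longest_match(0, len(seq_a), 0, len(seq_b))
    return IdentityTract(length=m.size, pos_a=m.a, pos_b=m.b)
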