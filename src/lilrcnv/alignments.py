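"""Alignment records and CIGAR arithmetic shared by depth and SV calling.

Alignments are consumed, never produced: either standard SAM/BAM (read with
pysam) or the simulator's plain-text TSV dialect with columns
``read_id, chrom, pos, mapq, cigar, flags`` (SAM flag semantics: 0x10
reverse strand, 0x800 supplementary).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Optional, Tuple

from .errors import LilrError

__all__ = [
    "AlignmentRecord",
    "parse_cigar",
    "cigar_to_string",
    "read_alignments",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_OPS = frozenset("MDN=X")
_QUERY_OPS = frozenset("MIS=X")

FLAG_REVERSE = 0x10
FLAG_SUPPLEMENTARY = 0x800


def parse_cigar(cigar: str, read_id: str = "?") -> List[Tuple[str, int]]:
    """Parse a CIGAR string into (op, length) tuples, validating syntax."""
    if not cigar or cigar == "*":
        raise LilrError(f"read {read_id}: missing CIGAR")
    ops = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise LilrError(f"read {read_id}: malformed CIGAR {cigar!r}")
        n = int(m.group(1))
        if n <= 0:
            raise LilrError(f"read {read_id}: zero-length CIGAR op in {cigar!r}")
        ops.append((m.group(2), n))
        pos = m.end()
    if pos != len(cigar) or not ops:
        raise LilrError(f"read {read_id}: malformed CIGAR {cigar!r}")
    return ops


def cigar_to_string(ops: List[Tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


@dataclass
class AlignmentRecord:
    read_id: str
    chrom: str
    pos: int  # 0-based reference start
    mapq: int
    cigar: str
    is_supplementary: bool = False
    strand: str = "+"

    def __post_init__(self) -> None:
        self._ops = parse_cigar(self.cigar, self.read_id)
        if self.pos < 0:
            raise LilrError(f"read {self.read_id}: negative position")

    @property
    def ops(self) -> List[Tuple[str, int]]:
        return self._ops

    @property
    def reference_end(self) -> int:
        return self.pos + sum(n for op, n in self._ops if op in _REF_OPS)

    @property
    def query_start(self) -> int:
        """Read offset of the first aligned base (leading soft clip)."""
        qs = 0
        for op, n in self._ops:
            if op in ("S", "H"):
                qs += n
            else:
                break
        return qs

    @property
    def query_end(self) -> int:
        """Read offset one past the last aligned base."""
        return self.query_start + sum(n for op, n in self._ops if op in ("M", "I", "=", "X"))

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self._ops if op in ("S", "H", "M", "I", "=", "X"))

    def reference_blocks(self) -> List[Tuple[int, int]]:
        """Aligned (start, end) reference blocks (M/=/X runs), merged across I."""
        blocks: List[Tuple[int, int]] = []
        ref = self.pos
        for op, n in self._ops:
            if op in ("M", "=", "X"):
                if blocks and blocks[-1][1] == ref:
                    blocks[-1] = (blocks[-1][0], ref + n)
                else:
                    blocks.append((ref, ref + n))
                ref += n
            elif op in ("D", "N"):
                ref += n
        return blocks


def _iter_sam(path: Path) -> Iterator[AlignmentRecord]:
    import pysam

    mode = "rb" if path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.cigarstring is None:
                continue
            yield AlignmentRecord(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                pos=rec.reference_start,
                mapq=rec.mapping_quality,
                cigar=rec.cigarstring,
                is_supplementary=rec.is_supplementary,
                strand="-" if rec.is_reverse else "+",
            )


def _iter_tsv(path: Path) -> Iterator[AlignmentRecord]:
    expected = ["read_id", "chrom", "pos", "mapq", "cigar", "flags"]
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(expected)] != expected:
            raise LilrError(
                f"{path}: alignment TSV must start with columns {expected}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise LilrError(f"{path}:{lineno}: expected >= 6 columns")
            try:
                pos, mapq, flags = int(fields[2]), int(fields[3]), int(fields[5])
            except ValueError as exc:
                raise LilrError(f"{path}:{lineno}: {exc}") from exc
            yield AlignmentRecord(
                read_id=fields[0],
                chrom=fields[1],
                pos=pos,
                mapq=mapq,
                cigar=fields[4],
                is_supplementary=bool(flags & FLAG_SUPPLEMENTARY),
                strand="-" if flags & FLAG_REVERSE else "+",
            )


def read_alignments(path) -> List[AlignmentRecord]:
    """Load alignments from SAM/BAM or the simulator's TSV dialect."""
    path = Path(path)
    if path.suffix in (".sam", ".bam", ".cram"):
        return list(_iter_sam(path))
    return list(_iter_tsv(path))


def write_alignment_tsv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tpos\tmapq\tcigar\tflags\n")
        for r in records:
            flags = (FLAG_SUPPLEMENTARY if r.is_supplementary else 0) | (
                FLAG_REVERSE if r.strand == "-" else 0
            )
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.pos}\t{r.mapq}\t{r.cigar}\t{flags}\n")
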