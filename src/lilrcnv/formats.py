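"""Readers and writers for the text formats the toolkit touches.

BED (region registry with a role column), GFF3 (gene models), FASTA
(reference / transcripts, via Biopython), and the tab-separated CN table.
Internal coordinates are 0-based half-open; GFF3's 1-based inclusive
coordinates are converted on read and write. All writers emit
newline-terminated, tab-separated, header-carrying files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import LilrError
from .hybrid import GeneModel
from .regions import GenomicInterval, RegionSet

__all__ = [
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "read_fasta",
    "write_fasta",
    "read_cn_table",
    "write_cn_table",
]

CN_COLUMNS = ["sample_id", "cn_b3core", "cn_a6core", "cn_sum", "x", "y", "cnv2_ratio"]


def read_bed(path: Union[str, Path], unit_length: int = None) -> RegionSet:
    """Region registry from BED4 (4th column = role core_b3|core_a6|body|control).

    The writer stores the paralog unit length in a ``#unit_length=`` header
    comment; an explicit `unit_length` argument overrides it.
    """
    rs = RegionSet(unit_length=unit_length or 8000)
    header_unit = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#unit_length="):
                    header_unit = int(line.split("=", 1)[1])
                continue
            if line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise LilrError(f"{path}:{lineno}: BED needs 4 columns (chrom start end role)")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise LilrError(f"{path}:{lineno}: {exc}") from exc
            role = fields[3]
            if role not in RegionSet.ROLES:
                raise LilrError(
                    f"{path}:{lineno}: unknown role {role!r}; expected one of {RegionSet.ROLES}"
                )
            rs.by_role(role).append(iv)
    if unit_length is None and header_unit is not None:
        rs.unit_length = header_unit
    rs.validate()
    return rs


def write_bed(regions: RegionSet, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(f"#unit_length={regions.unit_length}\n")
        fh.write("#chrom\tstart\tend\trole\n")
        for role in RegionSet.ROLES:
            for iv in regions.by_role(role):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{role}\n")


def _gff_attrs(field: str) -> Dict[str, str]:
    out = {}
    for part in field.split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: Union[str, Path]) -> List[GeneModel]:
    """Gene models from GFF3 (gene/mRNA/exon features).

    Exons are attached to their mRNA via ``Parent`` and ordered by
    transcription (reversed for minus-strand genes); 1-based inclusive
    coordinates become 0-based half-open. One transcript per gene is
    assumed (the first mRNA wins).
    """
    mrnas: Dict[str, dict] = {}
    gene_names: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise LilrError(f"{path}:{lineno}: GFF3 needs 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            attrs = _gff_attrs(attrs)
            if ftype == "gene":
                gene_names[attrs.get("ID", "")] = attrs.get("Name", attrs.get("ID", "gene"))
            elif ftype == "mRNA":
                mid = attrs.get("ID")
                if mid is None:
                    raise LilrError(f"{path}:{lineno}: mRNA without ID")
                mrnas[mid] = {
                    "gene": attrs.get("Parent", mid),
                    "strand": strand,
                    "chrom": chrom,
                    "cds_start_offset": int(attrs.get("cds_start_offset", 0)),
                    "exons": [],
                }
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent in mrnas:
                    try:
                        iv = GenomicInterval(chrom, int(start) - 1, int(end))
                    except ValueError as exc:
                        raise LilrError(f"{path}:{lineno}: {exc}") from exc
                    mrnas[parent]["exons"].append(iv)
    if not mrnas:
        raise LilrError(f"{path}: no mRNA features found")
    genes, seen = [], set()
    for info in mrnas.values():
        name = gene_names.get(info["gene"], info["gene"])
        if name in seen:
            continue
        seen.add(name)
        exons = sorted(info["exons"])
        if info["strand"] == "-":
            exons = exons[::-1]
        genes.append(
            GeneModel(name, info["strand"], exons, cds_start_offset=info["cds_start_offset"])
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID=gene-{g.name};Name={g.name}"
            fh.write(
                f"{g.chrom}\tlilrcnv\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mattrs = f"ID=mrna-{g.name};Parent=gene-{g.name};cds_start_offset={g.cds_start_offset}"
            fh.write(
                f"{g.chrom}\tlilrcnv\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{mattrs}\n"
            )
            for i, exon in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tlilrcnv\texon\t{exon.start + 1}\t{exon.end}\t.\t{g.strand}\t.\t"
                    f"ID=exon-{g.name}-{i};Parent=mrna-{g.name}\n"
                )


def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Dict[str, str], path: Union[str, Path]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_cn_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("cn_b3core", "cn_a6core", "cn_sum") if c not in df.columns]
    if missing:
        raise LilrError(f"{path}: CN table missing columns {missing}")
    return df


def write_cn_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False)
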