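"""Readers/writers for the standard formats the pipeline touches.

All coordinates are internally 0-based half-open; GFF3's 1-based inclusive
coordinates are converted on read and restored on write. Sequences are
uppercased, U is mapped to T, and IUPAC ambiguity codes other than N are
mapped to N (with a warning) so that downstream alignment scoring can treat
N uniformly as a mismatch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "GeneFeature",
    "Interval",
    "HitRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff_genes",
    "write_gff_genes",
    "read_hits_table",
    "read_bed",
    "write_bed",
]

_VALID = set("ACGTN")
_AMBIG = set("RYSWKMBDHV")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Interval:
    seq_id: str
    start: int
    end: int
    strand: Optional[str] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.seq_id}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end


@dataclass
class GeneFeature:
    gene_id: str
    seq_id: str
    strand: str
    translation_start: int  # 0-based coordinate of the first CDS base (5'-most)
    gene_span: tuple[int, int]  # half-open

    def __post_init__(self) -> None:
        s, e = self.gene_span
        if not (0 <= s < e):
            raise ValueError(f"invalid gene span [{s}, {e}) for {self.gene_id}")
        if not (s <= self.translation_start < e):
            raise ValueError(
                f"translation start {self.translation_start} outside span of {self.gene_id}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class HitRecord:
    query_id: str
    subject_id: str
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e-value must be >= 0")


def _clean_sequence(seq: str, record_id: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        amb = bad & _AMBIG
        if bad - _AMBIG:
            raise FormatError(
                f"record {record_id}: illegal characters {sorted(bad - _AMBIG)}"
            )
        warnings.warn(
            f"record {record_id}: ambiguity codes {sorted(amb)} mapped to N",
            stacklevel=3,
        )
        seq = "".join("N" if c in _AMBIG else c for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercased, U->T, ambiguity->N)."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.read(1)
        if first == "":
            raise FormatError(f"{path}: empty file")
        if first != ">":
            raise FormatError(f"{path}: line 1: expected '>' header")
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty id")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                rec.id,
                _clean_sequence(str(rec.seq), rec.id),
                rec.description[len(rec.id):].strip() if rec.description else "",
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
            if not rec.sequence:
                fh.write("\n")


_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _attr_value(attributes: str, *keys: str) -> Optional[str]:
    for part in attributes.rstrip(";").split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        k, v = part.split("=", 1)
        if k in keys:
            return v
    return None


def read_gff_genes(path: str | Path) -> list[GeneFeature]:
    """Read gene + CDS features from a GFF3 file.

    The translation start is the 5'-most CDS base in gene orientation
    (min CDS start on +, max CDS end - 1 on -), pooled across transcripts.
    Genes without any CDS are skipped with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=_GFF_COLS,
            dtype={"start": int, "end": int},
        )
    except ValueError as exc:
        raise FormatError(f"{path}: malformed GFF ({exc})") from exc
    if (df["end"] < df["start"]).any():
        bad = df.index[(df["end"] < df["start"])][0]
        raise FormatError(f"{path}: feature end < start at data row {bad + 1}")

    genes: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        if row.type != "gene":
            continue
        gid = _attr_value(row.attributes, "ID", "gene_id")
        if gid is None:
            raise FormatError(f"{path}: gene feature without ID attribute")
        genes[gid] = {
            "seq_id": row.seqid,
            "strand": row.strand,
            # GFF 1-based inclusive -> 0-based half-open
            "span": (row.start - 1, row.end),
            "cds": [],
        }
    for row in df.itertuples(index=False):
        if row.type != "CDS":
            continue
        gid = _attr_value(row.attributes, "gene_id", "Parent", "ID")
        if gid is None:
            continue
        # allow CDS Parent to be a transcript named <gene>.t<N>
        base = gid.split(".t")[0]
        target = gid if gid in genes else base
        if target in genes:
            genes[target]["cds"].append((row.start - 1, row.end))

    out: list[GeneFeature] = []
    for gid, info in genes.items():
        if not info["cds"]:
            warnings.warn(f"{path}: gene {gid} has no CDS; skipped", stacklevel=2)
            continue
        if info["strand"] == "+":
            tls = min(s for s, _ in info["cds"])
        else:
            tls = max(e for _, e in info["cds"]) - 1
        out.append(GeneFeature(gid, info["seq_id"], info["strand"], tls, info["span"]))
    return out


def write_gff_genes(genes: Iterable[GeneFeature], path: str | Path) -> None:
    """Write genes and a single full-span CDS per gene (synthetic cohorts)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.gene_span
            fh.write(
                f"{g.seq_id}\tcnescan\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            if g.strand == "+":
                cs, ce = g.translation_start, e
            else:
                cs, ce = s, g.translation_start + 1
            fh.write(
                f"{g.seq_id}\tcnescan\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id};gene_id={g.gene_id}\n"
            )


def read_hits_table(path: str | Path) -> list[HitRecord]:
    """Read a BLAST tabular (outfmt 6) file: query, subject, ..., e-value, bit score."""
    path = Path(path)
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}: line {lineno}: expected >=12 columns")
            try:
                e_value = float(cols[10])
                bit_score = float(cols[11])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric e-value or bit score"
                ) from exc
            hits.append(HitRecord(cols[0], cols[1], bit_score, e_value))
    return hits


def read_bed(path: str | Path) -> list[Interval]:
    path = Path(path)
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 columns")
            start, end = int(cols[1]), int(cols[2])
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start >= end")
            name = cols[3] if len(cols) > 3 else None
            strand = cols[5] if len(cols) > 5 else None
            out.append(Interval(cols[0], start, end, strand=strand, name=name))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.seq_id, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.strand is not None:
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
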