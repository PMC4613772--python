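"""Extraction of the <=2 kb non-coding region upstream of the translation start.

The region is anchored at (and excludes) the translation start, read 5'->3'
in gene orientation; minus-strand regions are reverse-complemented. If the
candidate region overlaps another gene it is truncated to keep the
translation-start-proximal part; if the whole anchored run is blocked by
another gene (the candidate lies inside it, or the other gene covers the base
immediately upstream of the translation start) the gene is removed from the
analysis. "Nearby gene" means any other gene's span on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io_formats import GeneFeature, Interval, SequenceRecord, reverse_complement

__all__ = ["UpstreamRegion", "RemovalVerdict", "extract_upstream", "extract_cohort_regions"]


@dataclass
class UpstreamRegion:
    gene_id: str
    species: str
    sequence: str  # 5'->3' in gene orientation
    genomic_interval: Interval
    truncated: bool = False
    repeat_mask: list[tuple[int, int]] = field(default_factory=list)  # region coords

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.genomic_interval):
            raise ValueError("sequence length does not match genomic interval")

    @property
    def span_used(self) -> int:
        return len(self.sequence)

    def to_genomic(self, start: int, end: int) -> Interval:
        """Lift a region-coordinate interval back to genomic coordinates."""
        gi = self.genomic_interval
        if self.genomic_interval.strand == "-":
            return Interval(gi.seq_id, gi.end - end, gi.end - start, strand="-")
        return Interval(gi.seq_id, gi.start + start, gi.start + end, strand="+")


@dataclass(frozen=True)
class RemovalVerdict:
    gene_id: str
    reason: str  # "contained" | "empty"


def extract_upstream(
    gene: GeneFeature,
    genome: SequenceRecord,
    all_genes: Sequence[GeneFeature],
    span: int = 2000,
    repeats: Optional[Iterable[Interval]] = None,
    species: str = "",
) -> UpstreamRegion | RemovalVerdict:
    """Extract the upstream region of one gene, or return a removal verdict."""
    if span <= 0:
        raise ValueError("span must be positive")
    if gene.seq_id != genome.id:
        raise ValueError(f"gene {gene.gene_id} not on contig {genome.id}")
    contig_len = len(genome.sequence)
    tls = gene.translation_start

    if gene.strand == "+":
        cand_start, cand_end = max(0, tls - span), tls
    else:
        cand_start, cand_end = tls + 1, min(contig_len, tls + 1 + span)
    if cand_start >= cand_end:
        return RemovalVerdict(gene.gene_id, "empty")

    # truncate at other-gene boundaries, keeping the 3' (TLS-proximal) part
    blocked = False
    for other in all_genes:
        if other.gene_id == gene.gene_id or other.seq_id != gene.seq_id:
            continue
        os, oe = other.gene_span
        if oe <= cand_start or os >= cand_end:
            continue
        if gene.strand == "+":
            if oe >= cand_end:  # covers the base adjacent to the TLS
                return RemovalVerdict(gene.gene_id, "contained")
            cand_start = max(cand_start, oe)
            blocked = True
        else:
            if os <= cand_start:
                return RemovalVerdict(gene.gene_id, "contained")
            cand_end = min(cand_end, os)
            blocked = True
    if cand_start >= cand_end:
        return RemovalVerdict(gene.gene_id, "contained" if blocked else "empty")

    raw = genome.sequence[cand_start:cand_end]
    if gene.strand == "-":
        seq = reverse_complement(raw)
    else:
        seq = raw
    region = UpstreamRegion(
        gene_id=gene.gene_id,
        species=species,
        sequence=seq,
        genomic_interval=Interval(gene.seq_id, cand_start, cand_end, strand=gene.strand),
        truncated=blocked or (cand_end - cand_start) < span,
    )
    if repeats is not None:
        mask: list[tuple[int, int]] = []
        n = len(seq)
        for iv in repeats:
            if iv.seq_id != gene.seq_id or iv.end <= cand_start or iv.start >= cand_end:
                continue
            s = max(iv.start, cand_start) - cand_start
            e = min(iv.end, cand_end) - cand_start
            if gene.strand == "-":
                s, e = n - e, n - s
            mask.append((s, e))
        region.repeat_mask = sorted(mask)
    return region


def extract_cohort_regions(
    genes: Sequence[GeneFeature],
    genome_records: Sequence[SequenceRecord],
    span: int = 2000,
    repeats: Optional[Sequence[Interval]] = None,
    species: str = "",
) -> tuple[dict[str, UpstreamRegion], list[RemovalVerdict]]:
    """Extract regions for all genes of one species; returns (regions, removals)."""
    by_contig = {rec.id: rec for rec in genome_records}
    regions: dict[str, UpstreamRegion] = {}
    removed: list[RemovalVerdict] = []
    for gene in genes:
        if gene.seq_id not in by_contig:
            raise KeyError(f"contig {gene.seq_id} missing from genome")
        result = extract_upstream(
            gene, by_contig[gene.seq_id], genes, span=span, repeats=repeats,
            species=species,
        )
        if isinstance(result, RemovalVerdict):
            removed.append(result)
        else:
            regions[gene.gene_id] = result
    return regions, removed
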