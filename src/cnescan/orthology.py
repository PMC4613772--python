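"""Reciprocal best hit (RBH) ortholog pairing from directed hit tables.

Two genes are called orthologs when each is the other's best similarity hit
across species. Hits are typically protein-level BLAST results over all
transcripts; they are collapsed to gene level (max bit score) before best-hit
selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .io_formats import HitRecord

__all__ = ["OrthologTable", "best_hits", "reciprocal_best_hits", "collapse_to_genes"]


@dataclass
class OrthologTable:
    central_species: str
    comparator: str
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise ValueError("a gene appears in more than one ortholog pair")

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for a, b in self.pairs:
                fh.write(f"{a}\t{b}\n")


def collapse_to_genes(
    hits: Iterable[HitRecord], transcript_to_gene: Mapping[str, str]
) -> list[HitRecord]:
    """Collapse transcript-level hits to gene level, keeping the max bit score.

    Ids absent from the map are taken to be gene ids already. On equal bit
    score the smaller e-value wins, so the collapsed record carries the
    strongest evidence for the gene pair.
    """
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        q = transcript_to_gene.get(h.query_id, h.query_id)
        s = transcript_to_gene.get(h.subject_id, h.subject_id)
        key = (q, s)
        cur = best.get(key)
        if (
            cur is None
            or h.bit_score > cur.bit_score
            or (h.bit_score == cur.bit_score and h.e_value < cur.e_value)
        ):
            best[key] = HitRecord(q, s, h.bit_score, h.e_value)
    return list(best.values())


def best_hits(hits: Iterable[HitRecord]) -> dict[str, str]:
    """Best subject per query: max bit score, ties by min e-value then subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if (
            cur is None
            or h.bit_score > cur.bit_score
            or (h.bit_score == cur.bit_score and h.e_value < cur.e_value)
            or (
                h.bit_score == cur.bit_score
                and h.e_value == cur.e_value
                and h.subject_id < cur.subject_id
            )
        ):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def reciprocal_best_hits(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    central_species: str = "A",
    comparator: str = "B",
    transcript_to_gene: Optional[Mapping[str, str]] = None,
) -> OrthologTable:
    """Pairs (a, b) with best_AB(a) == b and best_BA(b) == a."""
    if transcript_to_gene is not None:
        hits_ab = collapse_to_genes(hits_ab, transcript_to_gene)
        hits_ba = collapse_to_genes(hits_ba, transcript_to_gene)
    fwd = best_hits(hits_ab)
    rev = best_hits(hits_ba)
    pairs = sorted((a, b) for a, b in fwd.items() if rev.get(b) == a)
    return OrthologTable(central_species, comparator, pairs)
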