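"""Synthetic orthologous upstream cohorts with planted truth.

The generator emulates the inputs of the footprinting analysis: for each gene
an ancestral upstream region is drawn and evolved independently down a star
phylogeny (per-species substitution and indel rates), conserved elements are
evolved at their own much lower rate and re-inserted at a fixed distance from
the translation start in every carrier species, repeats are planted and
annotated, and pseudo-ortholog pairings (a derangement of the genes) provide
the false-discovery control. Everything is deterministic given the cohort
seed; per-stage streams are derived from it.

What this emulates and what it does not: divergence is i.i.d. per site on a
star phylogeny with geometric indel lengths -- there is no rate heterogeneity,
no phylogenetic correlation between comparator species, and no selection
model. Planted elements never receive indels (they are spliced back in after
background evolution) so that positional truth is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    GeneFeature,
    Interval,
    SequenceRecord,
    reverse_complement,
    write_bed,
    write_fasta,
    write_gff_genes,
)

__all__ = [
    "SpeciesParams",
    "EvolutionConfig",
    "PlantedElement",
    "SyntheticCohort",
    "evolve_sequence",
    "generate_ortholog_cohort",
    "generate_pseudo_ortholog_pairs",
    "plant_hairpin_alignment",
    "generate_transcriptome",
]

_BASES = np.array(list("ACGT"))
GENE_BODY_LENGTH = 300  # synthetic CDS placed immediately 3' of each region


@dataclass(frozen=True)
class SpeciesParams:
    name: str
    substitution_rate: float
    indel_rate: float
    indel_mean_length: float = 3.0

    def __post_init__(self):
        if not (0 <= self.substitution_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")


@dataclass
class EvolutionConfig:
    """Study conditions for a cohort.

    Defaults mirror the real analysis: 2 kb upstream regions, a central
    species plus four comparators at deep divergence (background substitution
    rate 0.35 per site per branch, 1% indels), AT-rich intergenic background.
    """

    ancestor_length: int = 2000
    gc: float = 0.40
    n_genes: int = 10
    central_species: str = "central"
    species: tuple[SpeciesParams, ...] = (
        SpeciesParams("comp1", 0.35, 0.01),
        SpeciesParams("comp2", 0.35, 0.01),
        SpeciesParams("comp3", 0.35, 0.01),
        SpeciesParams("comp4", 0.35, 0.01),
    )
    seed: int = 0

    def __post_init__(self):
        if self.ancestor_length <= 0:
            raise ValueError("ancestor_length must be positive")
        if not 0 <= self.gc <= 1:
            raise ValueError("gc must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedElement:
    """A conserved element at a fixed distance 5' of the translation start.

    An optional motif is written into the ancestral element sequence at a
    fixed offset (shared across genes), so that motif over-representation in
    discovered elements can be tested against matched controls.
    """

    distance_from_tls: int = 200
    length: int = 90
    element_substitution_rate: float = 0.02
    gc: Optional[float] = None  # None: background composition
    present_in: Optional[frozenset[str]] = None  # None: all species
    motif: Optional[str] = None
    motif_offset: int = 10

    def __post_init__(self):
        if self.distance_from_tls < 0:
            raise ValueError("distance must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.motif is not None and self.motif_offset + len(self.motif) > self.length:
            raise ValueError("motif does not fit in the element")


@dataclass
class SyntheticCohort:
    config: EvolutionConfig
    genomes: dict[str, list[SequenceRecord]]  # species -> contigs
    genes: dict[str, list[GeneFeature]]  # species -> gene features
    regions: dict[str, dict[str, str]]  # species -> gene -> upstream sequence
    truth: dict[str, list[Interval]]  # species -> planted element intervals (genomic)
    truth_region: dict[str, dict[str, list[Interval]]]  # species -> gene -> region coords
    repeats: dict[str, list[Interval]]  # species -> planted repeat intervals (genomic)
    elements: list[PlantedElement]
    element_sequences: dict[tuple[str, str, int], str] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes[self.config.central_species]]

    def write(self, outdir: str | Path) -> None:
        """Write per-species FASTA + GFF3 + truth/repeat BED and a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp, contigs in self.genomes.items():
            write_fasta(contigs, outdir / f"{sp}.genome.fa")
            write_gff_genes(self.genes[sp], outdir / f"{sp}.genes.gff3")
            if self.truth[sp]:
                write_bed(self.truth[sp], outdir / f"{sp}.truth.bed")
            if self.repeats[sp]:
                write_bed(self.repeats[sp], outdir / f"{sp}.repeats.bed")
        with open(outdir / "manifest.txt", "w") as fh:
            fh.write(f"central_species\t{self.config.central_species}\n")
            fh.write(f"n_genes\t{self.config.n_genes}\n")
            fh.write(f"ancestor_length\t{self.config.ancestor_length}\n")
            fh.write(f"seed\t{self.config.seed}\n")
            for sp in self.genomes:
                fh.write(f"species\t{sp}\n")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def evolve_sequence(
    ancestor: str,
    substitution_rate: float,
    indel_rate: float,
    indel_mean_len: float = 3.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Evolve a sequence: i.i.d. substitutions plus geometric-length indels.

    Each site is substituted with the given probability (to a uniformly
    chosen different base). Independently, each site nucleates an indel with
    probability ``indel_rate`` (insertion or deletion with equal odds,
    geometric length with the given mean). Deterministic given the seed.
    """
    if not (0 <= substitution_rate <= 1 and 0 <= indel_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(ancestor)
    if n == 0:
        return ""
    idx = np.array([{"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}[c] for c in ancestor])
    sub_mask = rng.random(n) < substitution_rate
    shifts = rng.integers(1, 4, size=n)
    new_idx = idx.copy()
    subbable = sub_mask & (idx < 4)
    new_idx[subbable] = (idx[subbable] + shifts[subbable]) % 4
    seq = np.where(new_idx < 4, _BASES[np.clip(new_idx, 0, 3)], "N")

    if indel_rate == 0:
        return "".join(seq)

    p_geom = 1.0 / max(indel_mean_len, 1.0)
    out: list[str] = []
    indel_here = rng.random(n) < indel_rate
    i = 0
    while i < n:
        if indel_here[i]:
            length = int(rng.geometric(p_geom))
            if rng.random() < 0.5:  # insertion before this site
                out.append(_random_sequence(rng, length, 0.5))
                out.append(str(seq[i]))
                i += 1
            else:  # deletion starting at this site
                i += length
        else:
            out.append(str(seq[i]))
            i += 1
    return "".join(out)


def _fit_length(seq: str, target: int, rng: np.random.Generator, gc: float) -> str:
    """Trim or pad at the 5' end so the region keeps its exact length."""
    if len(seq) > target:
        return seq[len(seq) - target :]
    if len(seq) < target:
        return _random_sequence(rng, target - len(seq), gc) + seq
    return seq


REPEAT_UNIT = "ACGGTACGGT"  # planted repeat: tandem copies of a 10-mer


def generate_ortholog_cohort(
    config: EvolutionConfig,
    planted: Sequence[PlantedElement] = (),
    repeats_per_gene: int = 0,
    repeat_length: int = 60,
    planted_per_gene: Optional[Sequence[Sequence[PlantedElement]]] = None,
) -> SyntheticCohort:
    """Generate a cohort of orthologous upstream regions with planted truth.

    Layout per gene and species: one contig holding the upstream region
    (exactly ``ancestor_length`` bp, element truth at exact distances from the
    translation start) followed by a synthetic gene body, so that upstream
    extraction recovers the region byte-for-byte.

    ``planted`` is applied to every gene; ``planted_per_gene`` (one element
    list per gene, length ``n_genes``) overrides it, e.g. to vary element
    distances across genes for positional-conservation studies.
    """
    if planted_per_gene is not None:
        if len(planted_per_gene) != config.n_genes:
            raise ValueError("planted_per_gene must list one element set per gene")
        gene_elements = [list(els) for els in planted_per_gene]
    else:
        gene_elements = [list(planted) for _ in range(config.n_genes)]
    for els in gene_elements:
        spans = sorted(
            ((e.distance_from_tls, e.distance_from_tls + e.length) for e in els)
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("planted elements overlap")
        for e in els:
            if e.distance_from_tls + e.length > config.ancestor_length:
                raise ValueError("planted element does not fit in the region")
    if repeats_per_gene * (repeat_length + 20) > config.ancestor_length // 2:
        raise ValueError("too many planted repeats for the region length")

    rng = np.random.default_rng(config.seed)
    all_species = [config.central_species] + [sp.name for sp in config.species]
    params = {config.central_species: SpeciesParams(config.central_species, 0.0, 0.0)}
    for sp in config.species:
        params[sp.name] = sp

    genomes: dict[str, list[SequenceRecord]] = {sp: [] for sp in all_species}
    genes: dict[str, list[GeneFeature]] = {sp: [] for sp in all_species}
    regions: dict[str, dict[str, str]] = {sp: {} for sp in all_species}
    truth: dict[str, list[Interval]] = {sp: [] for sp in all_species}
    truth_region: dict[str, dict[str, list[Interval]]] = {sp: {} for sp in all_species}
    repeats: dict[str, list[Interval]] = {sp: [] for sp in all_species}
    element_sequences: dict[tuple[str, str, int], str] = {}

    L = config.ancestor_length
    for g in range(config.n_genes):
        gene_id = f"g{g:03d}"
        planted_here = gene_elements[g]
        ancestor = _random_sequence(rng, L, config.gc)
        anc_elements = []
        for e in planted_here:
            if e.gc is None:
                seq = _random_sequence(rng, e.length, config.gc)
            else:
                seq = _random_sequence(rng, e.length, e.gc)
            if e.motif is not None:
                seq = (
                    seq[: e.motif_offset]
                    + e.motif
                    + seq[e.motif_offset + len(e.motif) :]
                )
            anc_elements.append(seq)
        body = _random_sequence(rng, GENE_BODY_LENGTH, 0.5)

        # choose repeat placements in region coordinates, clear of elements
        rep_spans: list[tuple[int, int]] = []
        tries = 0
        while len(rep_spans) < repeats_per_gene and tries < 200:
            tries += 1
            start = int(rng.integers(0, L - repeat_length))
            span = (start, start + repeat_length)
            blocked = [(L - e.distance_from_tls - e.length, L - e.distance_from_tls) for e in planted_here]
            if any(span[0] < b[1] and b[0] < span[1] for b in blocked + rep_spans):
                continue
            rep_spans.append(span)

        for sp_name in all_species:
            p = params[sp_name]
            child_rng = np.random.default_rng(
                rng.integers(0, 2**31 - 1)
            )
            background = evolve_sequence(
                ancestor, p.substitution_rate, p.indel_rate, p.indel_mean_length,
                seed=child_rng,
            )
            region = _fit_length(background, L, child_rng, config.gc)
            region_chars = list(region)
            gene_truth: list[Interval] = []
            for e, anc_seq in zip(planted_here, anc_elements):
                carriers = e.present_in
                if carriers is not None and sp_name not in carriers:
                    continue
                evolved = evolve_sequence(
                    anc_seq, e.element_substitution_rate, 0.0, seed=child_rng
                )
                start = L - e.distance_from_tls - e.length
                region_chars[start : start + e.length] = list(evolved)
                gene_truth.append(
                    Interval(f"{sp_name}.{gene_id}", start, start + e.length,
                             name=f"{gene_id}.elem{e.distance_from_tls}")
                )
                element_sequences[(sp_name, gene_id, e.distance_from_tls)] = evolved
            for start, end in rep_spans:
                unit = REPEAT_UNIT
                rep = (unit * (repeat_length // len(unit) + 1))[: end - start]
                region_chars[start:end] = list(rep)
                repeats[sp_name].append(
                    Interval(f"{sp_name}.{gene_id}", start, end, name="repeat")
                )
            region = "".join(region_chars)
            contig_id = f"{sp_name}.{gene_id}"
            contig = region + body
            genomes[sp_name].append(SequenceRecord(contig_id, contig))
            genes[sp_name].append(
                GeneFeature(gene_id, contig_id, "+", L, (L, L + GENE_BODY_LENGTH))
            )
            regions[sp_name][gene_id] = region
            truth[sp_name].extend(gene_truth)
            truth_region[sp_name][gene_id] = [
                Interval(gene_id, iv.start, iv.end, name=iv.name) for iv in gene_truth
            ]

    return SyntheticCohort(
        config=config,
        genomes=genomes,
        genes=genes,
        regions=regions,
        truth=truth,
        truth_region=truth_region,
        repeats=repeats,
        elements=[e for els in gene_elements for e in els],
        element_sequences=element_sequences,
    )


def generate_pseudo_ortholog_pairs(
    cohort: SyntheticCohort, seed: int = 0
) -> list[tuple[str, str]]:
    """Uniformly random derangement of gene pairings (no gene with its ortholog)."""
    gene_ids = cohort.gene_ids
    n = len(gene_ids)
    if n < 2:
        raise ValueError("need at least two genes for pseudo-ortholog pairing")
    rng = np.random.default_rng(seed)
    while True:  # rejection sampling: uniform over derangements
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            break
    return [(gene_ids[i], gene_ids[perm[i]]) for i in range(n)]


_PAIRABLE = {"A": "T", "T": "A", "C": "G", "G": "C"}


def plant_hairpin_alignment(
    n_rows: int,
    stem_len: int = 12,
    loop_len: int = 4,
    stem_identity: float = 1.0,
    loop_substitution_rate: float = 0.5,
    seed: int = 0,
    flank_len: int = 0,
):
    """Alignment block of hairpins: conserved complementary stems, variable loop.

    Each row is 5'-stem + loop + reverse-complement 3'-stem (optionally with
    mutated flanks); rows form a gapless alignment. Emulates a deeply
    conserved hairpin whose stem base-pairing is preserved while the apical
    loop sequence drifts.
    """
    if stem_len < 2:
        raise ValueError("stem_len must be >= 2")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (minimum hairpin loop)")
    from .rna_structure import AlignmentBlock  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    stem5 = _random_sequence(rng, stem_len, 0.5)
    loop = _random_sequence(rng, loop_len, 0.5)
    flank = _random_sequence(rng, flank_len, 0.5) if flank_len else ""
    rows = []
    for r in range(n_rows):
        row_stem = evolve_sequence(stem5, 1.0 - stem_identity, 0.0, seed=rng)
        row_loop = evolve_sequence(loop, loop_substitution_rate, 0.0, seed=rng)
        row_flank = evolve_sequence(flank, 0.5, 0.0, seed=rng) if flank else ""
        stem3 = reverse_complement(row_stem)
        rows.append((f"sp{r}", row_flank + row_stem + row_loop + stem3))
    return AlignmentBlock(rows)


def generate_transcriptome(
    cohort: SyntheticCohort, fraction_of_element_transcribed: float = 1.0
) -> list[SequenceRecord]:
    """Central-species transcripts covering a 5'-anchored fraction of each element.

    Each planted element contributes exactly ceil(fraction * length) of its 5'
    end to a transcript; the remainder of the transcript is gene-body sequence
    so that junction k-mers do not match the element.
    """
    if not 0 <= fraction_of_element_transcribed <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    central = cohort.config.central_species
    bodies = {r.id: r.sequence for r in cohort.genomes[central]}
    L = cohort.config.ancestor_length
    out: list[SequenceRecord] = []
    for gene_id in cohort.gene_ids:
        contig_id = f"{central}.{gene_id}"
        body = bodies[contig_id][L:]
        for k, iv in enumerate(cohort.truth_region[central].get(gene_id, [])):
            elem = cohort.regions[central][gene_id][iv.start : iv.end]
            # round before ceil so 1/3 of 90 is 30, not 31
            take = math.ceil(round(fraction_of_element_transcribed * len(elem), 9))
            prefix = elem[:take]
            tx_body = body
            if 0 < take < len(elem) and body and body[0] == elem[take]:
                # break the junction so no k-mer spanning it can extend a match
                tx_body = {"A": "C", "C": "G", "G": "T", "T": "A"}[body[0]] + body[1:]
            out.append(
                SequenceRecord(f"{gene_id}.tx{k}", prefix + tx_body, "synthetic transcript")
            )
        if not cohort.truth_region[central].get(gene_id):
            out.append(SequenceRecord(f"{gene_id}.tx0", body, "synthetic transcript"))
    return out
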