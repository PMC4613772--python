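"""End-to-end orchestration: discovery and characterization.

Discovery wires the stages together: upstream extraction, repeat masking,
all-window-pairs alignment of each central-species region against its
orthologs, bundling into candidates, pseudo-ortholog calibration of the CCS
detection threshold, coding-sequence filtering, and final re-scoring under
the strict bounds. Characterization produces the comparison tables between
CNEs and pseudo-CNEs (composition, position, transcribed overlap, structure
conservation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cne_call import (
    CANDIDATE_BOUNDS,
    FINAL_BOUNDS,
    PSEUDO_CNE_CCS_CUTOFF,
    CNE,
    CandidateCNE,
    ThresholdConfig,
    calibrate_ccs_threshold,
    call_candidates_for_gene,
    call_pseudo_cnes,
    coding_filter,
    rescore_candidate,
)
from .cne_features import (
    distance_to_translation_start,
    hypergeometric_enrichment,
    kmer_transcribed_overlap,
    position_conservation_test,
    rank_sum_test,
    sequence_composition,
)
from .io_formats import HitRecord, Interval, SequenceRecord
from .rna_structure import AlignmentBlock, MaxPairEngine, sci_empirical_pvalue
from .upstream_extract import UpstreamRegion
from .window_align import ScoringScheme

logger = logging.getLogger("cnescan")

__all__ = ["RunConfig", "RunReport", "DiscoveryResult", "run_discovery", "run_characterization"]


@dataclass
class RunConfig:
    """Run parameters; defaults are the published protocol values."""

    span: int = 2000
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    candidate_bounds: tuple[float, float] = CANDIDATE_BOUNDS
    final_bounds: tuple[float, float] = FINAL_BOUNDS
    pseudo_cne_ccs_cutoff: float = PSEUDO_CNE_CCS_CUTOFF
    kmer_length: int = 20
    sci_shuffles: int = 1000
    n_composition_controls: int = 10
    n_motif_controls: int = 100
    seed: int = 0
    central_species: str = "central"


@dataclass
class RunReport:
    counts: dict[str, int] = field(default_factory=dict)
    calibrated_ccs_threshold: float = 0.0
    coding_evalue_threshold: float = float("inf")
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    stats: dict[str, float] = field(default_factory=dict)


@dataclass
class DiscoveryResult:
    cnes: list[CNE]
    candidates: list[CandidateCNE]
    pseudo_candidates: list[CandidateCNE]
    threshold: float
    report: RunReport


def _comparators_for_gene(
    gene_id: str,
    comparator_regions: Mapping[str, Mapping[str, UpstreamRegion]],
    ortholog_maps: Mapping[str, Mapping[str, str]],
) -> dict[str, UpstreamRegion]:
    comps: dict[str, UpstreamRegion] = {}
    for species, regions in comparator_regions.items():
        partner = ortholog_maps.get(species, {}).get(gene_id)
        if partner is None:
            continue
        region = regions.get(partner)
        if region is not None:
            comps[species] = region
    return comps


def run_discovery(
    central_regions: Mapping[str, UpstreamRegion],
    comparator_regions: Mapping[str, Mapping[str, UpstreamRegion]],
    ortholog_maps: Mapping[str, Mapping[str, str]],
    pseudo_pairs: Sequence[tuple[str, str]],
    config: Optional[RunConfig] = None,
    true_hits: Iterable[HitRecord] = (),
    permuted_hits: Iterable[HitRecord] = (),
) -> DiscoveryResult:
    """Two-phase calibrated discovery over one cohort.

    ortholog_maps: species -> {central gene -> comparator gene}. Pseudo pairs
    re-pair central genes with the comparator orthologs of a different gene.
    """
    config = config or RunConfig()
    cand_thresholds = ThresholdConfig(*config.candidate_bounds)
    final_thresholds = ThresholdConfig(*config.final_bounds)
    report = RunReport()
    report.counts["central_regions"] = len(central_regions)

    candidates: list[CandidateCNE] = []
    comps_by_gene: dict[str, dict[str, UpstreamRegion]] = {}
    for gene_id, region in central_regions.items():
        comps = _comparators_for_gene(gene_id, comparator_regions, ortholog_maps)
        comps_by_gene[gene_id] = comps
        if not comps:
            logger.warning("gene %s has no comparator regions; skipped", gene_id)
            continue
        candidates.extend(
            call_candidates_for_gene(region, comps, cand_thresholds, config.scheme)
        )
    report.counts["candidates"] = len(candidates)

    pseudo_candidates: list[CandidateCNE] = []
    for central_gene, partner_gene in pseudo_pairs:
        region = central_regions.get(central_gene)
        comps = _comparators_for_gene(partner_gene, comparator_regions, ortholog_maps)
        if region is None or not comps:
            continue
        pseudo_candidates.extend(
            call_candidates_for_gene(region, comps, cand_thresholds, config.scheme)
        )
    report.counts["pseudo_candidates"] = len(pseudo_candidates)

    threshold = calibrate_ccs_threshold(pseudo_candidates)
    report.calibrated_ccs_threshold = threshold
    detected = [c for c in candidates if c.ccs > threshold]
    report.counts["detected"] = len(detected)

    passed, removed, e_threshold = coding_filter(detected, true_hits, permuted_hits)
    report.coding_evalue_threshold = e_threshold
    report.counts["post_coding_filter"] = len(passed)
    if e_threshold == float("inf") and any(True for _ in true_hits):
        logger.warning("no permuted hits: coding threshold is +inf, any hit removes")

    cnes: list[CNE] = []
    for cand in passed:
        region = central_regions[cand.gene_id]
        final = rescore_candidate(
            cand, region, comps_by_gene[cand.gene_id], final_thresholds, config.scheme
        )
        cnes.append(
            CNE(
                gene_id=cand.gene_id,
                central_interval=cand.central_interval,
                genomic_interval=region.to_genomic(
                    cand.central_interval.start, cand.central_interval.end
                ),
                supports=final.supports or cand.supports,
                ccs=final.ccs,
                passed_coding_filter=True,
            )
        )
    report.counts["cnes"] = len(cnes)
    logger.info(
        "discovery: %d candidates, threshold %.3f, %d detected, %d after coding filter",
        len(candidates), threshold, len(detected), len(cnes),
    )
    return DiscoveryResult(cnes, candidates, pseudo_candidates, threshold, report)


def feature_table(
    cnes: Sequence[CNE],
    central_regions: Mapping[str, UpstreamRegion],
    transcripts: Sequence[SequenceRecord] = (),
    k: int = 20,
) -> pd.DataFrame:
    rows = []
    for idx, cne in enumerate(cnes):
        region = central_regions[cne.gene_id]
        seq = region.sequence[cne.central_interval.start : cne.central_interval.end]
        comp = sequence_composition(seq)
        overlap = (
            kmer_transcribed_overlap(seq, transcripts, k=k) if transcripts else None
        )
        rows.append(
            {
                "cne_id": f"{cne.gene_id}.cne{idx}",
                "gene_id": cne.gene_id,
                "gc": comp.gc,
                "cpg_oe": comp.cpg_oe,
                "length": len(cne.central_interval),
                "distance_to_tls": distance_to_translation_start(
                    cne.central_interval, region
                ),
                "transcribed_overlap_pct": overlap,
                "atg_count": comp.trinucleotide_counts.get("ATG", 0),
                "ccs": cne.ccs,
                "n_species": len(cne.supports),
            }
        )
    return pd.DataFrame(rows)


def _position_pairs(
    cnes: Sequence[CNE],
    central_regions: Mapping[str, UpstreamRegion],
    comparator_regions: Mapping[str, Mapping[str, UpstreamRegion]],
    ortholog_maps: Mapping[str, Mapping[str, str]],
) -> list[tuple[float, float]]:
    pairs = []
    for cne in cnes:
        d_central = distance_to_translation_start(
            cne.central_interval, central_regions[cne.gene_id]
        )
        for species, (sup_iv, _) in cne.supports.items():
            partner = ortholog_maps.get(species, {}).get(cne.gene_id)
            if partner is None:
                continue
            region = comparator_regions[species].get(partner)
            if region is None:
                continue
            end = min(sup_iv.end, len(region.sequence))
            pairs.append((float(d_central), float(len(region.sequence) - end)))
    return pairs


def cne_alignment_block(
    cne: CNE,
    central_regions: Mapping[str, UpstreamRegion],
    comparator_regions: Mapping[str, Mapping[str, UpstreamRegion]],
    ortholog_maps: Mapping[str, Mapping[str, str]],
    central_species: str = "central",
) -> Optional[AlignmentBlock]:
    """Ungapped alignment block over the CNE footprint (central + supports).

    Support sequences are anchored at their support start and trimmed to the
    central interval length; this is adequate for elements conserved without
    indels and is the input the SCI machinery expects.
    """
    region = central_regions[cne.gene_id]
    length = len(cne.central_interval)
    rows = [
        (
            central_species,
            region.sequence[cne.central_interval.start : cne.central_interval.end],
        )
    ]
    for species, (sup_iv, _) in cne.supports.items():
        partner = ortholog_maps.get(species, {}).get(cne.gene_id)
        if partner is None:
            continue
        comp_region = comparator_regions[species].get(partner)
        if comp_region is None:
            continue
        seq = comp_region.sequence[sup_iv.start : sup_iv.start + length]
        if len(seq) == length:
            rows.append((species, seq))
    if len(rows) < 2:
        return None
    return AlignmentBlock(rows)


def run_characterization(
    cnes: Sequence[CNE],
    pseudo_cnes: Sequence[CNE],
    central_regions: Mapping[str, UpstreamRegion],
    comparator_regions: Mapping[str, Mapping[str, UpstreamRegion]] = None,
    ortholog_maps: Mapping[str, Mapping[str, str]] = None,
    transcripts: Sequence[SequenceRecord] = (),
    config: Optional[RunConfig] = None,
    deep_subset: Optional[Sequence[int]] = None,
    run_sci: bool = False,
) -> RunReport:
    """Comparison statistics between CNEs and pseudo-CNEs.

    Returns a report with the per-CNE feature tables, Wilcoxon comparisons of
    GC / CpG O/E / length / TLS distance, the positional-conservation test,
    transcribed-overlap enrichment of the designated deep subset (indices
    into cnes), and optionally SCI reports per CNE.
    """
    config = config or RunConfig()
    report = RunReport()
    report.counts["cnes"] = len(cnes)
    report.counts["pseudo_cnes"] = len(pseudo_cnes)
    if not cnes:
        return report

    table = feature_table(cnes, central_regions, transcripts, config.kmer_length)
    report.tables["cne_features"] = table
    if pseudo_cnes:
        pseudo_table = feature_table(
            pseudo_cnes, central_regions, transcripts, config.kmer_length
        )
        report.tables["pseudo_features"] = pseudo_table
        for feature in ("gc", "cpg_oe", "length", "distance_to_tls"):
            x = table[feature].dropna().to_numpy()
            y = pseudo_table[feature].dropna().to_numpy()
            if len(x) and len(y):
                u, p = rank_sum_test(x, y)
                report.stats[f"wilcoxon_{feature}_p"] = p

    if comparator_regions is not None and ortholog_maps is not None:
        pairs = _position_pairs(cnes, central_regions, comparator_regions, ortholog_maps)
        if len(pairs) >= 3:
            try:
                rho, p = position_conservation_test(pairs)
                report.stats["position_rho"] = rho
                report.stats["position_p"] = p
            except ValueError:
                pass

    if transcripts and deep_subset is not None:
        overlaps = table["transcribed_overlap_pct"]
        covered = [
            o is not None and not np.isnan(o) and _length_fraction(o, table["length"][i], config.kmer_length) >= 1 / 3
            for i, o in enumerate(overlaps)
        ]
        N = len(cnes)
        K = sum(covered)
        subset = list(deep_subset)
        n = len(subset)
        k = sum(1 for i in subset if covered[i])
        if n:
            report.stats["deep_overlap_enrichment_p"] = hypergeometric_enrichment(
                N, K, n, k
            )

    if run_sci and comparator_regions is not None and ortholog_maps is not None:
        sci_rows = []
        engine = MaxPairEngine()
        for idx, cne in enumerate(cnes):
            block = cne_alignment_block(
                cne, central_regions, comparator_regions, ortholog_maps,
                config.central_species,
            )
            if block is None:
                continue
            try:
                rep = sci_empirical_pvalue(
                    block, engine, n=config.sci_shuffles, seed=config.seed + idx
                )
            except ValueError:
                continue
            sci_rows.append(
                {
                    "cne_id": f"{cne.gene_id}.cne{idx}",
                    "sci": rep.sci,
                    "z": rep.z,
                    "p": rep.empirical_p,
                    "engine": rep.engine,
                    "n_valid": rep.n_valid,
                }
            )
        report.tables["sci"] = pd.DataFrame(sci_rows)
    return report


def _length_fraction(overlap_pct: float, length: int, k: int) -> float:
    """Convert a k-mer overlap percentage to a covered-length fraction."""
    n_kmers = length - k + 1
    if n_kmers <= 0:
        return 0.0
    matched = overlap_pct / 100.0 * n_kmers
    if matched <= 0:
        return 0.0
    return min(1.0, (matched + k - 1) / length)
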