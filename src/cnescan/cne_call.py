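"""Calibrated CNE calling from window score grids.

The calling machinery follows a two-phase protocol. Candidate discovery runs
with permissive bounds (L=80, U=94 on the 0-100 intermediate scale): window
pairs scoring above L become significant pairs, overlapping central-species
windows are bundled into candidate elements with per-species supports, and
each candidate receives a combined conservation score (CCS)

    CCS = 1 - prod_i (1 - P_i)

over the per-species maximum conservation scores P_i. The same machinery is
run on pseudo-ortholog pairs (randomly re-paired upstream regions); the
detection threshold is set to the maximum CCS seen there, so by construction
no conservation is detected in the control. Surviving candidates are filtered
for similarity to coding sequence using a permutation-derived e-value
threshold, then re-scored with strict bounds (L=87, U=100) to assign final
confidence scores.

Repeat annotation is applied punitively before alignment by masking repeat
positions to N, which scores as a mismatch against everything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io_formats import HitRecord, Interval
from .upstream_extract import UpstreamRegion
from .window_align import ScoringScheme, WindowScoreGrid, all_window_pairs

__all__ = [
    "ThresholdConfig",
    "ScoredWindowPair",
    "CandidateCNE",
    "CNE",
    "apply_repeat_penalty",
    "intermediate_score",
    "sigmoid_scale",
    "extract_significant_windows",
    "bundle_windows",
    "combined_conservation_score",
    "calibrate_ccs_threshold",
    "permute_sequence",
    "coding_filter",
    "call_candidates_for_gene",
    "call_pseudo_cnes",
]

CANDIDATE_BOUNDS = (80.0, 94.0)
FINAL_BOUNDS = (87.0, 100.0)
PSEUDO_CNE_CCS_CUTOFF = 0.528


@dataclass(frozen=True)
class ThresholdConfig:
    L: float = CANDIDATE_BOUNDS[0]
    U: float = CANDIDATE_BOUNDS[1]
    ccs_threshold: float = 0.0
    pseudo_cne_ccs_cutoff: float = PSEUDO_CNE_CCS_CUTOFF

    def __post_init__(self) -> None:
        if not (0 <= self.L < self.U <= 100):
            raise ValueError("need 0 <= L < U <= 100")


@dataclass
class ScoredWindowPair:
    central_offset: int
    comparator_offset: int
    raw_score: float
    intermediate_score: float
    conservation_score: float
    comparator_species: str


@dataclass
class CandidateCNE:
    gene_id: str
    central_interval: Interval  # region coordinates on the central species
    supports: dict[str, tuple[Interval, float]]  # species -> (interval, P_i)
    ccs: float

    @property
    def p_values(self) -> list[float]:
        return [p for _, p in self.supports.values()]


@dataclass
class CNE:
    gene_id: str
    central_interval: Interval
    genomic_interval: Interval
    supports: dict[str, tuple[Interval, float]]
    ccs: float
    passed_coding_filter: bool = True
    pseudo: bool = False


def apply_repeat_penalty(region: UpstreamRegion) -> str:
    """Mask annotated repeat positions to N so they score as mismatches."""
    n = len(region.sequence)
    for s, e in region.repeat_mask:
        if not (0 <= s < e <= n):
            raise ValueError(f"repeat mask [{s}, {e}) outside region of length {n}")
    if not region.repeat_mask:
        return region.sequence
    chars = list(region.sequence)
    for s, e in region.repeat_mask:
        chars[s:e] = "N" * (e - s)
    return "".join(chars)


def intermediate_score(raw: float, w: int) -> float:
    """Percent-of-maximum window score, on the 0-100 scale the bounds use."""
    if not 0 <= raw <= w:
        raise ValueError(f"raw score {raw} outside [0, {w}]")
    return 100.0 * raw / w


def sigmoid_scale(s: float, L: float, U: float) -> float:
    """Conservation score on [0, 1]: 0 below L, 1 above U, sigmoid between.

    The curve is a logistic with slope parameter k = 10/(U-L) centred at the
    midpoint, affinely rescaled to hit exactly 0 at L and 1 at U; it is
    strictly increasing on (L, U) with value 0.5 at the midpoint.
    """
    if not L < U:
        raise ValueError("need L < U")
    if s <= L:
        return 0.0
    if s >= U:
        return 1.0
    k = 10.0 / (U - L)
    mid = 0.5 * (L + U)
    f = 1.0 / (1.0 + math.exp(-k * (s - mid)))
    f_l = 1.0 / (1.0 + math.exp(-k * (L - mid)))
    f_u = 1.0 / (1.0 + math.exp(-k * (U - mid)))
    return (f - f_l) / (f_u - f_l)


def extract_significant_windows(
    grid: WindowScoreGrid,
    thresholds: ThresholdConfig,
    comparator_species: str = "",
) -> list[ScoredWindowPair]:
    """All window pairs whose intermediate score exceeds the lower bound L."""
    w = grid.scheme.window_length
    floor_raw = thresholds.L * w / 100.0  # intermediate > L  <=>  raw > floor
    ii, jj = np.nonzero(grid.scores > floor_raw)
    out: list[ScoredWindowPair] = []
    for i, j in zip(ii.tolist(), jj.tolist()):
        raw = float(grid.scores[i, j])
        inter = intermediate_score(raw, w)
        out.append(
            ScoredWindowPair(
                central_offset=i,
                comparator_offset=j,
                raw_score=raw,
                intermediate_score=inter,
                conservation_score=sigmoid_scale(inter, thresholds.L, thresholds.U),
                comparator_species=comparator_species,
            )
        )
    return out


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Transitive closure of overlap merging (touching intervals stay separate)."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def bundle_windows(
    pairs_by_species: Mapping[str, Sequence[ScoredWindowPair]],
    w: int,
    gene_id: str = "",
) -> list[CandidateCNE]:
    """Merge overlapping significant windows into candidate CNEs.

    Central-species window intervals [offset, offset+w) that are not disjoint
    are merged (transitively, across species); for each merged central
    interval, each species' support is the hull of its windows overlapping the
    interval and P_i is the maximum conservation score among them.
    """
    central: list[tuple[int, int]] = []
    for pairs in pairs_by_species.values():
        central.extend((p.central_offset, p.central_offset + w) for p in pairs)
    if not central:
        return []
    candidates: list[CandidateCNE] = []
    for cs, ce in _merge_intervals(central):
        supports: dict[str, tuple[Interval, float]] = {}
        for species in sorted(pairs_by_species):
            overlapping = [
                p
                for p in pairs_by_species[species]
                if p.central_offset < ce and p.central_offset + w > cs
            ]
            if not overlapping:
                continue
            lo = min(p.comparator_offset for p in overlapping)
            hi = max(p.comparator_offset for p in overlapping) + w
            p_i = max(p.conservation_score for p in overlapping)
            supports[species] = (Interval(species, lo, hi), p_i)
        if supports:
            candidates.append(
                CandidateCNE(
                    gene_id=gene_id,
                    central_interval=Interval(gene_id or "central", cs, ce),
                    supports=supports,
                    ccs=combined_conservation_score(
                        [p for _, p in supports.values()]
                    ),
                )
            )
    return candidates


def combined_conservation_score(p_list: Sequence[float]) -> float:
    """CCS = 1 - prod_i (1 - P_i) over per-species maximum conservation scores."""
    if len(p_list) == 0:
        raise ValueError("need at least one species conservation score")
    prod = 1.0
    for p in p_list:
        if not 0 <= p <= 1:
            raise ValueError("conservation scores must lie in [0, 1]")
        prod *= 1.0 - p
    return 1.0 - prod


def calibrate_ccs_threshold(pseudo_candidates: Sequence[CandidateCNE]) -> float:
    """Detection threshold: the maximum CCS observed on pseudo-ortholog pairs.

    Detection is the strict rule CCS > threshold, so at the calibrated value
    no conservation at all is detected in the control, by construction.
    """
    if not pseudo_candidates:
        return 0.0
    return max(c.ccs for c in pseudo_candidates)


def permute_sequence(seq: str, seed: int = 0) -> str:
    """Uniform random permutation of the residues (multiset preserved)."""
    rng = np.random.default_rng(seed)
    chars = np.array(list(seq))
    return "".join(chars[rng.permutation(len(chars))]) if len(chars) else ""


def coding_filter(
    candidates: Sequence,
    true_hits: Iterable[HitRecord],
    permuted_hits: Iterable[HitRecord],
    id_of=lambda c: c.gene_id,
) -> tuple[list, list, float]:
    """Discard candidates resembling coding sequence more than chance allows.

    The threshold is the minimum (most significant) e-value obtained by
    permuted versions of the candidate sequences; any candidate with a true
    hit below that threshold is removed. With no permuted hits the threshold
    is +inf and every candidate with any hit at all is removed (logged
    prominently by callers).
    """
    permuted = list(permuted_hits)
    threshold = min((h.e_value for h in permuted), default=math.inf)
    best_true: dict[str, float] = {}
    for h in true_hits:
        cur = best_true.get(h.query_id)
        if cur is None or h.e_value < cur:
            best_true[h.query_id] = h.e_value
    passed, removed = [], []
    for cand in candidates:
        e = best_true.get(id_of(cand))
        if e is not None and e < threshold:
            removed.append(cand)
        else:
            passed.append(cand)
    return passed, removed, threshold


def call_candidates_for_gene(
    central_region: UpstreamRegion,
    comparator_regions: Mapping[str, UpstreamRegion],
    thresholds: ThresholdConfig,
    scheme: ScoringScheme = ScoringScheme(),
) -> list[CandidateCNE]:
    """Run the window scan + bundling for one central gene across species."""
    w = scheme.window_length
    central_seq = apply_repeat_penalty(central_region)
    if len(central_seq) < w:
        return []
    pairs_by_species: dict[str, list[ScoredWindowPair]] = {}
    for species, region in comparator_regions.items():
        comp_seq = apply_repeat_penalty(region)
        if len(comp_seq) < w:
            continue
        grid = all_window_pairs(
            central_seq, comp_seq, scheme,
            ids=(central_region.gene_id, region.gene_id),
        )
        pairs = extract_significant_windows(grid, thresholds, comparator_species=species)
        if pairs:
            pairs_by_species[species] = pairs
    return bundle_windows(pairs_by_species, w, gene_id=central_region.gene_id)


def rescore_candidate(
    cand: CandidateCNE,
    central_region: UpstreamRegion,
    comparator_regions: Mapping[str, UpstreamRegion],
    thresholds: ThresholdConfig,
    scheme: ScoringScheme = ScoringScheme(),
) -> CandidateCNE:
    """Re-assign P_i and CCS under different (stricter) bounds.

    The candidate's footprint is kept; each species' P_i is recomputed as the
    maximum conservation score over window pairs within the candidate's
    central interval and that species' support hull.
    """
    w = scheme.window_length
    central_seq = apply_repeat_penalty(central_region)
    supports: dict[str, tuple[Interval, float]] = {}
    cs, ce = cand.central_interval.start, cand.central_interval.end
    for species, (sup_iv, _) in cand.supports.items():
        region = comparator_regions.get(species)
        if region is None:
            continue
        comp_seq = apply_repeat_penalty(region)
        best = 0.0
        i_lo, i_hi = max(0, cs), min(len(central_seq) - w, ce - w)
        j_lo, j_hi = max(0, sup_iv.start), min(len(comp_seq) - w, sup_iv.end - w)
        if i_hi < i_lo or j_hi < j_lo:
            continue
        sub_grid = all_window_pairs(
            central_seq[i_lo : i_hi + w],
            comp_seq[j_lo : j_hi + w],
            scheme,
        )
        raw_max = float(sub_grid.scores.max())
        best = sigmoid_scale(intermediate_score(raw_max, w), thresholds.L, thresholds.U)
        supports[species] = (sup_iv, best)
    if not supports:
        return replace(cand, supports={}, ccs=0.0)
    return replace(
        cand,
        supports=supports,
        ccs=combined_conservation_score([p for _, p in supports.values()]),
    )


def call_pseudo_cnes(
    pseudo_regions: Sequence[tuple[UpstreamRegion, Mapping[str, UpstreamRegion]]],
    thresholds: Optional[ThresholdConfig] = None,
    ccs_cutoff: float = PSEUDO_CNE_CCS_CUTOFF,
    true_hits: Iterable[HitRecord] = (),
    permuted_hits: Iterable[HitRecord] = (),
    scheme: ScoringScheme = ScoringScheme(),
) -> list[CNE]:
    """Pseudo-CNE control set: permissive bounds, fixed CCS cutoff, coding filter.

    Pseudo-CNEs are high-scoring alignments of non-orthologous region pairs;
    they match true CNEs in every respect except orthology and serve as the
    comparison set for feature statistics.
    """
    thresholds = thresholds or ThresholdConfig(*CANDIDATE_BOUNDS)
    candidates: list[CandidateCNE] = []
    for central_region, comps in pseudo_regions:
        candidates.extend(
            call_candidates_for_gene(central_region, comps, thresholds, scheme)
        )
    kept = [c for c in candidates if c.ccs > ccs_cutoff]
    passed, _removed, _thr = coding_filter(kept, true_hits, permuted_hits)
    out = []
    for cand in passed:
        out.append(
            CNE(
                gene_id=cand.gene_id,
                central_interval=cand.central_interval,
                genomic_interval=cand.central_interval,
                supports=cand.supports,
                ccs=cand.ccs,
                passed_coding_filter=True,
                pseudo=True,
            )
        )
    return out
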