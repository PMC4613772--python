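import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnescan.cne_call import (
    CandidateCNE,
    ScoredWindowPair,
    ThresholdConfig,
    apply_repeat_penalty,
    bundle_windows,
    calibrate_ccs_threshold,
    call_candidates_for_gene,
    call_pseudo_cnes,
    coding_filter,
    combined_conservation_score,
    extract_significant_windows,
    intermediate_score,
    permute_sequence,
    sigmoid_scale,
)
from cnescan.io_formats import HitRecord, Interval
from cnescan.upstream_extract import UpstreamRegion
from cnescan.window_align import ScoringScheme, all_window_pairs


def _region(seq, gene_id="g", mask=()):
    return UpstreamRegion(
        gene_id=gene_id,
        species="sp",
        sequence=seq,
        genomic_interval=Interval("c", 0, len(seq)),
        repeat_mask=list(mask),
    )


class TestRepeatPenalty:
    def test_no_repeats_unchanged(self):
        region = _region("ACGT" * 20)
        assert apply_repeat_penalty(region) == region.sequence

    def test_fully_masked_region_scores_zero(self):
        seq = "ACGT" * 20
        region = _region(seq, mask=[(0, len(seq))])
        masked = apply_repeat_penalty(region)
        assert masked == "N" * len(seq)
        grid = all_window_pairs(masked, masked).scores
        assert grid.max() == 0.0

    def test_partial_mask_costs_matches(self):
        rng = np.random.default_rng(1)
        win = "".join(rng.choice(list("ACGT"), 50))
        region = _region(win, mask=[(10, 20)])
        masked = apply_repeat_penalty(region)
        from cnescan.window_align import window_pair_score

        raw = window_pair_score(masked, win)
        assert raw == 40.0  # 10 masked positions become mismatches
        assert intermediate_score(raw, 50) == 80.0

    def test_mask_outside_region_rejected(self):
        region = _region("ACGT", mask=[(2, 9)])
        with pytest.raises(ValueError):
            apply_repeat_penalty(region)


class TestScoreScaling:
    def test_intermediate_score_is_percent_of_max(self):
        assert intermediate_score(50, 50) == 100.0
        assert intermediate_score(0, 50) == 0.0
        assert intermediate_score(43.5, 50) == 87.0

    def test_intermediate_score_range_checked(self):
        with pytest.raises(ValueError):
            intermediate_score(51, 50)

    def test_sigmoid_endpoints(self):
        assert sigmoid_scale(79, 80, 94) == 0.0
        assert sigmoid_scale(80, 80, 94) == 0.0
        assert sigmoid_scale(94, 80, 94) == 1.0
        assert sigmoid_scale(95, 80, 94) == 1.0

    def test_sigmoid_midpoint_is_half(self):
        assert sigmoid_scale(87, 80, 94) == pytest.approx(0.5)

    def test_sigmoid_strictly_increasing_between_bounds(self):
        xs = np.linspace(80, 94, 40)
        ys = [sigmoid_scale(x, 80, 94) for x in xs]
        assert all(b > a for a, b in zip(ys, ys[1:]))


class TestSignificantWindows:
    def test_all_zero_grid_yields_nothing(self):
        grid = all_window_pairs("A" * 60, "C" * 60)
        assert extract_significant_windows(grid, ThresholdConfig(80, 94)) == []

    def test_perfect_cell_yields_p_one(self):
        s = "".join(np.random.default_rng(2).choice(list("ACGT"), 50))
        grid = all_window_pairs(s, s)
        pairs = extract_significant_windows(grid, ThresholdConfig(80, 94), "sp1")
        assert len(pairs) == 1
        assert pairs[0].conservation_score == 1.0
        assert pairs[0].comparator_species == "sp1"


def _pair(i, j, p=0.5, species="s1"):
    return ScoredWindowPair(i, j, 45.0, 90.0, p, species)


class TestBundling:
    def test_overlapping_central_windows_merge(self):
        cands = bundle_windows({"s1": [_pair(10, 0), _pair(40, 30)]}, w=50)
        assert len(cands) == 1
        assert (cands[0].central_interval.start, cands[0].central_interval.end) == (10, 90)

    def test_disjoint_windows_stay_separate(self):
        cands = bundle_windows({"s1": [_pair(10, 0), _pair(70, 60)]}, w=50)
        assert len(cands) == 2

    def test_cross_species_windows_merge_into_one_cne(self):
        cands = bundle_windows(
            {"sA": [_pair(10, 5, 0.4, "sA")], "sB": [_pair(40, 80, 0.9, "sB")]}, w=50
        )
        assert len(cands) == 1
        cand = cands[0]
        assert (cand.central_interval.start, cand.central_interval.end) == (10, 90)
        assert set(cand.supports) == {"sA", "sB"}
        assert cand.supports["sA"][1] == 0.4
        assert cand.supports["sB"][1] == 0.9
        assert cand.ccs == pytest.approx(1 - 0.6 * 0.1)

    def test_support_is_hull_and_p_is_max(self):
        cands = bundle_windows(
            {"s1": [_pair(10, 100, 0.3), _pair(30, 220, 0.8)]}, w=50
        )
        (cand,) = cands
        iv, p = cand.supports["s1"]
        assert (iv.start, iv.end) == (100, 270)
        assert p == 0.8

    def test_idempotent_and_order_independent(self):
        pairs = [_pair(10, 0, 0.2), _pair(40, 30, 0.7), _pair(200, 150, 0.5)]
        a = bundle_windows({"s1": pairs}, w=50)
        b = bundle_windows({"s1": pairs[::-1]}, w=50)
        key = lambda c: (c.central_interval.start, c.central_interval.end, c.ccs)
        assert sorted(map(key, a)) == sorted(map(key, b))


class TestCCS:
    @pytest.mark.parametrize(
        "ps,expected",
        [([0.5], 0.5), ([0.5, 0.5], 0.75), ([1.0, 0.2, 0.0], 1.0), ([0.0, 0.0], 0.0)],
    )
    def test_known_values(self, ps, expected):
        assert combined_conservation_score(ps) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combined_conservation_score([])

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=6),
        st.floats(0.01, 1.0),
    )
    def test_adding_a_species_never_decreases_ccs(self, ps, extra):
        base = combined_conservation_score(ps)
        more = combined_conservation_score(ps + [extra])
        assert more >= base - 1e-12
        assert max(ps) - 1e-12 <= base <= min(1.0, sum(ps)) + 1e-12


def _cand(ccs, gene="g"):
    return CandidateCNE(
        gene_id=gene,
        central_interval=Interval(gene, 0, 50),
        supports={"s1": (Interval("s1", 0, 50), ccs)},
        ccs=ccs,
    )


class TestCalibration:
    def test_threshold_is_max_pseudo_ccs(self):
        thr = calibrate_ccs_threshold([_cand(0.2), _cand(0.4)])
        assert thr == 0.4
        assert _cand(0.41).ccs > thr
        assert not _cand(0.40).ccs > thr

    def test_no_pseudo_candidates_gives_zero(self):
        assert calibrate_ccs_threshold([]) == 0.0

    def test_calibrated_cohort_has_zero_pseudo_detections(self, small_discovery):
        result, *_ = small_discovery
        detected_pseudo = [
            c for c in result.pseudo_candidates if c.ccs > result.threshold
        ]
        assert detected_pseudo == []


class TestPermuteSequence:
    def test_homopolymer_invariant(self):
        assert permute_sequence("AAAA", 1) == "AAAA"

    def test_multiset_preserved(self):
        s = "ACGTACGTTTGCA"
        assert sorted(permute_sequence(s, 2)) == sorted(s)

    def test_deterministic(self):
        s = "ACGTACGTTTGCA"
        assert permute_sequence(s, 3) == permute_sequence(s, 3)


class TestCodingFilter:
    def test_hit_below_threshold_removed(self):
        cands = [_cand(0.9, "a"), _cand(0.9, "b")]
        true_hits = [HitRecord("a", "prot", 100, 1e-7), HitRecord("b", "prot", 50, 1e-3)]
        permuted = [HitRecord("p1", "prot", 40, 1e-5)]
        passed, removed, thr = coding_filter(cands, true_hits, permuted)
        assert thr == 1e-5
        assert [c.gene_id for c in removed] == ["a"]
        assert [c.gene_id for c in passed] == ["b"]

    def test_no_permuted_hits_removes_any_hit(self):
        cands = [_cand(0.9, "a"), _cand(0.9, "b")]
        true_hits = [HitRecord("a", "prot", 100, 10.0)]
        passed, removed, thr = coding_filter(cands, true_hits, [])
        assert thr == math.inf
        assert [c.gene_id for c in removed] == ["a"]
        assert [c.gene_id for c in passed] == ["b"]


class TestPseudoCnes:
    def _shared_segment_regions(self):
        rng = np.random.default_rng(4)
        shared = "".join(rng.choice(list("ACGT"), 70))
        r1 = "".join(rng.choice(list("ACGT"), 100)) + shared + "".join(
            rng.choice(list("ACGT"), 30)
        )
        r2 = "".join(rng.choice(list("ACGT"), 20)) + shared + "".join(
            rng.choice(list("ACGT"), 110)
        )
        return [(_region(r1, "gA"), {"sp1": _region(r2, "gB")})]

    def test_cutoff_one_empty(self):
        assert call_pseudo_cnes(self._shared_segment_regions(), ccs_cutoff=1.0) == []

    def test_cutoff_zero_keeps_all_candidates(self):
        out = call_pseudo_cnes(self._shared_segment_regions(), ccs_cutoff=0.0)
        assert len(out) >= 1
        assert all(c.pseudo for c in out)

    def test_count_monotone_in_cutoff(self):
        regions = self._shared_segment_regions()
        counts = [
            len(call_pseudo_cnes(regions, ccs_cutoff=c)) for c in (0.0, 0.528, 0.9, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)


def test_candidate_calls_find_planted_element(small_cohort, small_cohort_regions):
    central = small_cohort_regions["central"]["g001"]
    comps = {
        sp: small_cohort_regions[sp]["g001"]
        for sp in small_cohort_regions
        if sp != "central"
    }
    cands = call_candidates_for_gene(central, comps, ThresholdConfig(80, 94))
    truth = small_cohort.truth_region["central"]["g001"][0]
    best = max(
        cands,
        key=lambda c: min(c.central_interval.end, truth.end)
        - max(c.central_interval.start, truth.start),
    )
    overlap = min(best.central_interval.end, truth.end) - max(
        best.central_interval.start, truth.start
    )
    assert overlap >= 0.5 * len(truth)
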