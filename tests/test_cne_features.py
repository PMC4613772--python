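import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from cnescan.cne_features import (
    distance_to_translation_start,
    hypergeometric_enrichment,
    kmer_transcribed_overlap,
    matched_control_regions,
    position_conservation_test,
    rank_sum_test,
    sequence_composition,
    sliding_gc_profile,
)
from cnescan.io_formats import Interval, SequenceRecord, reverse_complement


class TestComposition:
    def test_gc_fraction(self):
        assert sequence_composition("ACGT").gc == 0.5

    def test_cpg_oe_hand_count(self):
        # CGCGCG: obs CG = 3, #C = #G = 3, len 6 -> 3*6/(3*3) = 2.0
        assert sequence_composition("CGCGCG").cpg_oe == pytest.approx(2.0)

    def test_cpg_oe_undefined_flagged_not_zero(self):
        assert sequence_composition("AAAA").cpg_oe is None

    def test_trinucleotide_counts(self):
        comp = sequence_composition("ATGATG")
        assert comp.trinucleotide_counts["ATG"] == 2
        assert comp.trinucleotide_counts["TGA"] == 1

    def test_n_excluded_from_denominators(self):
        assert sequence_composition("GCNN").gc == 1.0


class TestSlidingGC:
    def test_homopolymer_profile(self):
        prof = sliding_gc_profile("G" * 100)
        assert all(v == 1.0 for _, v in prof)

    def test_window_count(self):
        prof = sliding_gc_profile("A" * 100, window=50, step=10)
        assert len(prof) == 6  # floor((100-50)/10) + 1
        assert [o for o, _ in prof] == [0, 10, 20, 30, 40, 50]

    def test_reverse_complement_reverses_profile(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 120))
        fwd = [v for _, v in sliding_gc_profile(seq, 50, 10)]
        rev = [v for _, v in sliding_gc_profile(reverse_complement(seq), 50, 10)]
        assert fwd == rev[::-1]

    def test_short_sequence_warns_empty(self):
        with pytest.warns(UserWarning):
            assert sliding_gc_profile("ACGT", window=50) == []


class TestDistanceToTLS:
    def test_abutting_translation_start(self):
        assert distance_to_translation_start(Interval("g", 1950, 2000), 2000) == 0

    def test_far_end(self):
        assert distance_to_translation_start(Interval("g", 0, 50), 2000) == 1950

    def test_truncated_region(self):
        assert distance_to_translation_start(Interval("g", 900, 950), 1000) == 50

    def test_outside_region_rejected(self):
        with pytest.raises(ValueError):
            distance_to_translation_start(Interval("g", 900, 1050), 1000)


class TestPositionConservation:
    def test_perfect_monotone(self):
        rho, p = position_conservation_test([(1, 10), (2, 20), (3, 35), (4, 50)])
        assert rho == pytest.approx(1.0)

    def test_hand_ranked_example(self):
        rho, p = position_conservation_test([(1, 2), (2, 1), (3, 3)])
        assert rho == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            position_conservation_test([(1, 5), (2, 5), (3, 5)])

    def test_exact_small_sample_p_matches_enumeration(self):
        pairs = [(1, 2), (2, 1), (3, 3), (4, 5), (5, 4)]
        rho, p = position_conservation_test(pairs)
        # brute-force over all 5! rank permutations
        x = np.array([a for a, _ in pairs], float)
        y = np.array([b for _, b in pairs], float)
        obs = abs(sps.spearmanr(x, y).statistic)
        perms = itertools.permutations(y)
        count = sum(
            1
            for yy in perms
            if abs(sps.spearmanr(x, np.array(yy)).statistic) >= obs - 1e-12
        )
        assert p == pytest.approx(count / math.factorial(5))

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(123)
        ps = []
        for _ in range(200):
            pairs = list(zip(rng.random(50), rng.random(50)))
            ps.append(position_conservation_test(pairs)[1])
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestRankSum:
    def test_identical_samples_large_p(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = rank_sum_test(x, list(x))
        assert p >= 0.99

    def test_separated_samples_exact_p(self):
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / 20)  # 2 of C(6,3) splits as extreme

    def test_exact_matches_scipy_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n, m = rng.integers(2, 6), rng.integers(2, 6)
            x = rng.normal(size=n)
            y = rng.normal(size=m) + rng.normal()
            _, p = rank_sum_test(list(x), list(y))
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_exact_handles_ties_like_permutation_test(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [2.0, 4.0, 4.0]
        _, p = rank_sum_test(x, y)

        def stat(a, b):
            pooled = np.concatenate([a, b])
            r = sps.rankdata(pooled)
            return r[: len(a)].sum()

        ref = sps.permutation_test(
            (np.array(x), np.array(y)), stat,
            permutation_type="independent", alternative="two-sided", n_resamples=np.inf,
        )
        assert p == pytest.approx(float(ref.pvalue), abs=1e-9)

    def test_normal_approximation_close_to_exact(self):
        # At 12 < n+m <= 16 the tie/continuity-corrected normal approximation
        # tracks the exact enumeration to about a percent (worst mid-range p).
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(30):
            n = int(rng.integers(6, 9))
            m = 14 - n
            x = list(rng.normal(size=n))
            y = list(rng.normal(0.5, size=m))
            _, p_exact = rank_sum_test(x, y, exact_limit=16)
            _, p_approx = rank_sum_test(x, y, exact_limit=0)
            errs.append(abs(p_exact - p_approx))
        assert max(errs) < 0.02
        assert np.mean(errs) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestKmerOverlap:
    def test_verbatim_cne_fully_transcribed(self):
        cne = "ACGTACGTACGTACGTACGT"  # 20-mer
        tx = [SequenceRecord("t", "GGG" + cne + "TTT")]
        assert kmer_transcribed_overlap(cne, tx) == 100.0

    def test_reverse_strand_match_counts(self):
        cne = "ACGTACGTAAGTACGTACGT"
        tx = [SequenceRecord("t", reverse_complement(cne))]
        assert kmer_transcribed_overlap(cne, tx) == 100.0

    def test_half_matching_21mer(self):
        cne = "A" * 21
        tx = [SequenceRecord("t", "A" * 20)]  # only the first 20-mer matches
        # both 20-mers of the poly-A CNE are the same k-mer -> 100 %
        assert kmer_transcribed_overlap(cne, tx) == 100.0
        rng = np.random.default_rng(1)
        cne2 = "".join(rng.choice(list("ACGT"), 21))
        tx2 = [SequenceRecord("t", cne2[:20])]
        assert kmer_transcribed_overlap(cne2, tx2) == 50.0

    def test_no_transcripts_zero(self):
        assert kmer_transcribed_overlap("ACGT" * 10, []) == 0.0

    def test_short_cne_flagged_undefined(self):
        with pytest.warns(UserWarning):
            assert kmer_transcribed_overlap("ACGT", []) is None


class TestHypergeometric:
    def test_zero_observed_is_one(self):
        assert hypergeometric_enrichment(100, 30, 10, 0) == 1.0

    def test_hand_computed_value(self):
        # P(both draws are successes) = C(5,2)/C(10,2) = 10/45
        assert hypergeometric_enrichment(10, 5, 2, 2) == pytest.approx(10 / 45)

    def test_matches_enumeration_small_populations(self):
        for N in (5, 8, 12):
            for K in (2, N // 2, N - 1):
                for n in (1, 3, min(5, N)):
                    population = [1] * K + [0] * (N - K)
                    draws = list(itertools.combinations(range(N), n))
                    for k in range(0, n + 1):
                        if k > K:
                            continue
                        frac = sum(
                            1 for d in draws if sum(population[i] for i in d) >= k
                        ) / len(draws)
                        assert hypergeometric_enrichment(N, K, n, k) == pytest.approx(
                            frac
                        )

    def test_inconsistent_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(10, 5, 12, 2)

    def test_deep_conservation_scale_enrichment(self):
        # 20 of 20 sampled vs ~70 % background of 322: well below 6.5e-4
        p = hypergeometric_enrichment(322, 225, 20, 20)
        assert 0 < p <= 6.5e-4


class TestMatchedControls:
    def _setup(self):
        regions = {f"g{i}": 2000 for i in range(20)}
        regions["short"] = 100
        cnes = [("g0", Interval("g0", 1800, 1890)), ("g1", Interval("g1", 100, 250))]
        return cnes, regions

    def test_geometry_matched(self):
        cnes, regions = self._setup()
        sets = matched_control_regions(cnes, regions, n_sets=10, seed=1)
        assert len(sets) == 10
        for s in sets:
            assert len(s) == len(cnes)
            for (gene, iv), (host, civ) in zip(cnes, s):
                assert host != gene
                assert len(civ) == len(iv)
                assert distance_to_translation_start(
                    civ, regions[host]
                ) == distance_to_translation_start(iv, regions[gene])

    def test_deterministic(self):
        cnes, regions = self._setup()
        a = matched_control_regions(cnes, regions, n_sets=3, seed=9)
        b = matched_control_regions(cnes, regions, n_sets=3, seed=9)
        assert [
            [(h, i.start, i.end) for h, i in s] for s in a
        ] == [[(h, i.start, i.end) for h, i in s] for s in b]

    def test_infeasible_cne_skipped_with_warning(self):
        regions = {"g0": 2000, "g1": 100}
        cnes = [("g0", Interval("g0", 0, 90))]  # distance 1910: no host fits
        with pytest.warns(UserWarning, match="no gene long enough"):
            sets = matched_control_regions(cnes, regions, n_sets=2, seed=0)
        assert all(s == [] for s in sets)
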