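import numpy as np
import pytest

from cnescan.io_formats import reverse_complement
from cnescan.synthetic_data import (
    EvolutionConfig,
    PlantedElement,
    SpeciesParams,
    evolve_sequence,
    generate_ortholog_cohort,
    generate_pseudo_ortholog_pairs,
    generate_transcriptome,
    plant_hairpin_alignment,
)
from cnescan.cne_features import kmer_transcribed_overlap


class TestEvolveSequence:
    def test_zero_rates_identity(self):
        anc = "ACGT" * 100
        assert evolve_sequence(anc, 0.0, 0.0, seed=1) == anc

    def test_deterministic_given_seed(self):
        anc = "ACGT" * 200
        a = evolve_sequence(anc, 0.2, 0.02, seed=7)
        b = evolve_sequence(anc, 0.2, 0.02, seed=7)
        assert a == b

    def test_substitution_rate_matches_hamming_distance(self):
        rng = np.random.default_rng(0)
        anc = "".join(rng.choice(list("ACGT"), 10_000))
        child = evolve_sequence(anc, 0.1, 0.0, seed=3)
        assert len(child) == len(anc)
        ham = sum(1 for a, b in zip(anc, child) if a != b) / len(anc)
        assert 0.08 <= ham <= 0.12  # binomial: P(outside) < 1e-2

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            evolve_sequence("ACGT", 1.5, 0.0)


class TestCohortGeneration:
    def test_truth_bookkeeping(self):
        config = EvolutionConfig(ancestor_length=400, n_genes=10, seed=4)
        cohort = generate_ortholog_cohort(
            config, [PlantedElement(distance_from_tls=100, length=90)]
        )
        # one element per gene in every species (central + 4 comparators)
        assert sum(len(v) for v in cohort.truth.values()) == 10 * 5
        for sp, by_gene in cohort.truth_region.items():
            for gene, ivs in by_gene.items():
                for iv in ivs:
                    assert 0 <= iv.start < iv.end <= 400
                    assert iv.end == 400 - 100  # distance from TLS respected

    def test_restricted_carrier_set(self):
        config = EvolutionConfig(ancestor_length=400, n_genes=3, seed=4)
        cohort = generate_ortholog_cohort(
            config,
            [
                PlantedElement(
                    distance_from_tls=50, length=90,
                    present_in=frozenset({"central"}),
                )
            ],
        )
        assert len(cohort.truth["central"]) == 3
        assert all(len(cohort.truth[sp.name]) == 0 for sp in config.species)

    def test_identical_element_reaches_max_window_score(self):
        from cnescan.window_align import all_window_pairs

        config = EvolutionConfig(
            ancestor_length=300, n_genes=1, seed=9,
            species=(SpeciesParams("comp1", 0.4, 0.0),),
        )
        cohort = generate_ortholog_cohort(
            config,
            [PlantedElement(distance_from_tls=60, length=90, element_substitution_rate=0.0)],
        )
        grid = all_window_pairs(
            cohort.regions["central"]["g000"], cohort.regions["comp1"]["g000"]
        ).scores
        assert grid.max() == 50.0

    def test_overlapping_elements_rejected(self):
        config = EvolutionConfig(ancestor_length=400, n_genes=1, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            generate_ortholog_cohort(
                config,
                [
                    PlantedElement(distance_from_tls=50, length=90),
                    PlantedElement(distance_from_tls=100, length=90),
                ],
            )

    def test_planted_repeats_annotated(self):
        config = EvolutionConfig(ancestor_length=600, n_genes=2, seed=5)
        cohort = generate_ortholog_cohort(config, repeats_per_gene=1)
        for sp in cohort.genomes:
            assert len(cohort.repeats[sp]) == 2
            for iv in cohort.repeats[sp]:
                region = cohort.regions[sp][iv.seq_id.split(".")[1]]
                assert region[iv.start : iv.end].startswith("ACGGT")

    def test_write_roundtrips_through_io(self, tmp_path):
        from cnescan.io_formats import read_bed, read_fasta, read_gff_genes

        config = EvolutionConfig(ancestor_length=300, n_genes=2, seed=6)
        cohort = generate_ortholog_cohort(
            config, [PlantedElement(distance_from_tls=40, length=90)]
        )
        cohort.write(tmp_path)
        recs = read_fasta(tmp_path / "central.genome.fa")
        assert len(recs) == 2
        genes = read_gff_genes(tmp_path / "central.genes.gff3")
        assert {g.gene_id for g in genes} == {"g000", "g001"}
        assert all(g.translation_start == 300 for g in genes)
        truth = read_bed(tmp_path / "central.truth.bed")
        assert len(truth) == 2


class TestPseudoPairs:
    def test_two_genes_single_swap(self):
        config = EvolutionConfig(ancestor_length=200, n_genes=2, seed=1)
        cohort = generate_ortholog_cohort(config)
        assert generate_pseudo_ortholog_pairs(cohort, seed=0) == [
            ("g000", "g001"),
            ("g001", "g000"),
        ]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_derangement_property(self, seed):
        config = EvolutionConfig(ancestor_length=200, n_genes=9, seed=2)
        cohort = generate_ortholog_cohort(config)
        pairs = generate_pseudo_ortholog_pairs(cohort, seed=seed)
        assert len(pairs) == 9
        assert all(a != b for a, b in pairs)
        assert sorted(b for _, b in pairs) == sorted(a for a, _ in pairs)

    def test_deterministic(self):
        config = EvolutionConfig(ancestor_length=200, n_genes=6, seed=2)
        cohort = generate_ortholog_cohort(config)
        assert generate_pseudo_ortholog_pairs(cohort, 5) == generate_pseudo_ortholog_pairs(
            cohort, 5
        )

    def test_single_gene_rejected(self):
        config = EvolutionConfig(ancestor_length=200, n_genes=1, seed=2)
        cohort = generate_ortholog_cohort(config)
        with pytest.raises(ValueError):
            generate_pseudo_ortholog_pairs(cohort)


class TestHairpins:
    def test_zero_loop_rate_identical_rows(self):
        block = plant_hairpin_alignment(4, 12, 4, loop_substitution_rate=0.0, seed=0)
        seqs = {seq for _, seq in block.rows}
        assert len(seqs) == 1

    def test_stems_self_reverse_complementary(self):
        stem = 12
        block = plant_hairpin_alignment(5, stem, 5, loop_substitution_rate=0.5, seed=1)
        for _, seq in block.rows:
            assert seq[-stem:] == reverse_complement(seq[:stem])

    def test_minimum_loop_enforced(self):
        with pytest.raises(ValueError):
            plant_hairpin_alignment(3, 12, 2)


class TestTranscriptome:
    def _cohort(self):
        config = EvolutionConfig(ancestor_length=300, n_genes=3, seed=8)
        return generate_ortholog_cohort(
            config, [PlantedElement(distance_from_tls=60, length=90)]
        )

    def test_full_transcription_gives_full_overlap(self):
        cohort = self._cohort()
        tx = generate_transcriptome(cohort, 1.0)
        elem = cohort.regions["central"]["g000"][150:240]
        assert kmer_transcribed_overlap(elem, tx) == 100.0

    def test_no_transcription_gives_zero_overlap(self):
        cohort = self._cohort()
        tx = generate_transcriptome(cohort, 0.0)
        elem = cohort.regions["central"]["g000"][150:240]
        assert kmer_transcribed_overlap(elem, tx) == 0.0

    def test_partial_transcription_counts_prefix_kmers(self):
        cohort = self._cohort()
        tx = generate_transcriptome(cohort, 1 / 3)
        elem = cohort.regions["central"]["g000"][150:240]
        # ceil(90/3) = 30 transcribed bases -> 30 - 20 + 1 = 11 of 71 k-mers
        assert kmer_transcribed_overlap(elem, tx) == pytest.approx(100 * 11 / 71)
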