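import numpy as np
import pytest

from cnescan.synthetic_data import (
    EvolutionConfig,
    PlantedElement,
    generate_ortholog_cohort,
    generate_pseudo_ortholog_pairs,
)
from cnescan.upstream_extract import extract_cohort_regions


def dp_align_score(a, b, match=1.0, mismatch=0.0, gap=-0.5):
    """Independent quadratic-DP oracle for the global window alignment score.

    Row-vectorized Needleman-Wunsch; N (or any non-ACGT symbol) mismatches
    everything, including another N.
    """
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    ca = np.array([code.get(c, 4) for c in a])
    cb = np.array([code.get(c, 5) for c in b])
    prev = gap * np.arange(len(b) + 1, dtype=float)
    for i in range(1, len(a) + 1):
        sub = np.where(cb == ca[i - 1], match, mismatch)
        cur = np.empty_like(prev)
        cur[0] = gap * i
        diag = prev[:-1] + sub
        up = prev[1:] + gap
        best = np.maximum(diag, up)
        for j in range(1, len(b) + 1):
            cur[j] = max(best[j - 1], cur[j - 1] + gap)
        prev = cur
    return prev[-1]


@pytest.fixture(scope="session")
def small_cohort():
    """8 genes x (central + 4 comparators), 600 bp regions, one 90 bp element."""
    config = EvolutionConfig(ancestor_length=600, n_genes=8, seed=11)
    cohort = generate_ortholog_cohort(
        config,
        [PlantedElement(distance_from_tls=150, length=90, element_substitution_rate=0.02)],
    )
    return cohort


@pytest.fixture(scope="session")
def small_cohort_regions(small_cohort):
    regions = {}
    for sp in small_cohort.genomes:
        regs, _ = extract_cohort_regions(
            small_cohort.genes[sp],
            small_cohort.genomes[sp],
            span=small_cohort.config.ancestor_length,
            species=sp,
        )
        regions[sp] = regs
    return regions


@pytest.fixture(scope="session")
def small_discovery(small_cohort, small_cohort_regions):
    from cnescan.pipeline import RunConfig, run_discovery

    central = small_cohort_regions["central"]
    comps = {
        sp: regs for sp, regs in small_cohort_regions.items() if sp != "central"
    }
    omaps = {sp: {g: g for g in central} for sp in comps}
    pseudo = generate_pseudo_ortholog_pairs(small_cohort, seed=3)
    result = run_discovery(
        central, comps, omaps, pseudo,
        RunConfig(span=small_cohort.config.ancestor_length, seed=11),
    )
    return result, small_cohort, central, comps, omaps
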