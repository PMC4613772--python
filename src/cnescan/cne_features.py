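"""Composition, positional and transcribed-overlap statistics for CNE sets.

These are the comparison statistics run between true CNEs and the
pseudo-CNE control set: GC content, CpG observed/expected, lengths,
distance to the translation start, conservation of that distance across
species, exact-match 20-mer overlap with a transcriptome, hypergeometric
enrichment of transcribed overlap in the most deeply conserved subset, and
geometry-matched control region sampling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import Interval, SequenceRecord, reverse_complement
from .upstream_extract import UpstreamRegion

__all__ = [
    "sequence_composition",
    "sliding_gc_profile",
    "distance_to_translation_start",
    "position_conservation_test",
    "rank_sum_test",
    "kmer_transcribed_overlap",
    "hypergeometric_enrichment",
    "matched_control_regions",
]


@dataclass
class Composition:
    gc: float
    cpg_oe: Optional[float]  # None when #C * #G == 0 (undefined, not zero)
    trinucleotide_counts: dict[str, int]


def sequence_composition(seq: str) -> Composition:
    """GC fraction, CpG observed/expected and trinucleotide counts.

    Positions with N are excluded from all denominators. CpG O/E uses the
    standard estimator obs(CG) * len / (#C * #G) with len the number of
    non-N positions; it is undefined (None) when the sequence has no C or
    no G.
    """
    counts = {b: seq.count(b) for b in "ACGT"}
    n_valid = sum(counts.values())
    gc = (counts["C"] + counts["G"]) / n_valid if n_valid else float("nan")
    obs_cpg = sum(
        1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"
    )
    denom = counts["C"] * counts["G"]
    cpg_oe = (obs_cpg * n_valid / denom) if denom else None
    tri: dict[str, int] = {}
    for i in range(len(seq) - 2):
        t = seq[i : i + 3]
        if "N" not in t:
            tri[t] = tri.get(t, 0) + 1
    return Composition(gc=gc, cpg_oe=cpg_oe, trinucleotide_counts=tri)


def sliding_gc_profile(
    seq: str, window: int = 50, step: int = 10
) -> list[tuple[int, float]]:
    """GC fraction in sliding windows (offsets 0, step, ... while they fit)."""
    if len(seq) < window:
        warnings.warn("sequence shorter than GC window; empty profile", stacklevel=2)
        return []
    out = []
    for off in range(0, len(seq) - window + 1, step):
        win = seq[off : off + window]
        counts = {b: win.count(b) for b in "ACGT"}
        n_valid = sum(counts.values())
        gc = (counts["C"] + counts["G"]) / n_valid if n_valid else float("nan")
        out.append((off, gc))
    return out


def distance_to_translation_start(cne: Interval, region: UpstreamRegion | int) -> int:
    """Distance from the CNE's 3' end to the translation start (0 = abutting)."""
    region_length = region if isinstance(region, int) else len(region.sequence)
    if not (0 <= cne.start and cne.end <= region_length):
        raise ValueError("CNE interval outside the upstream region")
    return region_length - cne.end


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for Spearman's rho (n <= 10).

    Only the cross term sum(rx_i * ry_perm(i)) varies across permutations,
    so the null distribution is enumerated on dot products alone.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    obs = abs(float(rx @ ry) - n * rx.mean() * ry.mean())
    count = 0
    total = 0
    chunk: list[tuple[int, ...]] = []

    def flush(chunk_perms: list[tuple[int, ...]]) -> int:
        idx = np.asarray(chunk_perms, dtype=np.intp)
        dots = (ry[idx] * rx).sum(axis=1)
        return int(np.sum(np.abs(dots - n * rx.mean() * ry.mean()) >= obs - 1e-9))

    for perm in permutations(range(n)):
        chunk.append(perm)
        total += 1
        if len(chunk) == 100_000:
            count += flush(chunk)
            chunk = []
    if chunk:
        count += flush(chunk)
    return count / total


def position_conservation_test(
    pairs: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Spearman rank correlation of central vs comparator TLS distances.

    Returns (rho, two-sided p). Uses the t approximation, exact permutation
    enumeration for n <= 10. A margin with zero variance is an error.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.asarray([a for a, _ in pairs], dtype=float)
    y = np.asarray([b for _, b in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a margin")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if len(pairs) <= 10:
        return rho, float(_spearman_exact_p(x, y))
    return rho, float(p)


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """Mann-Whitney U of x with midrank ties."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = stats.rankdata(pooled)
    n = len(x)
    return float(ranks[:n].sum() - n * (n + 1) / 2)


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 12
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Exact enumeration over all C(n+m, n) group assignments (midrank ties
    handled) when n + m <= exact_limit; otherwise the normal approximation
    with tie and continuity correction. The two-sided exact p doubles the
    smaller tail (capped at 1), the convention of R's wilcox.test. Returns
    (U, p).
    """
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if n + m <= exact_limit:
        pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
        ranks = stats.rankdata(pooled)
        lower = 0
        upper = 0
        total = 0
        offset = n * (n + 1) / 2
        for idx in combinations(range(n + m), n):
            u = ranks[list(idx)].sum() - offset
            if u <= u_obs + 1e-12:
                lower += 1
            if u >= u_obs - 1e-12:
                upper += 1
            total += 1
        return u_obs, min(1.0, 2 * min(lower, upper) / total)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", use_continuity=True,
                             method="asymptotic")
    return u_obs, float(res.pvalue)


def kmer_transcribed_overlap(
    cne_seq: str,
    transcripts: Iterable[SequenceRecord | str],
    k: int = 20,
    max_mismatches: int = 0,
) -> Optional[float]:
    """Percent of the CNE's k-mers exactly matching any transcript (either strand).

    Returns None (flagged undefined) for CNEs shorter than k. A mismatch
    budget of 1 is supported but off by default.
    """
    if len(cne_seq) < k:
        warnings.warn("CNE shorter than k; overlap undefined", stacklevel=2)
        return None
    kmer_set: set[str] = set()
    for t in transcripts:
        seq = t.sequence if isinstance(t, SequenceRecord) else t
        for s in (seq, reverse_complement(seq)):
            for i in range(len(s) - k + 1):
                kmer_set.add(s[i : i + k])
    total = len(cne_seq) - k + 1
    if max_mismatches == 0:
        hits = sum(1 for i in range(total) if cne_seq[i : i + k] in kmer_set)
    elif max_mismatches == 1:
        hits = 0
        for i in range(total):
            kmer = cne_seq[i : i + k]
            if kmer in kmer_set or any(
                kmer[:p] + b + kmer[p + 1 :] in kmer_set
                for p in range(k)
                for b in "ACGT"
                if b != kmer[p]
            ):
                hits += 1
    else:
        raise ValueError("mismatch budget must be 0 or 1")
    return 100.0 * hits / total


def hypergeometric_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    Integer arithmetic throughout (math.comb), so the tail is exact even for
    extreme probabilities.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError("inconsistent hypergeometric arguments")
    if k == 0:
        return 1.0
    total = math.comb(N, n)
    tail = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(n, K) + 1)
    )
    return tail / total


def matched_control_regions(
    cnes: Sequence[tuple[str, Interval]],
    regions: Mapping[str, UpstreamRegion | int],
    n_sets: int = 10,
    seed: int = 0,
) -> list[list[tuple[str, Interval]]]:
    """Geometry-matched control intervals upstream of randomly chosen other genes.

    For each CNE (gene, interval in region coordinates) and each of n_sets,
    draw a different gene uniformly among those whose region is long enough,
    and place an interval of identical length at identical distance from the
    translation start. CNEs with no feasible host gene are skipped with a
    warning. Deterministic by seed.
    """
    rng = np.random.default_rng(seed)
    lengths = {
        g: (r if isinstance(r, int) else len(r.sequence)) for g, r in regions.items()
    }
    sets: list[list[tuple[str, Interval]]] = [[] for _ in range(n_sets)]
    for gene_id, iv in cnes:
        length = len(iv)
        dist = distance_to_translation_start(iv, lengths[gene_id])
        hosts = sorted(
            g for g, L in lengths.items() if g != gene_id and L >= dist + length
        )
        if not hosts:
            warnings.warn(
                f"no gene long enough to host a control for {gene_id}:{iv.start}-{iv.end}",
                stacklevel=2,
            )
            continue
        for s in range(n_sets):
            host = hosts[int(rng.integers(0, len(hosts)))]
            L = lengths[host]
            sets[s].append(
                (host, Interval(host, L - dist - length, L - dist, name=f"ctrl.{gene_id}"))
            )
    return sets
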