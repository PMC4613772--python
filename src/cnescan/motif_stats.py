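"""PWM redundancy reduction and over/under-representation statistics.

Position weight matrices are compared by Hellinger distance (best ungapped
offset, reverse complement considered), clustered agglomeratively (complete
linkage) and each cluster is represented by its median-entropy member. A
motif is called over-represented in the CNE set when its binomial upper-tail
p-value there is lower than in every one of the matched control sets, and
under-represented when it is higher than in all of them.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "PWM",
    "OverrepCall",
    "read_jaspar",
    "hellinger_distance",
    "cluster_pwms",
    "pwm_summaries",
    "scan_and_count",
    "overrepresentation_call",
]

_BASE_ORDER = "ACGT"
MIN_OVERLAP = 5  # columns; capped at the shorter matrix length


@dataclass
class PWM:
    id: str
    matrix: np.ndarray  # (L, 4) probabilities, columns ordered A C G T

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError("PWM matrix must be L x 4 with L >= 1")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.id}: columns must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(self.id, self.matrix[::-1, ::-1].copy())


@dataclass
class OverrepCall:
    pwm_id: str
    p_true: float
    p_controls: list[float]
    verdict: str  # over | under | neither
    flagged: bool = False


def read_jaspar(path: str | Path) -> list[PWM]:
    """Read JASPAR-style matrices (counts or probabilities; normalized on read)."""
    pwms: list[PWM] = []
    current_id: Optional[str] = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        lines = list(fh) + [">"]
    for line in lines:
        line = line.strip()
        if line.startswith(">"):
            if current_id is not None and rows:
                if set(rows) != set("ACGT"):
                    raise ValueError(f"matrix {current_id}: need A, C, G and T rows")
                mat = np.array([rows[b] for b in _BASE_ORDER], dtype=float).T
                mat = mat / mat.sum(axis=1, keepdims=True)
                pwms.append(PWM(current_id, mat))
            current_id = line[1:].split()[0] if len(line) > 1 else None
            rows = {}
        elif line:
            m = re.match(r"^([ACGT])\s*\[?\s*([-\d.eE+\s]+?)\]?$", line)
            if not m:
                raise ValueError(f"unparseable matrix line: {line!r}")
            rows[m.group(1)] = [float(x) for x in m.group(2).split()]
    return pwms


def _column_hellinger(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    return np.sqrt(0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum(axis=1))


def _best_offset_distance(a: np.ndarray, b: np.ndarray) -> float:
    la, lb = a.shape[0], b.shape[0]
    min_overlap = min(la, lb, MIN_OVERLAP)
    best = math.inf
    for off in range(-(lb - min_overlap), la - min_overlap + 1):
        s_a = max(0, off)
        e_a = min(la, off + lb)
        if e_a - s_a < min_overlap:
            continue
        s_b = s_a - off
        cols = _column_hellinger(a[s_a:e_a], b[s_b : s_b + (e_a - s_a)])
        best = min(best, float(cols.sum()))
    return best


def hellinger_distance(a: PWM, b: PWM) -> float:
    """Summed per-column Hellinger distance at the best ungapped offset.

    All offsets with at least min(L_a, L_b, 5) overlapping columns are
    considered, for b in both orientations; the minimum summed distance wins.
    Symmetric, zero for identical matrices. The distance is extensive in the
    overlap (a per-column distance is at most 1), which is what makes the
    published clustering threshold of 1.5 meaningful.
    """
    return min(
        _best_offset_distance(a.matrix, b.matrix),
        _best_offset_distance(a.matrix, b.reverse_complement().matrix),
    )


def pwm_summaries(pwm: PWM) -> tuple[float, float]:
    """(total entropy in bits, information-weighted GC content).

    GC weight averages each column's G+C probability with weight
    (2 - column entropy); a matrix whose strong positions are G/C scores
    high even if weak positions are AT-rich. With zero total information the
    unweighted mean is returned.
    """
    p = np.clip(pwm.matrix, 1e-12, 1.0)
    col_entropy = -(pwm.matrix * np.log2(p)).sum(axis=1)
    entropy = float(col_entropy.sum())
    gc_cols = pwm.matrix[:, 1] + pwm.matrix[:, 2]
    weights = 2.0 - col_entropy
    total = float(weights.sum())
    if total <= 0:
        return entropy, float(gc_cols.mean())
    return entropy, float((gc_cols * weights).sum() / total)


def cluster_pwms(
    pwms: Sequence[PWM], threshold: float = 1.5
) -> tuple[list[list[PWM]], list[PWM]]:
    """Complete-linkage clustering at the distance threshold.

    Returns (clusters, representatives); the representative of a cluster is
    the member whose total entropy is the (lower) median, ties broken by id.
    Input order does not matter: matrices are sorted by id first.
    """
    if not pwms:
        raise ValueError("need at least one PWM")
    pwms = sorted(pwms, key=lambda p: p.id)
    if len(pwms) == 1:
        return [list(pwms)], [pwms[0]]
    n = len(pwms)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = hellinger_distance(pwms[i], pwms[j])
    if threshold <= 0:
        labels = np.arange(n)
    else:
        Z = hierarchy.linkage(squareform(dm, checks=False), method="complete")
        labels = hierarchy.fcluster(Z, t=threshold, criterion="distance")
    clusters: dict[int, list[PWM]] = {}
    for lab, p in zip(labels, pwms):
        clusters.setdefault(int(lab), []).append(p)
    cluster_list = [clusters[k] for k in sorted(clusters)]
    reps = []
    for members in cluster_list:
        ranked = sorted(members, key=lambda p: (pwm_summaries(p)[0], p.id))
        reps.append(ranked[(len(ranked) - 1) // 2])  # lower median
    return cluster_list, reps


_SCAN_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0, 4])


def scan_and_count(
    pwm: PWM,
    sequences: Iterable[str],
    score_fraction: float = 0.8,
) -> tuple[int, int]:
    """Count motif hits on both strands of a sequence set.

    A position is a hit when its log-odds score against a uniform background
    reaches score_fraction of the maximum attainable score. Positions whose
    window contains N never score as hits but are still counted as scanned.
    Returns (hits, scanned positions).
    """
    L = len(pwm)
    logodds = np.log2(np.clip(pwm.matrix, 1e-9, 1.0) / 0.25)
    logodds = np.vstack([logodds.T, np.full((1, L), -1e9)])  # row 4: N
    max_score = float(np.log2(np.clip(pwm.matrix.max(axis=1), 1e-9, 1.0) / 0.25).sum())
    cutoff = score_fraction * max_score
    hits = 0
    positions = 0
    for seq in sequences:
        codes = np.fromiter(
            (_SCAN_CODE.get(c, 4) for c in seq.upper()), dtype=np.intp, count=len(seq)
        )
        if len(codes) < L:
            continue
        n_pos = len(codes) - L + 1
        for strand_codes in (codes, _COMPLEMENT_IDX[codes[::-1]]):
            window_idx = np.lib.stride_tricks.sliding_window_view(strand_codes, L)
            scores = logodds[window_idx, np.arange(L)].sum(axis=1)
            hits += int(np.sum(scores >= cutoff - 1e-12))
            positions += n_pos
    return hits, positions


def _binom_upper_tail(hits: int, n: int, p: float) -> float:
    if n == 0:
        return 1.0
    if hits <= 0:
        return 1.0
    return float(stats.binom.sf(hits - 1, n, p))


def overrepresentation_call(
    pwm: PWM,
    true_set: Sequence[str],
    control_sets: Sequence[Sequence[str]],
    score_fraction: float = 0.8,
) -> OverrepCall:
    """Binomial over/under-representation of a motif vs matched control sets.

    The per-position hit probability is estimated from the pooled control
    sets; the verdict is "over" only when the true set's upper-tail binomial
    p is strictly below every control set's, "under" when strictly above all
    of them.
    """
    true_hits, true_pos = scan_and_count(pwm, true_set, score_fraction)
    control_counts = [scan_and_count(pwm, cs, score_fraction) for cs in control_sets]
    pooled_hits = sum(h for h, _ in control_counts)
    pooled_pos = sum(n for _, n in control_counts)
    if true_pos == 0 or pooled_pos == 0:
        return OverrepCall(pwm.id, 1.0, [1.0] * len(control_sets), "neither", flagged=True)
    p_hat = pooled_hits / pooled_pos
    p_true = _binom_upper_tail(true_hits, true_pos, p_hat)
    p_controls = [_binom_upper_tail(h, npos, p_hat) for h, npos in control_counts]
    if p_controls and p_true < min(p_controls):
        verdict = "over"
    elif p_controls and p_true > max(p_controls):
        verdict = "under"
    else:
        verdict = "neither"
    return OverrepCall(pwm.id, p_true, p_controls, verdict)
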