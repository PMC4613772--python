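"""Optimal global alignment scores for all pairs of fixed-length windows.

The scan scores every length-``w`` window of one upstream region against every
length-``w`` window of the other under the scheme +1 per match, 0 per
mismatch, -0.5 per gap symbol; N mismatches everything, including another N.

For this particular scheme the optimal end-to-end alignment score of two
sequences a, b satisfies

    score(a, b) = (len(a) + len(b)) / 2 - levenshtein(a, b)

because an alignment with x substitutions and g gap symbols in total has
exactly (len(a)+len(b)-g)/2 aligned pairs, of which the non-matching ones are
the x substitutions; maximizing matches - g/2 is therefore equivalent to
minimizing the unit-cost edit distance x + g. The all-pairs grid exploits
this with a Myers bit-parallel edit-distance kernel (windows up to 64 bp),
which is exactly equal to the direct dynamic program pinned by
:func:`window_pair_score`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit, uint64

__all__ = [
    "ScoringScheme",
    "WindowScoreGrid",
    "window_pair_score",
    "all_window_pairs",
    "count_window_pairs",
    "encode_sequence",
]

# base codes: A C G T = 0..3; N in the first sequence = 4, in the second = 5,
# so an N never matches anything (not even another N).
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 1.0
    mismatch: float = 0.0
    gap: float = -0.5  # per gap symbol
    window_length: int = 50

    @property
    def is_edit_equivalent(self) -> bool:
        """True when score = (|a|+|b|)/2 - levenshtein holds (the defaults)."""
        return self.match == 1.0 and self.mismatch == 0.0 and self.gap == -0.5


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class WindowScoreGrid:
    scores: np.ndarray  # shape (m-w+1, n-w+1)
    source_ids: tuple[str, str]
    scheme: ScoringScheme

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape


def encode_sequence(seq: str, n_code: int = 4) -> np.ndarray:
    return np.fromiter(
        (_CODE.get(c, n_code) for c in seq), dtype=np.uint8, count=len(seq)
    )


def window_pair_score(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Optimal global alignment score of two windows (direct dynamic program).

    This is the defining computation: the grid kernel must agree with it
    exactly. General lengths are accepted for testing; N scores as mismatch
    against anything.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    ca = encode_sequence(a, n_code=4)
    cb = encode_sequence(b, n_code=5)
    return float(_dp_score(ca, cb, scheme.match, scheme.mismatch, scheme.gap))


@njit(cache=True)
def _dp_score(ca, cb, match, mismatch, gap):  # pragma: no cover - jitted
    m, n = ca.size, cb.size
    prev = np.empty(n + 1, np.float64)
    cur = np.empty(n + 1, np.float64)
    for j in range(n + 1):
        prev[j] = gap * j
    for i in range(1, m + 1):
        cur[0] = gap * i
        ai = ca[i - 1]
        for j in range(1, n + 1):
            s = match if ai == cb[j - 1] else mismatch
            best = prev[j - 1] + s
            if prev[j] + gap > best:
                best = prev[j] + gap
            if cur[j - 1] + gap > best:
                best = cur[j - 1] + gap
            cur[j] = best
        prev, cur = cur, prev
    return prev[n]


@njit(cache=True)
def _myers_grid(c1, c2, w):  # pragma: no cover - jitted
    n1 = c1.size - w + 1
    n2 = c2.size - w + 1
    out = np.empty((n1, n2), np.float64)
    full = (uint64(1) << uint64(w)) - uint64(1)
    top = uint64(1) << uint64(w - 1)
    for i in range(n1):
        peq = np.zeros(8, np.uint64)
        for p in range(w):
            peq[c1[i + p]] |= uint64(1) << uint64(p)
        for j in range(n2):
            VP = full
            VN = uint64(0)
            score = w
            for q in range(w):
                Eq = peq[c2[j + q]]
                Xv = Eq | VN
                Xh = (((Eq & VP) + VP) ^ VP) | Eq
                HP = VN | ~(Xh | VP)
                HN = VP & Xh
                if HP & top:
                    score += 1
                elif HN & top:
                    score -= 1
                HP = (HP << uint64(1)) | uint64(1)
                HN = HN << uint64(1)
                VP = HN | ~(Xv | HP)
                VN = HP & Xv
            out[i, j] = w - score
    return out


@njit(cache=True)
def _dp_grid(c1, c2, w, match, mismatch, gap):  # pragma: no cover - jitted
    n1 = c1.size - w + 1
    n2 = c2.size - w + 1
    out = np.empty((n1, n2), np.float64)
    prev = np.empty(w + 1, np.float64)
    cur = np.empty(w + 1, np.float64)
    for i in range(n1):
        for j in range(n2):
            for q in range(w + 1):
                prev[q] = gap * q
            for p in range(1, w + 1):
                cur[0] = gap * p
                ap = c1[i + p - 1]
                for q in range(1, w + 1):
                    s = match if ap == c2[j + q - 1] else mismatch
                    best = prev[q - 1] + s
                    if prev[q] + gap > best:
                        best = prev[q] + gap
                    if cur[q - 1] + gap > best:
                        best = cur[q - 1] + gap
                    cur[q] = best
                for q in range(w + 1):
                    prev[q] = cur[q]
            out[i, j] = prev[w]
    return out


def all_window_pairs(
    s1: str, s2: str, scheme: ScoringScheme = DEFAULT_SCHEME,
    ids: tuple[str, str] = ("s1", "s2"),
) -> WindowScoreGrid:
    """Score grid for every pair of w-length windows between two sequences.

    grid[i, j] == window_pair_score(s1[i:i+w], s2[j:j+w], scheme), exactly.
    """
    w = scheme.window_length
    if len(s1) < w or len(s2) < w:
        raise ValueError(f"sequences must be at least window length ({w}) long")
    c1 = encode_sequence(s1, n_code=4)
    c2 = encode_sequence(s2, n_code=5)
    if scheme.is_edit_equivalent and w <= 64:
        scores = _myers_grid(c1, c2, w)
    else:
        scores = _dp_grid(c1, c2, w, scheme.match, scheme.mismatch, scheme.gap)
    return WindowScoreGrid(scores, ids, scheme)


def count_window_pairs(m: int, n: int, w: int) -> int:
    """Number of window pairs scored between sequences of lengths m and n."""
    if w > min(m, n):
        raise ValueError("window length exceeds a sequence length")
    if w <= 0:
        raise ValueError("window length must be positive")
    return (m - w + 1) * (n - w + 1)


def dump_grid_tsv(grid: WindowScoreGrid, path, floor: float = 0.0) -> None:
    """Write (i, j, score) rows for grid cells with score >= floor (debugging)."""
    ii, jj = np.nonzero(grid.scores >= floor)
    with open(path, "w") as fh:
        fh.write("i\tj\tscore\n")
        for i, j in zip(ii.tolist(), jj.tolist()):
            fh.write(f"{i}\t{j}\t{grid.scores[i, j]:g}\n")
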