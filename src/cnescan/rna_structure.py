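"""Conserved RNA secondary structure on CNE alignments.

The structure conservation index (SCI) is the energy of the consensus fold of
an alignment divided by the mean energy of its rows folded independently:
values near 1 indicate a conserved structure, values above 1 suggest
compensatory mutations. Significance is assessed against alignments shuffled
column-by-column within classes that preserve the conservation pattern (gap
pattern and number of distinct residues per column), with an add-one
empirical p-value over the shuffled SCI distribution and a Z score reported
alongside.

Folding goes through an engine contract. The default engine maximizes
Watson-Crick + GU base pairing (Nussinov-style, minimum hairpin loop 3,
energy -1 per pair; consensus energy is the maximal sum over column pairs of
the fraction of rows able to pair there). A thermodynamic engine backed by
the RNAfold/RNAalifold executables is provided when those are on PATH.
Numbers from different engines are never compared.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

__all__ = [
    "AlignmentBlock",
    "FoldResult",
    "StructureReport",
    "MaxPairEngine",
    "ViennaEngine",
    "fold_mfe",
    "consensus_fold",
    "structure_conservation_index",
    "shuffle_alignment_columns",
    "sci_empirical_pvalue",
]

_RNA_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4, "-": 5, ".": 5}
MIN_LOOP = 3


@dataclass
class AlignmentBlock:
    rows: list[tuple[str, str]]  # (species, gapped sequence)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows must have equal length")
        for _, seq in self.rows:
            bad = set(seq.upper()) - set(_RNA_CODE)
            if bad:
                raise ValueError(f"illegal alignment characters {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    def column(self, j: int) -> str:
        return "".join(seq[j] for _, seq in self.rows)

    def degapped_rows(self) -> list[str]:
        return [seq.replace("-", "").replace(".", "") for _, seq in self.rows]


@dataclass
class FoldResult:
    structure: str  # dot-bracket
    energy: float
    engine: str = "maxpair"
    column_map: Optional[list[int]] = None  # set when all-gap columns were dropped


@dataclass
class StructureReport:
    sci: float
    z: float
    empirical_p: float
    n_shuffles: int
    n_valid: int
    engine: str
    unreliable: bool = False


def _encode_rna(seq: str) -> np.ndarray:
    return np.fromiter(
        (_RNA_CODE[c] for c in seq.upper()), dtype=np.uint8, count=len(seq)
    )


@njit(cache=True)
def _pair_ok(a, b):  # pragma: no cover - jitted
    return (
        (a == 0 and b == 3) or (a == 3 and b == 0)
        or (a == 1 and b == 2) or (a == 2 and b == 1)
        or (a == 2 and b == 3) or (a == 3 and b == 2)
    )


@njit(cache=True)
def _weight_matrix(codes):  # pragma: no cover - jitted
    """Fraction of rows able to pair at each column pair (gaps cannot pair)."""
    k, n = codes.shape
    W = np.zeros((n, n), np.float64)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            c = 0
            for r in range(k):
                if _pair_ok(codes[r, i], codes[r, j]):
                    c += 1
            W[i, j] = c / k
    return W


@njit(cache=True)
def _nussinov(W):  # pragma: no cover - jitted
    """Max-weight non-crossing pairing with min loop 3.

    Returns (M, P): M[i, j] = best total weight on [i, j], P[i, j] = fewest
    pairs among optima (zero-weight pairs are never used).
    """
    n = W.shape[0]
    M = np.zeros((n, n), np.float64)
    P = np.zeros((n, n), np.int32)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1, j]
            pairs = P[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if W[i, k] <= 0.0:
                    continue
                inner = M[i + 1, k - 1] if k - 1 >= i + 1 else 0.0
                right = M[k + 1, j] if k + 1 <= j else 0.0
                ip = P[i + 1, k - 1] if k - 1 >= i + 1 else 0
                rp = P[k + 1, j] if k + 1 <= j else 0
                val = W[i, k] + inner + right
                np_ = 1 + ip + rp
                if val > best + 1e-12 or (val > best - 1e-12 and np_ < pairs):
                    best = val
                    pairs = np_
            M[i, j] = best
            P[i, j] = pairs
    return M, P


def _traceback(W: np.ndarray, M: np.ndarray, P: np.ndarray) -> str:
    """Canonical traceback: unpaired preferred on ties, else smallest partner."""
    n = W.shape[0]
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if abs(M[i + 1, j] - M[i, j]) < 1e-12 and P[i + 1, j] == P[i, j]:
            stack.append((i + 1, j))
            continue
        chosen = -1
        for k in range(i + MIN_LOOP + 1, j + 1):
            if W[i, k] <= 0.0:
                continue
            inner = M[i + 1, k - 1] if k - 1 >= i + 1 else 0.0
            right = M[k + 1, j] if k + 1 <= j else 0.0
            ip = P[i + 1, k - 1] if k - 1 >= i + 1 else 0
            rp = P[k + 1, j] if k + 1 <= j else 0
            if (
                abs(W[i, k] + inner + right - M[i, j]) < 1e-12
                and 1 + ip + rp == P[i, j]
            ):
                chosen = k
                break
        if chosen < 0:  # numerical fallback: treat i as unpaired
            stack.append((i + 1, j))
            continue
        struct[i] = "("
        struct[chosen] = ")"
        if chosen - 1 >= i + 1:
            stack.append((i + 1, chosen - 1))
        if chosen + 1 <= j:
            stack.append((chosen + 1, j))
    return "".join(struct)


class MaxPairEngine:
    """Base-pair maximization folding (the built-in, dependency-free engine)."""

    name = "maxpair"

    def fold(self, seq: str) -> FoldResult:
        if not seq:
            raise ValueError("empty sequence")
        codes = _encode_rna(seq).reshape(1, -1)
        W = _weight_matrix(codes)
        if len(seq) <= MIN_LOOP + 1:
            return FoldResult("." * len(seq), 0.0, self.name)
        M, P = _nussinov(W)
        return FoldResult(_traceback(W, M, P), -float(M[0, -1]), self.name)

    def fold_energy(self, seq: str) -> float:
        if not seq:
            raise ValueError("empty sequence")
        if len(seq) <= MIN_LOOP + 1:
            return 0.0
        codes = _encode_rna(seq).reshape(1, -1)
        W = _weight_matrix(codes)
        M, _ = _nussinov(W)
        return -float(M[0, -1])

    def _consensus_arrays(self, rows: Sequence[str]):
        mat = np.stack([_encode_rna(r) for r in rows])
        keep = [j for j in range(mat.shape[1]) if not np.all(mat[:, j] == 5)]
        column_map = keep if len(keep) != mat.shape[1] else None
        mat = mat[:, keep]
        return mat, column_map

    def consensus(self, rows: Sequence[str]) -> FoldResult:
        mat, column_map = self._consensus_arrays(rows)
        n = mat.shape[1]
        if n <= MIN_LOOP + 1:
            return FoldResult("." * n, 0.0, self.name, column_map)
        W = _weight_matrix(mat)
        M, P = _nussinov(W)
        return FoldResult(_traceback(W, M, P), -float(M[0, -1]), self.name, column_map)

    def consensus_energy(self, rows: Sequence[str]) -> float:
        mat, _ = self._consensus_arrays(rows)
        if mat.shape[1] <= MIN_LOOP + 1:
            return 0.0
        W = _weight_matrix(mat)
        M, _ = _nussinov(W)
        return -float(M[0, -1])


class ViennaEngine:
    """Thermodynamic folding through the RNAfold / RNAalifold executables."""

    name = "vienna"

    def __init__(self) -> None:
        if shutil.which("RNAfold") is None or shutil.which("RNAalifold") is None:
            raise RuntimeError("RNAfold/RNAalifold not found on PATH")

    def fold(self, seq: str) -> FoldResult:
        if not seq:
            raise ValueError("empty sequence")
        out = subprocess.run(
            ["RNAfold", "--noPS"],
            input=seq.replace("T", "U").replace("t", "u") + "\n",
            capture_output=True, text=True, check=True,
        ).stdout.splitlines()
        struct_line = out[1]
        structure = struct_line.rsplit(" (", 1)[0].strip()
        energy = float(struct_line.rsplit("(", 1)[1].rstrip(")").strip())
        return FoldResult(structure, energy, self.name)

    def fold_energy(self, seq: str) -> float:
        return self.fold(seq).energy

    def consensus(self, rows: Sequence[str]) -> FoldResult:
        mat = np.stack([_encode_rna(r) for r in rows])
        keep = [j for j in range(mat.shape[1]) if not np.all(mat[:, j] == 5)]
        column_map = keep if len(keep) != mat.shape[1] else None
        rows = ["".join(r[j] for j in keep) for r in rows]
        with tempfile.NamedTemporaryFile("w", suffix=".aln", delete=False) as fh:
            fh.write("CLUSTAL W\n\n")
            for idx, seq in enumerate(rows):
                fh.write(f"row{idx}  {seq.upper().replace('T', 'U')}\n")
            path = fh.name
        out = subprocess.run(
            ["RNAalifold", "--noPS", path],
            capture_output=True, text=True, check=True,
        ).stdout.splitlines()
        struct_line = out[1]
        structure = struct_line.split(" ", 1)[0]
        # trailer looks like "( -8.70 = -8.20 +  -0.50)"
        trailer = struct_line[len(structure):]
        energy = float(trailer.split("(", 1)[1].split("=", 1)[0].strip())
        return FoldResult(structure, energy, self.name, column_map)

    def consensus_energy(self, rows: Sequence[str]) -> float:
        return self.consensus(rows).energy


def fold_mfe(seq: str, engine: Optional[MaxPairEngine] = None) -> FoldResult:
    """Fold one sequence with the given engine (default: max-pairing fallback)."""
    return (engine or MaxPairEngine()).fold(seq)


def consensus_fold(block: AlignmentBlock, engine: Optional[MaxPairEngine] = None) -> FoldResult:
    """One structure applied to all rows of the alignment."""
    return (engine or MaxPairEngine()).consensus([seq for _, seq in block.rows])


def structure_conservation_index(
    block: AlignmentBlock, engine: Optional[MaxPairEngine] = None
) -> Optional[float]:
    """SCI = consensus energy / mean independent row energy (rows de-gapped).

    Returns None (flagged unstructured) when the mean independent energy is
    zero; such blocks cannot carry a structure signal.
    """
    eng = engine or MaxPairEngine()
    e_cons = eng.consensus_energy([seq for _, seq in block.rows])
    indep = [eng.fold_energy(row) for row in block.degapped_rows()]
    mean_indep = float(np.mean(indep))
    if mean_indep == 0.0:
        return None
    return float(e_cons / mean_indep)


def _column_classes(block: AlignmentBlock) -> dict[tuple, list[int]]:
    classes: dict[tuple, list[int]] = {}
    for j in range(block.n_columns):
        col = block.column(j).upper().replace(".", "-")
        gap_pattern = tuple(c == "-" for c in col)
        residues = {c for c in col if c != "-"}
        key = (gap_pattern, len(residues))
        classes.setdefault(key, []).append(j)
    return classes


def shuffle_alignment_columns(block: AlignmentBlock, seed: int = 0) -> AlignmentBlock:
    """Permute columns within classes of identical (gap pattern, conservation).

    Conservation level is the number of distinct non-gap residues in the
    column, so the overall conservation pattern of the alignment is kept
    intact; per-row residue multisets are preserved by construction.
    """
    if block.n_columns < 2:
        raise ValueError("need at least 2 columns to shuffle")
    rng = np.random.default_rng(seed)
    order = np.arange(block.n_columns)
    for _, cols in sorted(_column_classes(block).items()):
        cols_arr = np.asarray(cols)
        order[cols_arr] = cols_arr[rng.permutation(len(cols_arr))]
    rows = [(sp, "".join(seq[j] for j in order)) for sp, seq in block.rows]
    return AlignmentBlock(rows)


def sci_empirical_pvalue(
    block: AlignmentBlock,
    engine: Optional[MaxPairEngine] = None,
    n: int = 1000,
    seed: int = 0,
) -> StructureReport:
    """Empirical significance of the block's SCI against column-shuffled controls.

    Generates n shuffled alignments, computes their SCIs (undefined ones are
    dropped and counted), and reports z = (SCI - mean)/sd of the shuffled
    distribution plus the add-one empirical p-value
    (1 + #{shuffled >= true}) / (n_valid + 1).
    """
    if n <= 0:
        raise ValueError("need at least one shuffle")
    eng = engine or MaxPairEngine()
    sci_true = structure_conservation_index(block, eng)
    if sci_true is None:
        raise ValueError("SCI undefined for this block (unstructured rows)")
    rng = np.random.default_rng(seed)
    shuffled: list[float] = []
    for _ in range(n):
        b = shuffle_alignment_columns(block, seed=int(rng.integers(0, 2**31 - 1)))
        s = structure_conservation_index(b, eng)
        if s is not None:
            shuffled.append(s)
    n_valid = len(shuffled)
    if n_valid == 0:
        return StructureReport(sci_true, float("nan"), 1.0, n, 0, eng.name, True)
    arr = np.asarray(shuffled)
    sd = float(arr.std(ddof=1)) if n_valid > 1 else 0.0
    z = (sci_true - float(arr.mean())) / sd if sd > 0 else float("inf") if sci_true > arr.mean() else 0.0
    p = (1 + int(np.sum(arr >= sci_true - 1e-12))) / (n_valid + 1)
    return StructureReport(
        sci=float(sci_true), z=float(z), empirical_p=float(p),
        n_shuffles=n, n_valid=n_valid, engine=eng.name,
        unreliable=n_valid < 10,
    )
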