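"""Global pairwise alignment and percent-identity matrices.

An affine-gap Needleman-Wunsch aligner with optionally free terminal gaps,
scored with EMBOSS-default nucleotide scores (+5 match / -4 mismatch, gap
open 10, extend 0.5) or BLOSUM62 for proteins.  The dynamic program is
jitted with numba; gap runs at any of the four alignment edges cost
nothing unless ``end_gaps_penalized`` is set.  A gap run of length L costs
``gap_open + (L-1) * gap_extend``.

Percent identity follows the EMBOSS "Identity" convention by default:
identical columns divided by total alignment columns, gap columns
included.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from numba import njit

from .seq_io import IUPAC_RNA, NucSeq

logger = logging.getLogger(__name__)

_NT_ALPHABET = "ACGUNRYSWKMBDHV-"
_NT_INDEX = {c: i for i, c in enumerate(_NT_ALPHABET)}

_AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX"
_AA_INDEX = {c: i for i, c in enumerate(_AA_ALPHABET)}


@dataclasses.dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters (EMBOSS Needle defaults).

    Nucleotide scoring is by character equality: ambiguity letters score as
    a mismatch against everything except themselves.  Protein scoring uses
    a BLOSUM62 substitution table.
    """

    match: float = 5.0
    mismatch: float = -4.0
    protein_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps_penalized: bool = False

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")


@dataclasses.dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def n_gap_columns(self) -> int:
        return sum(1 for a, b in zip(self.aligned_a, self.aligned_b)
                   if a == "-" or b == "-")


_NEG = np.float32(-1e30)


@njit(cache=True)
def _affine_nw(a, b, sub, gap_open, gap_extend, free_ends):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), _NEG, dtype=np.float32)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.float32)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.float32)  # gap in a (consume b)
    pm = np.zeros((n + 1, m + 1), dtype=np.uint8)
    px = np.zeros((n + 1, m + 1), dtype=np.uint8)
    py = np.zeros((n + 1, m + 1), dtype=np.uint8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        if free_ends:
            X[i, 0] = 0.0
        else:
            X[i, 0] = -(gap_open + (i - 1) * gap_extend)
        px[i, 0] = 1
    for j in range(1, m + 1):
        if free_ends:
            Y[0, j] = 0.0
        else:
            Y[0, j] = -(gap_open + (j - 1) * gap_extend)
        py[0, j] = 2

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            # match/mismatch state: preference M > X > Y on ties
            s = sub[ai, b[j - 1]]
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + s
            pm[i, j] = ptr

            # gap-in-b state (vertical); free when the whole run lies on an edge
            if free_ends and (j == m):
                open_cost = 0.0
                ext_cost = 0.0
            else:
                open_cost = gap_open
                ext_cost = gap_extend
            best = M[i - 1, j] - open_cost
            ptr = 0
            if X[i - 1, j] - ext_cost > best:
                best = X[i - 1, j] - ext_cost
                ptr = 1
            if Y[i - 1, j] - open_cost > best:
                best = Y[i - 1, j] - open_cost
                ptr = 2
            X[i, j] = best
            px[i, j] = ptr

            # gap-in-a state (horizontal)
            if free_ends and (i == n):
                open_cost = 0.0
                ext_cost = 0.0
            else:
                open_cost = gap_open
                ext_cost = gap_extend
            best = M[i, j - 1] - open_cost
            ptr = 0
            if X[i, j - 1] - open_cost > best:
                best = X[i, j - 1] - open_cost
                ptr = 1
            if Y[i, j - 1] - ext_cost > best:
                best = Y[i, j - 1] - ext_cost
                ptr = 2
            Y[i, j] = best
            py[i, j] = ptr

    # termination: preference M > X > Y on ties
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2

    # traceback: 0 = diagonal, 1 = up (gap in b), 2 = left (gap in a)
    ops = np.empty(n + m, dtype=np.uint8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 and j == 0:
                break
            ops[k] = 0
            state = pm[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            state = px[i, j]
            i -= 1
        else:
            ops[k] = 2
            state = py[i, j]
            j -= 1
        k += 1
    return score, ops[:k][::-1].copy()


def _encode(seq: str, kind: str) -> np.ndarray:
    index = _NT_INDEX if kind == "nucleotide" else _AA_INDEX
    default = index["N"] if kind == "nucleotide" else index["X"]
    return np.array([index.get(c, default) for c in seq], dtype=np.int64)


def _nt_submatrix(params: AlignmentParams) -> np.ndarray:
    k = len(_NT_ALPHABET)
    sub = np.full((k, k), params.mismatch, dtype=np.float32)
    np.fill_diagonal(sub, params.match)
    return sub


_BLOSUM_CACHE: dict[str, np.ndarray] = {}


def _aa_submatrix(params: AlignmentParams) -> np.ndarray:
    name = params.protein_matrix
    if name not in _BLOSUM_CACHE:
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load(name)
        k = len(_AA_ALPHABET)
        sub = np.zeros((k, k), dtype=np.float32)
        for i, x in enumerate(_AA_ALPHABET):
            for j, y in enumerate(_AA_ALPHABET):
                sub[i, j] = blosum[x][y]
        _BLOSUM_CACHE[name] = sub
    return _BLOSUM_CACHE[name]


def _infer_kind(a: str, b: str) -> str:
    if set(a) <= IUPAC_RNA and set(b) <= IUPAC_RNA:
        return "nucleotide"
    return "protein"


def global_align(
    a: str | NucSeq,
    b: str | NucSeq,
    params: AlignmentParams | None = None,
    kind: str = "auto",
    identity_denominator: str = "alignment",
) -> AlignmentResult:
    """Optimal affine-gap global alignment of two sequences.

    With ``end_gaps_penalized=False`` (default) terminal gap runs cost 0.
    Percent identity = identical columns / total alignment columns x 100
    (set ``identity_denominator="shorter"`` to divide by the shorter
    sequence length instead).  When co-optimal alignments exist the
    traceback deterministically prefers diagonal > up > left.
    """
    if params is None:
        params = AlignmentParams()
    sa = a.residues if isinstance(a, NucSeq) else a
    sb = b.residues if isinstance(b, NucSeq) else b
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    if kind == "auto":
        kind = _infer_kind(sa, sb)
    sub = _nt_submatrix(params) if kind == "nucleotide" else _aa_submatrix(params)
    score, ops = _affine_nw(
        _encode(sa, kind),
        _encode(sb, kind),
        sub,
        np.float32(params.gap_open),
        np.float32(params.gap_extend),
        not params.end_gaps_penalized,
    )

    ca, cb = [], []
    i = j = 0
    for op in ops:
        if op == 0:
            ca.append(sa[i]); cb.append(sb[j]); i += 1; j += 1
        elif op == 1:
            ca.append(sa[i]); cb.append("-"); i += 1
        else:
            ca.append("-"); cb.append(sb[j]); j += 1
    aligned_a, aligned_b = "".join(ca), "".join(cb)

    identical = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    if identity_denominator == "alignment":
        denom = len(aligned_a)
    elif identity_denominator == "shorter":
        denom = min(len(sa), len(sb))
    else:
        raise ValueError(f"unknown identity denominator {identity_denominator!r}")
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score),
        percent_identity=100.0 * identical / denom,
    )


@dataclasses.dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric percent-identity matrix with a 100 diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")

    def lookup(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_tsv(self, path) -> None:
        from .seq_io import write_tsv

        rows = [
            {"id": self.ids[i], **{self.ids[j]: f"{self.values[i, j]:.4f}"
                                   for j in range(len(self.ids))}}
            for i in range(len(self.ids))
        ]
        write_tsv(rows, path, columns=["id", *self.ids])

    def to_phylip(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                vals = " ".join(f"{v:.4f}" for v in self.values[i])
                fh.write(f"{name:<12s}{vals}\n")


def identity_matrix(
    seqs: Sequence[NucSeq], params: AlignmentParams | None = None
) -> IdentityMatrix:
    """Align all unordered pairs once and collect percent identities."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    n = len(seqs)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = global_align(seqs[i], seqs[j], params, kind="nucleotide").percent_identity
            values[i, j] = values[j, i] = pid
    return IdentityMatrix(ids=tuple(ids), values=values)
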