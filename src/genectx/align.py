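"""Exact affine-gap local alignment of protein pairs.

The production path is a numba-compiled Smith-Waterman/Gotoh DP with fully
pinned tie-breaking so that results are bit-reproducible:

* gap of length k costs ``gap_open + k * gap_extend`` (BLAST convention;
  defaults 11 + k, BLOSUM62 scoring);
* among co-optimal end cells the one with the largest (i, j) in row-major
  order is chosen, so co-optimal extensions with score-0 substitutions are
  kept in the alignment;
* traceback prefers diagonal > up (gap in b) > left (gap in a), and gap
  chains are closed as early as possible.

Percent identity is computed over the residue-residue columns of the optimal
local alignment (gap columns count in neither numerator nor denominator);
``X`` never counts as identical. Coverage of each sequence is the aligned
span divided by its full length.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .genome import AMINO_ACIDS

#: Residue order used for integer encoding; X is index 20.
ALPHABET = AMINO_ACIDS + "X"
_CODE = {ch: i for i, ch in enumerate(ALPHABET)}

_NEG = -(10 ** 7)


def _blosum62() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    sub = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int32)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            sub[i, j] = int(mat[a][b])
    return sub


BLOSUM62 = _blosum62()


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters: substitution matrix and affine gap costs."""

    matrix: np.ndarray = None  # type: ignore[assignment]
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self):
        if self.matrix is None:
            object.__setattr__(self, "matrix", BLOSUM62)


DEFAULT_PARAMS = AlignParams()


@dataclass(frozen=True)
class PairSimilarity:
    """Identity/coverage summary of one optimal local alignment.

    ``percent_identity`` is in [0, 100]; ``coverage_a``/``coverage_b`` are
    the aligned fraction of each full sequence, in [0, 1]. Swapping the two
    sequences exchanges the coverage fields and nothing else.
    """

    pid_a: str
    pid_b: str
    percent_identity: float
    coverage_a: float
    coverage_b: float
    raw_score: int

    def swapped(self) -> "PairSimilarity":
        return PairSimilarity(self.pid_b, self.pid_a, self.percent_identity,
                              self.coverage_b, self.coverage_a, self.raw_score)


def encode(seq: str) -> np.ndarray:
    """Encode a protein string as residue codes; reject non-residue characters."""
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-residue character {exc.args[0]!r} in sequence") from None


@njit(cache=True)
def _sw_align(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    """Fill + traceback in one compiled pass.

    Returns (score, identical, residue_pair_columns, a_lo, a_hi, b_lo, b_hi)
    with 0-based inclusive span bounds; all zeros when no positive-scoring
    local alignment exists.
    """
    n = a.shape[0]
    m = b.shape[0]
    H = np.empty((n + 1, m + 1), np.int32)
    E = np.empty((n + 1, m + 1), np.int32)
    F = np.empty((n + 1, m + 1), np.int32)
    for j in range(m + 1):
        H[0, j] = 0
        E[0, j] = _NEG
        F[0, j] = _NEG
    for i in range(n + 1):
        H[i, 0] = 0
        E[i, 0] = _NEG
        F[i, 0] = _NEG
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        srow = sub[a[i - 1]]
        Hp = H[i - 1]
        Hc = H[i]
        Ep = E[i - 1]
        Ec = E[i]
        Fc = F[i]
        hdiag = 0
        hleft = 0
        fprev = _NEG
        for j in range(1, m + 1):
            e = Ep[j]
            t = Hp[j] - gap_open
            if t > e:
                e = t
            e -= gap_extend
            f = fprev
            t = hleft - gap_open
            if t > f:
                f = t
            f -= gap_extend
            h = hdiag + srow[b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Ec[j] = e
            Fc[j] = f
            Hc[j] = h
            hdiag = Hp[j]
            hleft = h
            fprev = f
            if h >= best and h > 0:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback: diagonal > up (gap in b) > left (gap in a); gap chains
    # close as early as possible
    i = bi
    j = bj
    ident = 0
    pairs = 0
    state = 0  # 0=M 1=E 2=F
    xcode = sub.shape[0] - 1
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if h == H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]:
                pairs += 1
                if a[i - 1] == b[j - 1] and a[i - 1] != xcode:
                    ident += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            if E[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = 0
            i -= 1
        else:
            if F[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = 0
            j -= 1
    return best, ident, pairs, i, bi - 1, j, bj - 1


def align_pair(a: str, b: str, params: AlignParams | None = None, *,
               pid_a: str = "a", pid_b: str = "b") -> PairSimilarity:
    """Optimal local alignment of two protein sequences.

    Returns a :class:`PairSimilarity`; a pair with no positive-scoring local
    alignment reports identity 0, coverages 0 and score 0.
    """
    params = params or DEFAULT_PARAMS
    ca, cb = encode(a), encode(b)
    if ca.size == 0 or cb.size == 0:
        raise ValueError("empty sequence")
    return _similarity_from_codes(ca, cb, params, pid_a, pid_b)


def _similarity_from_codes(ca: np.ndarray, cb: np.ndarray, params: AlignParams,
                           pid_a: str, pid_b: str) -> PairSimilarity:
    score, ident, pairs, a_lo, a_hi, b_lo, b_hi = _sw_align(
        ca, cb, params.matrix, params.gap_open, params.gap_extend)
    if score == 0:
        return PairSimilarity(pid_a, pid_b, 0.0, 0.0, 0.0, 0)
    return PairSimilarity(
        pid_a, pid_b,
        percent_identity=100.0 * ident / pairs,
        coverage_a=(a_hi - a_lo + 1) / ca.size,
        coverage_b=(b_hi - b_lo + 1) / cb.size,
        raw_score=int(score),
    )
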