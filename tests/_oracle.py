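"""Independent brute-force oracles used to check the production paths.

The aligner here is a deliberately plain, pure-Python affine-gap local DP
(no numba, no shared code with the package kernel) implementing the same
documented conventions: BLAST-style gap cost open + k*extend, end cell at
the largest (i, j) among co-optimal cells, traceback diagonal > up > left
with gaps closed as early as possible. The clusterer enumerates every pair
and finds connected components by breadth-first search.
"""
from __future__ import annotations

from collections import deque

from Bio.Align import substitution_matrices

_BL = substitution_matrices.load("BLOSUM62")
_SCORE = {(x, y): int(_BL[x][y]) for x in _BL.alphabet for y in _BL.alphabet}
NEG = float("-inf")


def oracle_align(a: str, b: str, gap_open: int = 11, gap_extend: int = 1):
    """Return (identity_pct, coverage_a, coverage_b, score)."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = max(E[i - 1][j], H[i - 1][j] - gap_open) - gap_extend
            f = max(F[i][j - 1], H[i][j - 1] - gap_open) - gap_extend
            h = max(0.0, H[i - 1][j - 1] + _SCORE[ai, b[j - 1]], e, f)
            E[i][j] = e
            F[i][j] = f
            H[i][j] = h
            if h >= best and h > 0:
                best, bi, bj = h, i, j
    if best == 0:
        return 0.0, 0.0, 0.0, 0
    i, j = bi, bj
    ident = pairs = 0
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            if H[i][j] == 0:
                break
            if H[i][j] == H[i - 1][j - 1] + _SCORE[a[i - 1], b[j - 1]]:
                pairs += 1
                if a[i - 1] == b[j - 1] and a[i - 1] != "X":
                    ident += 1
                i -= 1
                j -= 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            if E[i][j] == H[i - 1][j] - gap_open - gap_extend:
                state = "M"
            i -= 1
        else:
            if F[i][j] == H[i][j - 1] - gap_open - gap_extend:
                state = "M"
            j -= 1
    return (100.0 * ident / pairs, (bi - i) / n, (bj - j) / m, int(best))


def oracle_cluster(items: list[tuple[str, str]], identity: float,
                   coverage: float) -> set[frozenset[str]]:
    """All-pairs DP + BFS connected components; returns member-set partition."""
    pids = [pid for pid, _ in items]
    seqs = dict(items)
    adj: dict[str, set[str]] = {pid: set() for pid in pids}
    for x in range(len(pids)):
        for y in range(x + 1, len(pids)):
            ident, cov_a, cov_b, _ = oracle_align(seqs[pids[x]], seqs[pids[y]])
            if ident >= identity and min(cov_a, cov_b) >= coverage:
                adj[pids[x]].add(pids[y])
                adj[pids[y]].add(pids[x])
    seen: set[str] = set()
    components = set()
    for pid in pids:
        if pid in seen:
            continue
        comp = {pid}
        queue = deque([pid])
        while queue:
            cur = queue.popleft()
            for nxt in adj[cur]:
                if nxt not in comp:
                    comp.add(nxt)
                    queue.append(nxt)
        seen |= comp
        components.add(frozenset(comp))
    return components
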