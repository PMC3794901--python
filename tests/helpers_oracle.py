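"""Independent brute-force reference for the alignment engine.

Everything here is deliberately plain Python (loops, recursion, direct
formulas) so that it shares no code path with the production engine: the
similarity matrix is evaluated element by element from its definition, the
longest admissible paths are enumerated by exhaustive recursion over block
subsequences, and the RMSD is computed from the centered-deviation formula
directly.  Feasible for profiles up to ~30 positions.
"""

from __future__ import annotations

import math
from functools import lru_cache


def oracle_similarity(v1, v2, W, normalize=True):
    v1, v2 = list(map(float, v1)), list(map(float, v2))
    R1, R2 = len(v1) - W + 1, len(v2) - W + 1

    def block(v, s):
        b = [[v[s + l] - v[s + k] for l in range(W)] for k in range(W)]
        if normalize:
            m = max(abs(x) for row in b for x in row)
            if m > 0:
                b = [[x / m for x in row] for row in b]
        return b

    S = [[0.0] * R2 for _ in range(R1)]
    for i in range(R1):
        b1 = block(v1, i)
        for j in range(R2):
            b2 = block(v2, j)
            total = 0.0
            for k in range(W):
                for l in range(W):
                    total += abs(b1[k][l] - b2[k][l])
            S[i][j] = total / (W * W)
    return S


def oracle_longest_paths(S, W, C, gap_max):
    """All admissible paths of maximal block count, lexicographic order."""
    R1, R2 = len(S), len(S[0])
    adm = [[S[i][j] <= C for j in range(R2)] for i in range(R1)]

    def succs(i, j):
        out = []
        for a in range(gap_max + 1):
            for b in range(gap_max + 1 - a):
                ni, nj = i + W + a, j + W + b
                if ni < R1 and nj < R2 and adm[ni][nj]:
                    out.append((ni, nj))
        return out

    @lru_cache(maxsize=None)
    def longest(i, j):
        best = 0
        for ni, nj in succs(i, j):
            best = max(best, longest(ni, nj))
        return best + 1

    cells = [(i, j) for i in range(R1) for j in range(R2) if adm[i][j]]
    if not cells:
        return []
    Lmax = max(longest(i, j) for i, j in cells)

    paths = []

    def extend(path, remaining):
        if remaining == 0:
            paths.append(tuple(path))
            return
        for nxt in succs(*path[-1]):
            if longest(*nxt) == remaining:
                path.append(nxt)
                extend(path, remaining - 1)
                path.pop()

    for cell in cells:
        if longest(*cell) == Lmax:
            extend([cell], Lmax - 1)
    return paths


def oracle_rmsd(v1, v2, path, W):
    a = [float(v1[i + t]) for i, _ in path for t in range(W)]
    b = [float(v2[j + t]) for _, j in path for t in range(W)]
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    sq = sum(((x - ma) - (y - mb)) ** 2 for x, y in zip(a, b))
    return math.sqrt(sq / len(a))


def oracle_optimal(v1, v2, W, C, gap_max, normalize=True):
    """(L, gaps, apd, rmsd) of the optimal alignment, or None for no match."""
    S = oracle_similarity(v1, v2, W, normalize)
    paths = oracle_longest_paths(S, W, C, gap_max)
    if not paths:
        return None
    best_path, best_rmsd = None, math.inf
    for path in paths:
        r = oracle_rmsd(v1, v2, path, W)
        if r < best_rmsd:
            best_path, best_rmsd = path, r
    gaps = 0
    for k in range(len(best_path) - 1):
        gaps += best_path[k + 1][0] - best_path[k][0] - W
        gaps += best_path[k + 1][1] - best_path[k][1] - W
    apd = sum(S[i][j] for i, j in best_path) / len(best_path)
    return len(best_path) * W, gaps, apd, best_rmsd
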