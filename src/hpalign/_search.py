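"""Numba kernels for the gap-bounded longest-path search.

The search works on the admissibility mask of the block-similarity matrix
``S`` (cells with ``S <= C``).  A path is an ordered list of block starts
``(i_k, j_k)`` with ``i_{k+1} >= i_k + W``, ``j_{k+1} >= j_k + W`` and at
most ``gap_max`` skipped cells per junction (summed over both sequences).

``longest_from`` computes, for every admissible cell, the maximal number of
blocks of any admissible path starting there (backward dynamic programme).
The enumeration kernels then walk all paths of globally maximal block count
in lexicographic order of their block-start sequences.

RMSD bookkeeping: over the aligned differences ``d_t = a_t - b_t`` the
centered RMSD satisfies ``RMSD^2 = mean(d^2) - mean(d)^2``, so per-cell
block sums of ``d`` and ``d^2`` (precomputed outside) are accumulated along
the walk and each complete path costs O(1) to score.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def longest_from(adm, W, gap_max):
    """Max block count of an admissible path starting at each cell (0 if none)."""
    R1, R2 = adm.shape
    f = np.zeros((R1, R2), np.int32)
    for i in range(R1 - 1, -1, -1):
        for j in range(R2 - 1, -1, -1):
            if not adm[i, j]:
                continue
            best = 0
            for a in range(gap_max + 1):
                ni = i + W + a
                if ni >= R1:
                    break
                for b in range(gap_max + 1 - a):
                    nj = j + W + b
                    if nj >= R2:
                        break
                    if f[ni, nj] > best:
                        best = f[ni, nj]
            f[i, j] = best + 1
    return f


@njit(cache=True)
def best_path(adm, f, Lmax, W, gap_max, sd, sd2, path_cap):
    """Minimum-RMSD path among the (at most ``path_cap``) longest paths.

    Returns ``(blocks, rmsd, gaps, n_paths, truncated)`` where ``blocks`` is
    the (Lmax, 2) block-start array of the winner, ties broken in favour of
    the first path in lexicographic enumeration order.
    """
    R1, R2 = adm.shape
    n = Lmax * W
    n_codes = (gap_max + 1) * (gap_max + 2) // 2
    gis = np.empty(n_codes, np.int64)
    gjs = np.empty(n_codes, np.int64)
    k = 0
    for a in range(gap_max + 1):
        for b in range(gap_max + 1 - a):
            gis[k] = a
            gjs[k] = b
            k += 1

    path = np.empty((Lmax, 2), np.int32)
    cs1 = np.empty(Lmax, np.float64)
    cs2 = np.empty(Lmax, np.float64)
    cgap = np.empty(Lmax, np.int64)
    state = np.empty(Lmax, np.int64)
    best = np.zeros((Lmax, 2), np.int32)
    best_rmsd = np.inf
    best_gaps = np.int64(0)
    count = np.int64(0)
    truncated = False

    for si in range(R1):
        if truncated:
            break
        for sj in range(R2):
            if truncated:
                break
            if not adm[si, sj] or f[si, sj] != Lmax:
                continue
            depth = 0
            path[0, 0] = si
            path[0, 1] = sj
            cs1[0] = sd[si, sj]
            cs2[0] = sd2[si, sj]
            cgap[0] = 0
            state[0] = 0
            while depth >= 0:
                if depth == Lmax - 1:
                    count += 1
                    if count > path_cap:
                        truncated = True
                        count = path_cap
                        break
                    mean_d = cs1[depth] / n
                    var = cs2[depth] / n - mean_d * mean_d
                    if var < 0.0:
                        var = 0.0
                    rmsd = np.sqrt(var)
                    if rmsd < best_rmsd:
                        best_rmsd = rmsd
                        best_gaps = cgap[depth]
                        for t in range(Lmax):
                            best[t, 0] = path[t, 0]
                            best[t, 1] = path[t, 1]
                    depth -= 1
                    continue
                i0 = path[depth, 0]
                j0 = path[depth, 1]
                found = False
                ni = 0
                nj = 0
                skip = 0
                code = state[depth]
                while code < n_codes:
                    a = gis[code]
                    b = gjs[code]
                    code += 1
                    ni = i0 + W + a
                    nj = j0 + W + b
                    if ni < R1 and nj < R2 and adm[ni, nj] and f[ni, nj] == Lmax - depth - 1:
                        found = True
                        skip = a + b
                        break
                state[depth] = code
                if found:
                    depth += 1
                    path[depth, 0] = ni
                    path[depth, 1] = nj
                    cs1[depth] = cs1[depth - 1] + sd[ni, nj]
                    cs2[depth] = cs2[depth - 1] + sd2[ni, nj]
                    cgap[depth] = cgap[depth - 1] + skip
                    state[depth] = 0
                else:
                    depth -= 1
    return best, best_rmsd, best_gaps, count, truncated


@njit(cache=True)
def all_longest_paths(adm, f, Lmax, W, gap_max, path_cap):
    """All longest paths (up to ``path_cap``) in lexicographic order.

    Returns ``(paths, truncated)`` with ``paths`` of shape (k, Lmax, 2).
    """
    R1, R2 = adm.shape
    n_codes = (gap_max + 1) * (gap_max + 2) // 2
    gis = np.empty(n_codes, np.int64)
    gjs = np.empty(n_codes, np.int64)
    k = 0
    for a in range(gap_max + 1):
        for b in range(gap_max + 1 - a):
            gis[k] = a
            gjs[k] = b
            k += 1

    path = np.empty((Lmax, 2), np.int32)
    state = np.empty(Lmax, np.int64)
    out = np.zeros((path_cap, Lmax, 2), np.int32)
    count = np.int64(0)
    truncated = False

    for si in range(R1):
        if truncated:
            break
        for sj in range(R2):
            if truncated:
                break
            if not adm[si, sj] or f[si, sj] != Lmax:
                continue
            depth = 0
            path[0, 0] = si
            path[0, 1] = sj
            state[0] = 0
            while depth >= 0:
                if depth == Lmax - 1:
                    if count >= path_cap:
                        truncated = True
                        break
                    for t in range(Lmax):
                        out[count, t, 0] = path[t, 0]
                        out[count, t, 1] = path[t, 1]
                    count += 1
                    depth -= 1
                    continue
                i0 = path[depth, 0]
                j0 = path[depth, 1]
                found = False
                ni = 0
                nj = 0
                code = state[depth]
                while code < n_codes:
                    a = gis[code]
                    b = gjs[code]
                    code += 1
                    ni = i0 + W + a
                    nj = j0 + W + b
                    if ni < R1 and nj < R2 and adm[ni, nj] and f[ni, nj] == Lmax - depth - 1:
                        found = True
                        break
                state[depth] = code
                if found:
                    depth += 1
                    path[depth, 0] = ni
                    path[depth, 1] = nj
                    state[depth] = 0
                else:
                    depth -= 1
    return out[:count], truncated
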