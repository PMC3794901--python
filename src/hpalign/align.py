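"""Core horizontal-alignment engine for numeric profiles.

The comparison is "horizontal": instead of scoring positions one at a time,
each profile is converted to its internal signed distance matrix
``D[i][j] = v_j - v_i``, and W-residue blocks of the two matrices are
compared by the average absolute difference of their (optionally per-block
scaled) internal distances.  Because only internal differences enter, any
constant offset between the two data sets cancels; with per-block scaling
on, positive rescaling cancels too, so the first stage matches pure shape.

The block-similarity matrix ``S`` is then searched exhaustively for the
longest paths of non-overlapping, order-preserving blocks whose every cell
passes the shape cutoff ``C``, skipping at most ``GapMax`` cells of ``S``
per junction.  Among the longest paths, the one with the smallest centered
RMSD of the aligned values is the optimal alignment (magnitude filter).
Its quality is summarized by the Optimal Path Score
``OPS = (L - Gaps) / RMSD``, whose null distribution is calibrated
empirically (see :mod:`hpalign.calibration`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from . import _search
from .profiles import NumericProfile

__all__ = [
    "SearchParams",
    "AlignmentPath",
    "AlignmentResult",
    "SimilarityMatrix",
    "signed_distance_matrix",
    "scale_block",
    "similarity_matrix",
    "enumerate_longest_paths",
    "path_apd",
    "path_gaps",
    "alignment_rmsd",
    "ops_score",
    "optimal_alignment",
]


@dataclass(frozen=True)
class SearchParams:
    """Parameters governing block similarity and path admissibility.

    W : block size in residues.
    C : shape-similarity cutoff; a block pair matches when its average
        absolute scaled-distance difference is at most C (with the default
        per-block scaling, C = 0.40 admits blocks whose normalized internal
        distances differ by at most 40% on average).
    gap_max : maximum number of similarity-matrix cells skipped between
        consecutive blocks (summed over both sequences, per junction).
    normalize : scale each W-block of the distance matrix so its largest
        absolute internal distance is 1 (pure-shape comparison).
    path_cap : safety bound on the number of co-optimal longest paths
        examined during RMSD selection.
    """

    W: int = 5
    C: float = 0.40
    gap_max: int = 4
    normalize: bool = True
    path_cap: int = 100_000

    def __post_init__(self) -> None:
        if self.W < 1:
            raise ValueError("W must be >= 1")
        if self.C < 0:
            raise ValueError("C must be >= 0")
        if self.gap_max < 0:
            raise ValueError("gap_max must be >= 0")
        if self.path_cap < 1:
            raise ValueError("path_cap must be >= 1")


@dataclass(frozen=True)
class AlignmentPath:
    """An ordered list of aligned block starts, 0-based internally."""

    blocks: np.ndarray  # (n_blocks, 2) int
    W: int

    def __post_init__(self) -> None:
        blocks = np.asarray(self.blocks, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "blocks", blocks)
        if len(blocks) == 0:
            raise ValueError("an alignment path needs at least one block")
        steps = np.diff(blocks, axis=0)
        if len(steps) and (steps < self.W).any():
            raise ValueError("blocks must be non-overlapping and order-preserving")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def aligned_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based residue indices of every aligned position in each profile."""
        offs = np.arange(self.W)
        idx1 = (self.blocks[:, 0][:, None] + offs).ravel()
        idx2 = (self.blocks[:, 1][:, None] + offs).ravel()
        return idx1, idx2

    def ranges_1based(self) -> list[tuple[int, int, int, int]]:
        """Per-block 1-based inclusive (q_start, q_end, t_start, t_end)."""
        return [
            (int(i) + 1, int(i) + self.W, int(j) + 1, int(j) + self.W)
            for i, j in self.blocks
        ]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Block shape-similarity matrix plus the parameters that built it."""

    S: np.ndarray
    params: SearchParams


@dataclass(frozen=True)
class AlignmentResult:
    """The optimal alignment and its summary statistics.

    ``L`` is the number of aligned residues (W x blocks), ``gaps`` the total
    number of skipped similarity-matrix cells, ``apd`` the mean block
    similarity along the path, ``rmsd`` the centered RMSD of the aligned
    values, ``ops`` the Optimal Path Score, ``p`` the significance with
    respect to random profiles of the same data type (when a model was
    supplied).  ``L == 0`` marks a no-match result.
    """

    path: AlignmentPath | None
    L: int
    gaps: int
    apd: float
    rmsd: float
    ops: float
    p: float | None = None
    n_candidates: int = 0
    truncated: bool = False

    @property
    def matched(self) -> bool:
        return self.L > 0


def _values(profile) -> np.ndarray:
    if isinstance(profile, NumericProfile):
        return profile.values
    vals = np.asarray(profile, dtype=float)
    if vals.ndim != 1 or vals.size < 1:
        raise ValueError("profile must be a non-empty 1-D sequence of values")
    if not np.all(np.isfinite(vals)):
        raise ValueError("profile values must be finite")
    return vals


def signed_distance_matrix(profile) -> np.ndarray:
    """Internal signed distance matrix ``D[i][j] = v_j - v_i``.

    Antisymmetric: positive when measured from a smaller to a larger value.
    """
    v = _values(profile)
    return v[None, :] - v[:, None]


def scale_block(D: np.ndarray, start: int, W: int) -> np.ndarray:
    """The W x W block of ``D`` at ``start``, scaled to max |distance| = 1.

    A flat (all-zero) block is returned unchanged (0/0 convention: a
    zero-variance block matches any other flat block exactly).
    """
    M = D.shape[0]
    if start < 0 or start + W > M:
        raise IndexError(f"block [{start}, {start + W}) out of range for M={M}")
    sub = D[start : start + W, start : start + W]
    m = np.abs(sub).max()
    if m == 0:
        return sub.copy()
    return sub / m


def _block_features(v: np.ndarray, W: int, normalize: bool) -> np.ndarray:
    """Flattened (scaled) W-blocks of the distance matrix, shape (R, W*W)."""
    win = np.lib.stride_tricks.sliding_window_view(v, W)  # (R, W)
    B = win[:, None, :] - win[:, :, None]  # B[s, k, l] = v[s+l] - v[s+k]
    if normalize:
        m = np.abs(B).max(axis=(1, 2))
        m[m == 0] = 1.0
        B = B / m[:, None, None]
    return B.reshape(len(win), W * W)


def similarity_matrix(p1, p2, params: SearchParams | None = None) -> SimilarityMatrix:
    """Average absolute difference of equivalenced internal block distances.

    ``S[i][j]`` compares the W-block of profile 1 starting at ``i`` with the
    W-block of profile 2 starting at ``j``; 0 means identical shape.  Shape
    is (M - W + 1) x (N - W + 1).
    """
    params = params or SearchParams()
    v1, v2 = _values(p1), _values(p2)
    W = params.W
    if len(v1) < W or len(v2) < W:
        raise ValueError(f"both profiles must be at least W={W} long")
    B1 = _block_features(v1, W, params.normalize)
    B2 = _block_features(v2, W, params.normalize)
    S = cdist(B1, B2, "cityblock") / (W * W)
    return SimilarityMatrix(S=S, params=params)


def _diff_block_sums(v1: np.ndarray, v2: np.ndarray, W: int):
    """Per-cell sums of d and d^2 over the W aligned differences d = a - b.

    Computed elementwise (not via the q1 + q2 - 2<w1,w2> identity) so that
    identical windows give exactly zero: RMSD ties between co-optimal paths
    of an exact match must be exact for the first-encountered tie-break.
    """
    w1 = np.lib.stride_tricks.sliding_window_view(v1, W)
    w2 = np.lib.stride_tricks.sliding_window_view(v2, W)
    d = w1[:, None, :] - w2[None, :, :]
    sd = d.sum(axis=2)
    sd2 = (d * d).sum(axis=2)
    return np.ascontiguousarray(sd), np.ascontiguousarray(sd2)


def enumerate_longest_paths(
    S: SimilarityMatrix | np.ndarray,
    params: SearchParams | None = None,
) -> list[AlignmentPath]:
    """Every admissible path of maximal block count, lexicographic order.

    Admissible: all visited cells satisfy ``S <= C`` and consecutive blocks
    skip at most ``gap_max`` cells.  Returns an empty list when no cell
    passes the cutoff.  If more than ``path_cap`` co-optimal paths exist,
    the first ``path_cap`` are returned and a warning is emitted.
    """
    if isinstance(S, SimilarityMatrix):
        params = params or S.params
        S = S.S
    if params is None:
        raise ValueError("params required when S is a bare matrix")
    adm = np.ascontiguousarray(S <= params.C)
    f = _search.longest_from(adm, params.W, params.gap_max)
    Lmax = int(f.max()) if f.size else 0
    if Lmax == 0:
        return []
    paths, truncated = _search.all_longest_paths(
        adm, f, Lmax, params.W, params.gap_max, params.path_cap
    )
    if truncated:
        warnings.warn(
            f"more than path_cap={params.path_cap} co-optimal paths; "
            "returning the first ones in lexicographic order",
            stacklevel=2,
        )
    return [AlignmentPath(blocks=p, W=params.W) for p in paths]


def path_apd(S: SimilarityMatrix | np.ndarray, path: AlignmentPath) -> float:
    """Average path distance: mean S over the path's blocks (gaps free)."""
    if isinstance(S, SimilarityMatrix):
        S = S.S
    i, j = path.blocks[:, 0], path.blocks[:, 1]
    return float(S[i, j].mean())


def path_gaps(path: AlignmentPath) -> int:
    """Total number of similarity-matrix cells skipped along the path."""
    if path.n_blocks < 2:
        return 0
    steps = np.diff(path.blocks, axis=0) - path.W
    return int(steps.sum())


def alignment_rmsd(p1, p2, path: AlignmentPath) -> float:
    """Centered RMSD over the aligned residue pairs.

    Both aligned value sets are translated to their centers of mass first,
    so a global offset between the profiles does not contribute.
    """
    v1, v2 = _values(p1), _values(p2)
    idx1, idx2 = path.aligned_indices()
    if idx1[-1] >= len(v1) or idx2[-1] >= len(v2):
        raise IndexError("path extends beyond the profiles")
    a = v1[idx1]
    b = v2[idx2]
    dev = (a - a.mean()) - (b - b.mean())
    return float(np.sqrt(np.mean(dev * dev)))


def ops_score(L: int, gaps: int, rmsd: float) -> float:
    """Optimal Path Score ``(L - Gaps) / RMSD``.

    Increases with aligned length, is penalized by gaps, and returns the
    +infinity sentinel for an exact (RMSD = 0) match.
    """
    if L - gaps <= 0:
        raise ValueError(f"invalid alignment: L - Gaps = {L - gaps} <= 0")
    if rmsd < 0:
        raise ValueError("RMSD must be >= 0")
    if rmsd == 0:
        return math.inf
    return (L - gaps) / rmsd


def optimal_alignment(
    p1,
    p2,
    params: SearchParams | None = None,
    model=None,
) -> AlignmentResult:
    """Optimal gapped alignment of two numeric profiles.

    Pipeline: distance matrices -> block similarity -> longest admissible
    paths -> minimum-RMSD selection (ties: first in lexicographic
    enumeration order) -> APD / OPS, with a p-value attached when a
    calibrated probability model is supplied.  When no cell of ``S`` passes
    the cutoff a distinguished no-match result with ``L = 0`` is returned.
    """
    params = params or SearchParams()
    if model is not None:
        model.check_params(params)
    v1, v2 = _values(p1), _values(p2)
    sim = similarity_matrix(v1, v2, params)
    adm = np.ascontiguousarray(sim.S <= params.C)
    f = _search.longest_from(adm, params.W, params.gap_max)
    Lmax = int(f.max()) if f.size else 0
    if Lmax == 0:
        return AlignmentResult(
            path=None, L=0, gaps=0, apd=math.nan, rmsd=math.nan, ops=math.nan
        )
    sd, sd2 = _diff_block_sums(v1, v2, params.W)
    blocks, rmsd, gaps, n_paths, truncated = _search.best_path(
        adm, f, Lmax, params.W, params.gap_max, sd, sd2, params.path_cap
    )
    path = AlignmentPath(blocks=blocks, W=params.W)
    L = Lmax * params.W
    apd = path_apd(sim, path)
    # the kernel's running-sum RMSD selects the path; recompute the reported
    # value with the direct centered formula (exact 0 for exact matches)
    rmsd = alignment_rmsd(v1, v2, path)
    ops = ops_score(L, int(gaps), float(rmsd))
    p = None
    if model is not None:
        p = model.p_value(ops, L)
    return AlignmentResult(
        path=path,
        L=L,
        gaps=int(gaps),
        apd=apd,
        rmsd=float(rmsd),
        ops=ops,
        p=p,
        n_candidates=int(n_paths),
        truncated=bool(truncated),
    )
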