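"""User-facing workflows: database search, all-vs-all matrix, clustering.

``db_search`` ranks every database profile by the significance of its
optimal alignment to a query.  ``all_vs_all`` builds the symmetric matrix
of pairwise p-values, and ``cluster_export`` turns each profile's row of
p-values into a feature vector, clusters the vectors by Manhattan distance
under Ward's minimum-variance criterion, and emits the linkage table and a
Newick dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .align import AlignmentResult, SearchParams, optimal_alignment
from .calibration import ProbabilityModel
from .profiles import NumericProfile

__all__ = [
    "SearchHit",
    "SearchResults",
    "PMatrix",
    "ClusterExport",
    "db_search",
    "all_vs_all",
    "cluster_export",
]


@dataclass(frozen=True)
class SearchHit:
    """One ranked database match."""

    query_id: str
    target_id: str
    result: AlignmentResult
    rank: int
    p_adjusted: float | None = None


@dataclass(frozen=True)
class SearchResults:
    """Ranked hits plus the search summary (no-match entries are counted,
    not listed)."""

    hits: tuple[SearchHit, ...]
    query_id: str
    n_database: int
    n_matched: int

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def __getitem__(self, k):
        return self.hits[k]


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]


def db_search(
    query: NumericProfile,
    database: Sequence[NumericProfile],
    params: SearchParams,
    model: ProbabilityModel,
    alpha: float | None = None,
) -> SearchResults:
    """Optimally align ``query`` to every database profile and rank by p.

    Hits are sorted by ascending p-value with input order as the stable
    tie-break; entries with no admissible alignment are omitted from the
    hit list but counted in the summary.  When ``alpha`` is given,
    Benjamini-Hochberg adjusted p-values are attached.
    """
    model.check_params(params)
    scored: list[tuple[float, int, str, AlignmentResult]] = []
    for order, target in enumerate(database):
        res = optimal_alignment(query, target, params, model)
        if res.matched:
            scored.append((res.p, order, target.id, res))
    scored.sort(key=lambda t: (t[0], t[1]))
    p_adj = None
    if alpha is not None and scored:
        p_adj = _benjamini_hochberg(np.array([t[0] for t in scored]))
    hits = tuple(
        SearchHit(
            query_id=query.id,
            target_id=target_id,
            result=res,
            rank=rank,
            p_adjusted=None if p_adj is None else float(p_adj[rank - 1]),
        )
        for rank, (_, _, target_id, res) in enumerate(scored, start=1)
    )
    return SearchResults(
        hits=hits,
        query_id=query.id,
        n_database=len(database),
        n_matched=len(hits),
    )


@dataclass(frozen=True)
class PMatrix:
    """Symmetric matrix of pairwise alignment p-values, diagonal 0."""

    ids: tuple[str, ...]
    P: np.ndarray
    invalid: tuple[str, ...] = ()


def all_vs_all(
    profiles: Sequence[NumericProfile],
    params: SearchParams,
    model: ProbabilityModel,
) -> PMatrix:
    """Pairwise p-value matrix over all profiles.

    The matrix is symmetric by the engine's swap symmetry and its diagonal
    is 0 (a self-match is exact).  Pairs with no admissible alignment get
    p = 1 (no evidence of similarity).  Profiles shorter than W are flagged
    invalid and their rows/columns set to NaN.
    """
    model.check_params(params)
    n = len(profiles)
    if n < 2:
        raise ValueError("all_vs_all needs at least 2 profiles")
    valid = [len(p) >= params.W for p in profiles]
    P = np.zeros((n, n))
    for i in range(n):
        if not valid[i]:
            P[i, :] = np.nan
            P[:, i] = np.nan
    for i in range(n):
        if not valid[i]:
            continue
        for j in range(i + 1, n):
            if not valid[j]:
                continue
            res = optimal_alignment(profiles[i], profiles[j], params, model)
            p = res.p if res.matched else 1.0
            P[i, j] = P[j, i] = p
    return PMatrix(
        ids=tuple(p.id for p in profiles),
        P=P,
        invalid=tuple(p.id for p, ok in zip(profiles, valid) if not ok),
    )


@dataclass(frozen=True)
class ClusterExport:
    """Ward/Manhattan clustering of p-value feature vectors."""

    ids: tuple[str, ...]
    linkage: np.ndarray
    newick: str


def cluster_export(pmat: PMatrix) -> ClusterExport:
    """Cluster profiles by their p-value vectors; emit linkage + Newick.

    Each profile's feature vector is its row of p-values against all
    profiles; pairwise Manhattan distances are agglomerated under Ward's
    minimum-variance criterion.
    """
    if pmat.invalid:
        raise ValueError(f"invalid rows present: {list(pmat.invalid)}")
    if not np.all(np.isfinite(pmat.P)):
        raise ValueError("p-value matrix contains non-finite entries")
    dist = pdist(pmat.P, metric="cityblock")
    Z = linkage(dist, method="ward")
    newick = _linkage_to_newick(Z, pmat.ids)
    return ClusterExport(ids=pmat.ids, linkage=Z, newick=newick)


def _linkage_to_newick(Z: np.ndarray, ids: Sequence[str]) -> str:
    import io

    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, list(ids))
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
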