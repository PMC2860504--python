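"""Node centrality measures on voxel-pair similarity matrices.

Eigenvector centrality is the per-voxel entry of the unit-norm dominant
eigenvector of the (symmetric, non-negative, irreducible) similarity matrix,
computed by power iteration.  For the factored scaled-correlation form the
matrix is never materialized, so whole-brain problems fit in memory.

Degree centrality is the off-diagonal row sum.  Betweenness centrality
(Brandes accumulation) is provided for small regions only; it is
intractable at voxel scale and refuses large inputs unless forced.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityMatrix, factored_matvec

__all__ = [
    "CentralityMap", "degree_centrality", "power_iteration",
    "eigenvector_centrality", "betweenness_centrality", "factored_matvec",
    "ConvergenceError", "ReducibleMatrixError",
]

logger = logging.getLogger(__name__)

#: betweenness refuses matrices larger than this unless force=True
BETWEENNESS_NODE_LIMIT = 5000

#: minimum edge length in weighted betweenness (guards zero-length edges)
_MIN_EDGE_LENGTH = 1e-12


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge within max_iter."""

    def __init__(self, iterations: int, residual: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"power iteration did not converge in {iterations} iterations "
            f"(last max-norm change {residual:.3g})")


class ReducibleMatrixError(ValueError):
    """Similarity matrix violates the off-diagonal support precondition."""


@dataclass
class CentralityMap:
    """Per-voxel centrality scores with provenance.

    ``iterations`` and ``eigenvalue`` are populated for the eigenvector
    method only.
    """

    values: np.ndarray
    method: str
    metric_tag: str = ""
    iterations: int | None = None
    eigenvalue: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be a 1D vector")
        if self.values.min() < 0:
            raise ValueError("centrality values must be non-negative")


def degree_centrality(a: SimilarityMatrix) -> CentralityMap:
    """Off-diagonal row sums: d_i = sum_{j != i} a_ij."""
    ones = np.ones(a.n)
    values = a.matvec(ones) - a.diagonal()
    values = np.clip(values, 0.0, None)
    return CentralityMap(values=values, method="degree", metric_tag=a.metric_tag)


def power_iteration(matvec, n: int, tol: float = 1e-9, max_iter: int = 1000):
    """Dominant eigenpair of a symmetric non-negative operator.

    Starts from the uniform positive vector 1/sqrt(n) (deterministic and
    never orthogonal to the Perron vector).  Converges when the max-norm
    change of the normalized iterate drops below ``tol``.

    Returns
    -------
    (vector, eigenvalue, iterations)
        Unit-norm non-negative vector, the Rayleigh quotient at convergence,
        and the number of iterations used.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if tol <= 0:
        raise ValueError("tol must be positive")
    v = np.full(n, 1.0 / np.sqrt(n))
    delta = np.inf
    for it in range(1, max_iter + 1):
        w = np.asarray(matvec(v), dtype=float)
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("operator maps the positive start vector to zero")
        w = w / norm
        delta = float(np.max(np.abs(w - v)))
        v = w
        if delta < tol:
            eigenvalue = float(v @ np.asarray(matvec(v), dtype=float))
            return v, eigenvalue, it
    raise ConvergenceError(max_iter, delta)


def eigenvector_centrality(a: SimilarityMatrix, tol: float = 1e-9,
                           max_iter: int = 1000) -> CentralityMap:
    """Entries of the unit-norm dominant eigenvector of ``a``.

    Uniqueness follows from Perron-Frobenius for irreducible non-negative
    matrices; the off-diagonal support condition (at least one non-zero
    off-diagonal entry in each row and column) is checked up front for
    dense matrices.  The result is identical for dense and factored forms
    of the same matrix up to floating-point error.
    """
    if not a.has_offdiagonal_support():
        raise ReducibleMatrixError(
            "similarity matrix has a row with no off-diagonal support; "
            "the dominant eigenvector is not unique — filter the mask "
            "(remove isolated voxels) and retry")
    v, eigenvalue, iterations = power_iteration(a.matvec, a.n, tol=tol,
                                                max_iter=max_iter)
    if v.sum() < 0:  # Perron vector sign convention
        v = -v
    if v.min() < -1e-10:
        raise RuntimeError(
            f"dominant eigenvector has negative entries (min {v.min():.3g}); "
            "input is not a valid non-negative similarity matrix")
    v = np.clip(v, 0.0, None)
    if eigenvalue <= 0:
        raise RuntimeError(f"non-positive dominant eigenvalue {eigenvalue}")
    return CentralityMap(values=v, method="eigenvector",
                         metric_tag=a.metric_tag, iterations=iterations,
                         eigenvalue=eigenvalue)


# ---------------------------------------------------------------------------
# betweenness (small-ROI only)
# ---------------------------------------------------------------------------

def _adjacency(a: SimilarityMatrix, edge_threshold: float, weighting: str):
    dense = a.materialize().copy()
    np.fill_diagonal(dense, 0.0)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(a.n)]
    rows, cols = np.nonzero(dense > edge_threshold)
    for i, j in zip(rows.tolist(), cols.tolist()):
        if weighting == "distance":
            length = max(1.0 - dense[i, j], _MIN_EDGE_LENGTH)
        else:
            length = 1.0
        adj[i].append((j, length))
    return adj


def betweenness_centrality(a: SimilarityMatrix, edge_threshold: float = 0.0,
                           weighting: str = "distance",
                           node_limit: int = BETWEENNESS_NODE_LIMIT,
                           force: bool = False) -> CentralityMap:
    """Normalized shortest-path betweenness via Brandes' accumulation.

    Edges exist where the (thresholded) similarity exceeds
    ``edge_threshold``.  ``weighting="distance"`` converts similarity to
    edge length ``1 - a_ij``; ``weighting="unweighted"`` uses unit lengths.
    Scores are normalized by (n-1)(n-2)/2, the number of node pairs
    excluding the scored node, so they lie in [0, 1].  Disconnected pairs
    contribute nothing.
    """
    if weighting not in ("distance", "unweighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if not 0.0 <= edge_threshold <= 1.0:
        raise ValueError("edge_threshold must lie in [0, 1]")
    n = a.n
    if n > node_limit and not force:
        raise ValueError(
            f"betweenness on {n} nodes exceeds the soft limit {node_limit} "
            "(computationally impracticable at voxel scale); pass force=True "
            "to override")
    if n < 3:
        return CentralityMap(values=np.zeros(n), method="betweenness",
                             metric_tag=a.metric_tag)
    adj = _adjacency(a, edge_threshold, weighting)
    cb = np.zeros(n)
    for s in range(n):
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, np.inf)
        dist[s] = 0.0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        if weighting == "distance":
            done = np.zeros(n, dtype=bool)
            heap: list[tuple[float, int]] = [(0.0, s)]
            while heap:
                d, v = heapq.heappop(heap)
                if done[v]:
                    continue
                done[v] = True
                order.append(v)
                for w, length in adj[v]:
                    nd = d + length
                    if nd < dist[w]:
                        dist[w] = nd
                        sigma[w] = sigma[v]
                        preds[w] = [v]
                        heapq.heappush(heap, (nd, w))
                    elif nd == dist[w] and not done[w]:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
        else:
            queue = [s]
            head = 0
            while head < len(queue):
                v = queue[head]
                head += 1
                order.append(v)
                for w, _ in adj[v]:
                    if dist[w] == np.inf:
                        dist[w] = dist[v] + 1
                        queue.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
        delta = np.zeros(n)
        for v in reversed(order):
            for p in preds[v]:
                delta[p] += sigma[p] / sigma[v] * (1.0 + delta[v])
            if v != s:
                cb[v] += delta[v]
    # each unordered (s, t) pair was counted twice in the undirected sweep
    cb /= 2.0
    cb /= (n - 1) * (n - 2) / 2.0
    values = np.clip(cb, 0.0, 1.0)
    return CentralityMap(values=values, method="betweenness",
                         metric_tag=a.metric_tag)
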