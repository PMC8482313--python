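"""Count-threshold binarization and global efficiency.

Connectivity matrices never contain exact zeros, so graphs are formed by
keeping a fixed *count* of the strongest absolute off-diagonal entries (a
proportional threshold).  The budget theta counts directed off-diagonal
entries — 240 for a 16-channel matrix — so theta in the 27..48 range keeps
the strongest 11–20% of entries; floor(theta/2) undirected edges are
retained.  Global efficiency is the Latora–Marchiori average of inverse
shortest-path hop counts over ordered node pairs, with unreachable pairs
contributing zero: 1.0 for a complete graph, 0.0 for an empty one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "BinaryAdjacency",
    "EfficiencyValue",
    "binarize",
    "global_efficiency",
    "global_efficiency_oracle",
    "ranked_pairs",
    "hop_distances_batch",
    "global_efficiency_batch",
]


@dataclass
class BinaryAdjacency:
    """Symmetric 0/1 adjacency with zero diagonal, from a count threshold."""

    values: np.ndarray
    theta: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if (np.diag(v) != 0).any():
            raise ValueError("adjacency diagonal must be zero")
        if (v != v.T).any():
            raise ValueError("adjacency must be symmetric")
        self.values = v.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.values.sum()) // 2


@dataclass
class EfficiencyValue:
    """Global efficiency in [0, 1] plus the hop-count distance matrix."""

    ge: float
    distances: np.ndarray


def ranked_pairs(matrix: np.ndarray) -> list[tuple[int, int]]:
    """Upper-triangle pairs ranked by descending absolute value.

    Ties are broken lexicographically by (i, j), which makes the ranking —
    and everything thresholded from it — deterministic.
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = np.abs(m[iu, ju])
    order = np.argsort(-vals, kind="stable")  # stable keeps (i, j) order on ties
    return [(int(iu[k]), int(ju[k])) for k in order]


def binarize(fc, theta: int) -> BinaryAdjacency:
    """Keep the floor(theta/2) strongest undirected pairs of ``|fc|``.

    ``theta`` is the directed-entry budget; the diagonal never participates.
    A budget beyond the available 2*(n choose 2) entries is clamped with a
    warning.
    """
    m = getattr(fc, "values", fc)
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input matrix must be square")
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("input matrix must be symmetric")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    n = m.shape[0]
    max_theta = n * (n - 1)
    if theta > max_theta:
        warnings.warn(
            f"theta={theta} exceeds the {max_theta} available off-diagonal entries; clamping",
            stacklevel=2,
        )
        theta = max_theta
    k = theta // 2
    adj = np.zeros((n, n), dtype=np.uint8)
    for i, j in ranked_pairs(m)[:k]:
        adj[i, j] = adj[j, i] = 1
    return BinaryAdjacency(adj, theta=theta)


def _inverse_distance_sum(d: np.ndarray) -> float:
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d) & (d > 0)
    return float((1.0 / d[finite]).sum())


def global_efficiency(adj: BinaryAdjacency | np.ndarray) -> EfficiencyValue:
    """GE = mean of 1/d_ij over ordered pairs i != j; unreachable pairs add 0.

    Hop-count distances come from breadth-first search on the unweighted
    graph.
    """
    a = adj.values if isinstance(adj, BinaryAdjacency) else BinaryAdjacency(np.asarray(adj)).values
    n = a.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    d = shortest_path(a.astype(float), method="D", unweighted=True, directed=False)
    ge = _inverse_distance_sum(d) / (n * (n - 1))
    return EfficiencyValue(ge=ge, distances=d)


def global_efficiency_oracle(adj: BinaryAdjacency | np.ndarray) -> EfficiencyValue:
    """Independent reference implementation via hand-rolled Floyd–Warshall.

    Used to cross-check :func:`global_efficiency`; same conventions
    (hop counts, unreachable pairs contribute zero).
    """
    a = adj.values if isinstance(adj, BinaryAdjacency) else BinaryAdjacency(np.asarray(adj)).values
    n = a.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[a > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    ge = _inverse_distance_sum(d) / (n * (n - 1))
    return EfficiencyValue(ge=ge, distances=d)


# ---------------------------------------------------------------------------
# Batched kernels used by the component search (many small graphs at once)
# ---------------------------------------------------------------------------

def hop_distances_batch(adj: np.ndarray) -> np.ndarray:
    """Hop-count distance matrices for a stack of graphs, shape (m, n, n).

    Breadth-first expansion through boolean matrix products; 0 off the
    diagonal marks an unreachable pair.
    """
    a = np.asarray(adj, dtype=bool)
    m, n, _ = a.shape
    af = a.astype(np.float32)  # BLAS batched matmul beats boolean products
    dist = np.where(a, 1, 0).astype(np.int16)
    reach = a.copy()
    eye = np.eye(n, dtype=bool)
    for hop in range(2, n):
        new_reach = np.matmul(reach.astype(np.float32), af) > 0
        newly = new_reach & ~reach & ~eye
        if not newly.any():
            break
        dist[newly] = hop
        reach |= new_reach
    return dist


def global_efficiency_batch(adj: np.ndarray) -> np.ndarray:
    """Global efficiency for a stack of graphs, shape (m,)."""
    dist = hop_distances_batch(adj)
    n = dist.shape[-1]
    inv = np.zeros(dist.shape)
    nz = dist > 0
    inv[nz] = 1.0 / dist[nz]
    return inv.sum(axis=(1, 2)) / (n * (n - 1))
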