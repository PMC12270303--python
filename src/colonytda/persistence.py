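"""Vietoris-Rips persistent homology in dimensions 0 and 1.

A point cloud is filtered by pairwise Euclidean distance: an edge enters the
complex when the distance between its endpoints reaches the filtration value
``r``, and a triangle enters at the largest of its three edge lengths.  The
barcode records, per homology dimension, the interval of filtration values
over which each class lives: dimension 0 tracks connected components,
dimension 1 tracks loops ("holes" between cells).

Dimension 0 is computed by a union-find sweep over edges in increasing
order (the finite deaths are exactly the Euclidean minimum-spanning-tree
edge weights, with the elder rule deciding which component dies).
Dimension 1 is computed by column reduction of the triangle boundary matrix
over GF(2), with columns stored as Python integer bitsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PersistenceBar",
    "PersistenceDiagram",
    "pairwise_distances",
    "h0_barcode",
    "h1_barcode",
    "compute_diagram",
]


@dataclass(frozen=True, order=True)
class PersistenceBar:
    """One barcode interval: a homology class born at ``birth`` dying at ``death``.

    ``death`` is ``math.inf`` for essential classes (the surviving connected
    component, or a loop still open at the filtration threshold).
    """

    dim: int
    birth: float
    death: float

    def __post_init__(self) -> None:
        if self.dim not in (0, 1):
            raise ValueError(f"only dimensions 0 and 1 are supported, got {self.dim}")
        if not (self.birth >= 0 and math.isfinite(self.birth)):
            raise ValueError(f"birth must be finite and >= 0, got {self.birth}")
        if not self.death > self.birth:
            raise ValueError(f"death must exceed birth, got [{self.birth}, {self.death})")

    @property
    def persistence(self) -> float:
        return self.death - self.birth


@dataclass
class PersistenceDiagram:
    """Barcode of a single point cloud: bars in dims 0 and 1 plus the threshold used."""

    bars: list[PersistenceBar]
    threshold: float
    colony_id: str | None = None
    timepoint: int | None = None

    def bars_in_dim(self, dim: int) -> list[PersistenceBar]:
        return [b for b in self.bars if b.dim == dim]

    def finite_bars(self, dim: int) -> list[PersistenceBar]:
        return [b for b in self.bars if b.dim == dim and math.isfinite(b.death)]


def pairwise_distances(points: np.ndarray) -> np.ndarray:
    """Full symmetric Euclidean distance matrix of an (n, 2) coordinate array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("need an (n, d) array with n >= 1")
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    if pts.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(pts))


def _validate_dm(dm: np.ndarray) -> np.ndarray:
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(dm)) or np.any(dm < 0):
        raise ValueError("distance matrix entries must be finite and non-negative")
    if np.any(np.diag(dm) != 0) or not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return dm


def _sorted_edges(dm: np.ndarray, threshold: float | None = None):
    """Edges (i < j) with weight <= threshold, sorted by (weight, i, j).

    Returns (ei, ej, w) arrays; the sort order fixes all tie-breaking.
    """
    n = dm.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = dm[iu, ju]
    if threshold is not None:
        keep = w <= threshold
        iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.lexsort((ju, iu, w))
    return iu[order], ju[order], w[order]


class _UnionFind:
    """Union-find keeping the minimum original point index per component.

    The minimum index identifies the "elder" component: all vertices are born
    at filtration 0 simultaneously, so age ties are broken by point index.
    """

    __slots__ = ("parent", "min_idx")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.min_idx = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        # elder survives: attach the component with the larger min index
        if self.min_idx[ra] > self.min_idx[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        return True


def h0_barcode(dm: np.ndarray) -> list[PersistenceBar]:
    """Dimension-0 bars: one per point, born at 0; elder rule at each merge.

    Finite deaths form the multiset of Euclidean MST edge weights.  Zero
    persistence bars (duplicate points) are dropped.  Exactly one bar is
    essential ([0, inf)).
    """
    dm = _validate_dm(dm)
    n = dm.shape[0]
    bars: list[PersistenceBar] = []
    uf = _UnionFind(n)
    ei, ej, w = _sorted_edges(dm)
    for a, b, d in zip(ei, ej, w):
        if uf.union(int(a), int(b)) and d > 0:
            bars.append(PersistenceBar(0, 0.0, float(d)))
    bars.append(PersistenceBar(0, 0.0, math.inf))
    return bars


def _triangles(dm: np.ndarray, threshold: float):
    """All triangles i<j<k of diameter <= threshold, with filtration values.

    Returns (tri, val): an (m, 3) int array and an (m,) float array, sorted by
    (value, lexicographic vertex tuple) for deterministic reduction order.
    """
    n = dm.shape[0]
    adj = (dm <= threshold) & ~np.eye(n, dtype=bool)
    tris_i, tris_j, tris_k = [], [], []
    idx = np.arange(n)
    for i in range(n - 2):
        nbr = idx[(idx > i) & adj[i]]
        if nbr.size < 2:
            continue
        sub = adj[np.ix_(nbr, nbr)]
        jj, kk = np.nonzero(np.triu(sub, k=1))
        if jj.size:
            tris_i.append(np.full(jj.size, i))
            tris_j.append(nbr[jj])
            tris_k.append(nbr[kk])
    if not tris_i:
        return np.empty((0, 3), dtype=int), np.empty(0)
    ti = np.concatenate(tris_i)
    tj = np.concatenate(tris_j)
    tk = np.concatenate(tris_k)
    val = np.maximum(np.maximum(dm[ti, tj], dm[ti, tk]), dm[tj, tk])
    order = np.lexsort((tk, tj, ti, val))
    return np.stack([ti[order], tj[order], tk[order]], axis=1), val[order]


def _reduce_python(tri_cols: np.ndarray, tval: np.ndarray, n_edges: int):
    """Column reduction with Python-int bitsets; returns (pivot_edges, pivot_deaths)."""
    pivot_col: dict[int, int] = {}
    pivot_val: dict[int, float] = {}
    for t in range(tri_cols.shape[0]):
        a, b, c = tri_cols[t]
        col = (1 << int(a)) | (1 << int(b)) | (1 << int(c))
        while col:
            low = col.bit_length() - 1
            if low not in pivot_col:
                pivot_col[low] = col
                pivot_val[low] = float(tval[t])
                break
            col ^= pivot_col[low]
    edges = np.fromiter(pivot_val.keys(), dtype=np.int64, count=len(pivot_val))
    deaths = np.fromiter(pivot_val.values(), dtype=float, count=len(pivot_val))
    return edges, deaths


def _make_reduce_numba():
    """Compile the bitset reduction with numba; None when numba is unavailable."""
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is an optional accelerator
        return None

    @njit(cache=True)
    def reduce_numba(tri_cols, tval, n_edges):  # pragma: no cover - compiled
        words = (n_edges + 63) // 64
        pivot_bits = np.zeros((n_edges, words), dtype=np.uint64)
        pivot_death = np.full(n_edges, -1.0)
        has_pivot = np.zeros(n_edges, dtype=np.bool_)
        col = np.zeros(words, dtype=np.uint64)
        m = tri_cols.shape[0]
        for t in range(m):
            e0, e1, e2 = tri_cols[t, 0], tri_cols[t, 1], tri_cols[t, 2]
            top = max(e0, max(e1, e2)) >> 6
            col[: top + 1] = 0  # only words up to the max row are ever touched
            col[e0 >> 6] ^= np.uint64(1) << np.uint64(e0 & 63)
            col[e1 >> 6] ^= np.uint64(1) << np.uint64(e1 & 63)
            col[e2 >> 6] ^= np.uint64(1) << np.uint64(e2 & 63)
            w = words - 1
            while w >= 0:
                if col[w] == 0:
                    w -= 1
                    continue
                # highest set bit in word w
                bit = 63
                word = col[w]
                while (word >> np.uint64(bit)) & np.uint64(1) == 0:
                    bit -= 1
                low = (w << 6) + bit
                if not has_pivot[low]:
                    pivot_bits[low] = col
                    pivot_death[low] = tval[t]
                    has_pivot[low] = True
                    break
                for k in range(w + 1):
                    col[k] ^= pivot_bits[low, k]
        edges = np.flatnonzero(has_pivot)
        return edges, pivot_death[edges]

    return reduce_numba


_reduce_numba = _make_reduce_numba()


def h1_barcode(dm: np.ndarray, threshold: float) -> list[PersistenceBar]:
    """Dimension-1 bars from GF(2) reduction of the triangle boundary matrix.

    Simplices are restricted to filtration value <= threshold; a loop still
    open at the threshold is reported with infinite death.  Row indices are
    edge positions in filtration order, so the pivot (lowest nonzero row) of a
    reduced triangle column is the positive edge whose cycle that triangle
    fills; the pair (edge value, triangle value) is the bar.  Zero-persistence
    bars are dropped.
    """
    dm = _validate_dm(dm)
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    ei, ej, ew = _sorted_edges(dm, threshold)
    n_edges = ei.size
    if n_edges == 0:
        return []

    # classify edges: negative edges kill components (MST), positive create cycles
    uf = _UnionFind(dm.shape[0])
    positive = np.zeros(n_edges, dtype=bool)
    for e in range(n_edges):
        if not uf.union(int(ei[e]), int(ej[e])):
            positive[e] = True

    tri, tval = _triangles(dm, threshold)
    # map triangle vertex triples to edge row indices (rows in filtration order)
    n = dm.shape[0]
    edge_row = np.full((n, n), -1, dtype=np.int64)
    edge_row[ei, ej] = np.arange(n_edges)
    edge_row[ej, ei] = np.arange(n_edges)
    tri_cols = np.stack(
        [edge_row[tri[:, 0], tri[:, 1]],
         edge_row[tri[:, 0], tri[:, 2]],
         edge_row[tri[:, 1], tri[:, 2]]],
        axis=1,
    ) if tri.shape[0] else np.empty((0, 3), dtype=np.int64)

    reduce_fn = _reduce_numba if _reduce_numba is not None else _reduce_python
    pivot_edges, pivot_deaths = reduce_fn(tri_cols, np.asarray(tval, dtype=float), n_edges)
    death_of = dict(zip(pivot_edges.tolist(), pivot_deaths.tolist()))

    bars: list[PersistenceBar] = []
    for e in np.nonzero(positive)[0]:
        e = int(e)
        birth = float(ew[e])
        death = death_of.get(e, math.inf)
        if death > birth:
            bars.append(PersistenceBar(1, birth, death))
    bars.sort()
    return bars


def compute_diagram(
    points: np.ndarray,
    threshold: float,
    colony_id: str | None = None,
    timepoint: int | None = None,
) -> PersistenceDiagram:
    """Dimension 0 and 1 barcode of a point cloud at the given Rips threshold."""
    dm = pairwise_distances(points)
    bars = h0_barcode(dm) + h1_barcode(dm, threshold)
    return PersistenceDiagram(bars, float(threshold), colony_id, timepoint)
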