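"""Candidate scale grids and exact k-nearest-neighbor tables.

The scale of a local neighborhood is its neighbor count k.  Candidate
scales form an arithmetic sequence (the default protocol is k = 10..100 in
steps of 10).  Neighbor queries are exact (kd-tree), the query point is
excluded from its own neighbor list, and lists are sorted by ascending
distance with ties broken by ascending point index so results are
platform-independent.  Because one sorted query serves every scale, the
neighbor list at scale k is the length-k prefix of the list at any larger
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import LabeledPointCloud

__all__ = ["ScaleGrid", "NeighborhoodTable", "build_scale_grid", "query_neighbors"]


@dataclass(frozen=True)
class ScaleGrid:
    """Ordered candidate neighborhood sizes."""

    k_values: tuple[int, ...]

    def __post_init__(self) -> None:
        ks = tuple(int(k) for k in self.k_values)
        object.__setattr__(self, "k_values", ks)
        if len(ks) == 0:
            raise ValueError("scale grid must contain at least one k")
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError(f"k_values must be strictly increasing; got {ks}")
        if ks[0] < 3:
            raise ValueError("minimum scale must be >= 3 (3D covariance needs >= 3 neighbors)")

    def __len__(self) -> int:
        return len(self.k_values)

    def __iter__(self):
        return iter(self.k_values)

    @property
    def k_max(self) -> int:
        return self.k_values[-1]


def build_scale_grid(k_min: int = 10, k_max: int = 100, step: int = 10) -> ScaleGrid:
    """Arithmetic candidate-scale sequence k_min, k_min+step, ..., <= k_max."""
    if k_min < 3:
        raise ValueError("k_min must be >= 3")
    if k_max < k_min:
        raise ValueError(f"k_max ({k_max}) must be >= k_min ({k_min})")
    if step < 1:
        raise ValueError("step must be >= 1")
    return ScaleGrid(tuple(range(k_min, k_max + 1, step)))


@dataclass
class NeighborhoodTable:
    """Exact nearest neighbors of each query point up to the largest scale.

    ``indices[i, :k]`` are the k nearest neighbors of query point i
    (ascending distance, excluding the point itself) and
    ``distances[i, k-1]`` is the neighborhood radius r_k at scale k.
    """

    query_indices: np.ndarray       # (n_q,)
    grid: ScaleGrid
    indices: np.ndarray             # (n_q, k_max) int
    distances: np.ndarray           # (n_q, k_max) float

    def neighbors_at(self, k: int) -> np.ndarray:
        if k > self.grid.k_max:
            raise ValueError(f"scale {k} exceeds table maximum {self.grid.k_max}")
        return self.indices[:, :k]

    def radius_at(self, k: int) -> np.ndarray:
        """Distance to the k-th neighbor (the 3D neighborhood radius)."""
        if k > self.grid.k_max:
            raise ValueError(f"scale {k} exceeds table maximum {self.grid.k_max}")
        return self.distances[:, k - 1]


def query_neighbors(
    cloud: LabeledPointCloud,
    query_indices: np.ndarray | None = None,
    grid: ScaleGrid | None = None,
    workers: int = 1,
) -> NeighborhoodTable:
    """Exact k-NN lists for the queried points at every scale of the grid.

    A single kd-tree query at ``k_max`` serves all scales (prefix
    property).  Distance ties are re-sorted by point index, and the query
    point itself is removed from its list.
    """
    if grid is None:
        grid = build_scale_grid()
    n = len(cloud)
    if grid.k_max > n - 1:
        raise ValueError(
            f"largest scale k={grid.k_max} needs at least {grid.k_max + 1} "
            f"points; cloud has {n}"
        )
    if query_indices is None:
        query_indices = np.arange(n, dtype=np.int64)
    else:
        query_indices = np.asarray(query_indices, dtype=np.int64)

    tree = cKDTree(cloud.coords)
    # k_max + 1 so the self-point can be dropped.
    dist, idx = tree.query(cloud.coords[query_indices], k=grid.k_max + 1,
                           workers=workers)

    n_q = len(query_indices)
    self_pos = idx == query_indices[:, None]
    # The self point is at distance 0; if an exact duplicate displaced it
    # beyond the returned window, drop the first zero-distance entry instead.
    no_self = ~self_pos.any(axis=1)
    if no_self.any():
        first = np.zeros_like(self_pos)
        first[no_self, 0] = True
        self_pos |= first
    # Keep exactly one drop per row (first occurrence).
    keep = np.ones_like(self_pos)
    drop_col = np.argmax(self_pos, axis=1)
    keep[np.arange(n_q), drop_col] = False
    idx = idx[keep].reshape(n_q, grid.k_max)
    dist = dist[keep].reshape(n_q, grid.k_max)

    # Deterministic tie-break: sort each row by (distance, index).
    rows = np.repeat(np.arange(n_q), grid.k_max)
    order = np.lexsort((idx.ravel(), dist.ravel(), rows))
    idx = idx.ravel()[order].reshape(n_q, grid.k_max)
    dist = dist.ravel()[order].reshape(n_q, grid.k_max)

    return NeighborhoodTable(
        query_indices=query_indices, grid=grid, indices=idx, distances=dist
    )
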