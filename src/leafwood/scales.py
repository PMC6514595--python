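"""Eigen-entropy of local neighborhoods and optimal-scale selection.

For a point q and scale k, PCA of the neighborhood {q} union its k nearest
neighbors yields covariance eigenvalues lambda1 <= lambda2 <= lambda3.
Normalizing, alpha_i = lambda_i / sum(lambda), the eigen-entropy

    E_alpha = -(alpha1 ln alpha1 + alpha2 ln alpha2 + alpha3 ln alpha3)

measures how ambiguous the local dimensionality is: E_alpha is 0 for a
perfect line (alpha = (0,0,1)) and ln 3 for isotropic scatter
(alpha = (1/3,1/3,1/3)).  The *optimal* scale of a point is the candidate
k minimizing E_alpha; the *multi-optimal* scales are the m candidates with
the m smallest entropies — each point gets its own set.  The *multi-scale*
baseline instead fixes one random size-m subset of the grid for all points.

Conventions: population covariance (divide by the point count);
0 ln 0 = 0; a neighborhood of coincident points (all eigenvalues zero) is
assigned alpha = (1/3,1/3,1/3) and E = ln 3 so it is never preferred as
"optimal"; entropy ties across scales break toward smaller k; selected
scales are reported in ascending k order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import LabeledPointCloud
from .neighbors import NeighborhoodTable, ScaleGrid, query_neighbors

__all__ = [
    "EigenTriple",
    "EntropyTable",
    "ScaleSelection",
    "eigen_decompose",
    "eigen_entropy",
    "entropy_table",
    "select_scales",
]

LN3 = float(np.log(3.0))

# Relative threshold below which lambda1 ~ lambda2 counts as degenerate
# (perfectly linear neighborhood) for the normal-vector convention.
_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class EigenTriple:
    """Covariance eigenvalues of one neighborhood, ascending, plus normal.

    ``alphas`` are the eigenvalues normalized to sum to one (the
    dimensionality "probabilities"); ``normal`` is the unit eigenvector of
    the smallest eigenvalue with non-negative z component.
    """

    lambdas: np.ndarray   # (3,) ascending, m^2
    alphas: np.ndarray    # (3,) sum to 1
    normal: np.ndarray    # (3,) unit


def _batched_cov_eigh(neigh: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of population covariances of (n, p, 3) stacks."""
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("npi,npj->nij", centered, centered) / neigh.shape[1]
    lam, vec = np.linalg.eigh(cov)          # ascending eigenvalues
    lam = np.clip(lam, 0.0, None)           # clip tiny negative round-off
    return lam, vec


def _normals_from_eigh(lam: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Smallest-eigenvalue eigenvectors with deterministic degeneracy rules.

    When lambda1 ~ lambda2 the normal is only defined up to the plane
    orthogonal to the lambda3 axis; the representative with maximal |z| is
    chosen.  Fully coincident neighborhoods get (0, 0, 1).
    """
    n = lam.shape[0]
    normal = vec[:, :, 0].copy()
    l1, l2, l3 = lam[:, 0], lam[:, 1], lam[:, 2]

    zero = l3 <= 0.0
    degen = (~zero) & ((l2 - l1) <= _DEGENERATE_RTOL * l3)
    if degen.any():
        v3 = vec[degen, :, 2]
        ez = np.zeros_like(v3)
        ez[:, 2] = 1.0
        proj = ez - (v3[:, 2:3]) * v3       # ez minus its component along v3
        norms = np.linalg.norm(proj, axis=1)
        ok = norms > 1e-12
        cand = normal[degen]
        cand[ok] = proj[ok] / norms[ok, None]
        normal[degen] = cand
    if zero.any():
        normal[zero] = (0.0, 0.0, 1.0)

    # Sign convention: non-negative z; if z == 0, first nonzero component > 0.
    flip = normal[:, 2] < 0.0
    z0 = normal[:, 2] == 0.0
    flip |= z0 & (normal[:, 0] < 0.0)
    flip |= z0 & (normal[:, 0] == 0.0) & (normal[:, 1] < 0.0)
    normal[flip] *= -1.0
    # Renormalize (eigh vectors are unit, but keep it exact for the frozen API).
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    return normal


def _alphas_from_lambdas(lam: np.ndarray) -> np.ndarray:
    total = lam.sum(axis=-1, keepdims=True)
    alphas = np.full_like(lam, 1.0 / 3.0)
    pos = total[..., 0] > 0.0
    alphas[pos] = lam[pos] / total[pos]
    return alphas


def eigen_decompose(neighborhood_coords: np.ndarray) -> EigenTriple:
    """PCA of one neighborhood (>= 3 points) about its centroid."""
    pts = np.asarray(neighborhood_coords, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (p, 3) coordinates; got {pts.shape}")
    if pts.shape[0] < 3:
        raise ValueError("eigen decomposition needs at least 3 points")
    lam, vec = _batched_cov_eigh(pts[None])
    normal = _normals_from_eigh(lam, vec)[0]
    return EigenTriple(
        lambdas=lam[0], alphas=_alphas_from_lambdas(lam)[0], normal=normal
    )


def _entropy_from_alphas(alphas: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(alphas > 0.0, alphas * np.log(alphas), 0.0)
    return np.clip(-terms.sum(axis=-1), 0.0, LN3)


def eigen_entropy(triple_or_alphas) -> float:
    """Shannon entropy (nats) of the normalized eigenvalues; in [0, ln 3]."""
    if isinstance(triple_or_alphas, EigenTriple):
        alphas = triple_or_alphas.alphas
    else:
        alphas = np.asarray(triple_or_alphas, dtype=np.float64)
    return float(_entropy_from_alphas(alphas))


@dataclass
class EntropyTable:
    """Eigen-entropy per query point (rows) and candidate scale (columns)."""

    query_indices: np.ndarray   # (n_q,)
    grid: ScaleGrid
    values: np.ndarray          # (n_q, n_scales), nats

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.values,
            index=pd.Index(self.query_indices, name="point"),
            columns=pd.Index(list(self.grid), name="k"),
        )


def entropy_table(
    cloud: LabeledPointCloud,
    query_indices: np.ndarray | None = None,
    grid: ScaleGrid | None = None,
    neighborhoods: NeighborhoodTable | None = None,
) -> EntropyTable:
    """Eigen-entropies for every queried point at every candidate scale."""
    if neighborhoods is None:
        neighborhoods = query_neighbors(cloud, query_indices, grid)
    grid = neighborhoods.grid
    q = neighborhoods.query_indices
    values = np.empty((len(q), len(grid)), dtype=np.float64)
    for j, k in enumerate(grid):
        nbr = neighborhoods.neighbors_at(k)
        neigh = np.concatenate(
            [cloud.coords[q][:, None, :], cloud.coords[nbr]], axis=1
        )
        lam, _ = _batched_cov_eigh(neigh)
        values[:, j] = _entropy_from_alphas(_alphas_from_lambdas(lam))
    return EntropyTable(query_indices=q, grid=grid, values=values)


@dataclass
class ScaleSelection:
    """Per-point selected scales (ascending k) under one strategy.

    ``selected[i]`` holds the k values used for query point i.  For the
    random multi-scale baseline every row is identical.
    """

    method: str                 # optimal | multi_optimal | multi_scale_random
    m: int
    query_indices: np.ndarray   # (n_q,)
    selected: np.ndarray        # (n_q, m) int, ascending within each row
    grid: ScaleGrid

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.selected,
            index=pd.Index(self.query_indices, name="point"),
            columns=[f"scale_slot_{j}" for j in range(self.selected.shape[1])],
        )


def select_scales(
    table: EntropyTable,
    method: str = "multi_optimal",
    m: int = 5,
    seed: int | None = None,
) -> ScaleSelection:
    """Choose m scales per point from the entropy table.

    ``multi_optimal``: the m grid scales with smallest entropy per point
    (ties toward smaller k).  ``optimal``: multi_optimal with m forced to 1.
    ``multi_scale_random``: one seeded size-m subset of the grid, shared by
    all points.
    """
    grid = table.grid
    ks = np.asarray(list(grid), dtype=np.int64)
    n_scales = len(ks)
    if method == "optimal":
        m = 1
    if not 1 <= m <= n_scales:
        raise ValueError(f"m must be in [1, {n_scales}]; got {m}")

    n_q = len(table.query_indices)
    if method in ("optimal", "multi_optimal"):
        # Stable argsort on rows already ordered by ascending k implements
        # the smaller-k tie-break for free.
        order = np.argsort(table.values, axis=1, kind="stable")[:, :m]
        selected = np.sort(ks[order], axis=1)
    elif method == "multi_scale_random":
        if seed is None:
            raise ValueError("multi_scale_random requires a seed")
        rng = np.random.default_rng(seed)
        subset = np.sort(rng.choice(ks, size=m, replace=False))
        selected = np.broadcast_to(subset, (n_q, m)).copy()
    else:
        raise ValueError(
            f"unknown method {method!r}; expected optimal, multi_optimal "
            f"or multi_scale_random"
        )
    return ScaleSelection(
        method=method, m=m, query_indices=table.query_indices,
        selected=selected, grid=grid,
    )
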