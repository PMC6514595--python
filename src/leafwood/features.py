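"""The 12 geometric features and the stacked multi-scale feature matrix.

Nine 3D features come from the neighborhood's covariance eigendecomposition
and z spread; three 2D features from the same neighborhood projected onto
the XY plane (not an independent 2D neighbor query).  With eigenvalues
sorted ascending (EV1 <= EV2 <= EV3):

======================  =====================================================
Linearity3D             EV3 / (EV1 + EV2 + EV3)
Planarity3D             EV2 / (EV1 + EV2 + EV3)
Omnivariance3D          (EV1 * EV2 * EV3) ** (1/3)
Anisotropy3D            (EV3 - EV1) / EV3              (0 if EV3 = 0)
Verticality3D           |z component of the surface normal|
Radius3D                distance to the k-th neighbor, m
Density3D               (k + 1) / ((4/3) pi Radius3D^3), points / m^3
Zdiff3D                 max z - min z over the neighborhood, m
StdZ3D                  population std of neighborhood z, m
Radius2D                max planar distance query -> projected neighbor, m
Density2D               (k + 1) / (pi Radius2D^2)      (0 if Radius2D = 0)
Linearity2D             EV2D_2 / (EV2D_1 + EV2D_2)     (1/2 if both 0)
======================  =====================================================

Note Linearity3D/Planarity3D are the normalized eigenvalues themselves
(alpha3, alpha2), not the classical (EV3-EV2)/EV3 style dimensionality
features.  Density formulas count the k+1 neighborhood points (query
included) in the ball/disk of the neighborhood radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import LabeledPointCloud
from .neighbors import NeighborhoodTable, query_neighbors
from .scales import (
    EigenTriple,
    ScaleSelection,
    _alphas_from_lambdas,
    _batched_cov_eigh,
    _normals_from_eigh,
)

FEATURE_NAMES_3D = (
    "Linearity3D", "Planarity3D", "Omnivariance3D", "Anisotropy3D",
    "Verticality3D", "Radius3D", "Density3D", "Zdiff3D", "StdZ3D",
)
FEATURE_NAMES_2D = ("Radius2D", "Density2D", "Linearity2D")
FEATURE_NAMES = FEATURE_NAMES_3D + FEATURE_NAMES_2D

N_FEATURES = len(FEATURE_NAMES)

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_NAMES_3D",
    "FEATURE_NAMES_2D",
    "N_FEATURES",
    "FeatureMatrix",
    "features_3d",
    "features_2d",
    "features_at_scale",
    "assemble_feature_matrix",
]


def _features_3d_batched(
    lam: np.ndarray, normals: np.ndarray, neigh: np.ndarray, r_k: np.ndarray
) -> np.ndarray:
    """(n, 9) block of 3D features from batched eigendecompositions."""
    n, p = neigh.shape[0], neigh.shape[1]
    total = lam.sum(axis=1)
    out = np.empty((n, 9), dtype=np.float64)
    alphas = _alphas_from_lambdas(lam)
    out[:, 0] = alphas[:, 2]                                 # Linearity3D
    out[:, 1] = alphas[:, 1]                                 # Planarity3D
    out[:, 2] = np.cbrt(lam[:, 0] * lam[:, 1] * lam[:, 2])   # Omnivariance3D
    l3 = lam[:, 2]
    out[:, 3] = np.where(l3 > 0.0, (l3 - lam[:, 0]) / np.where(l3 > 0, l3, 1.0), 0.0)
    out[:, 4] = np.abs(normals[:, 2])                        # Verticality3D
    out[:, 5] = r_k                                          # Radius3D
    with np.errstate(divide="ignore"):
        vol = (4.0 / 3.0) * np.pi * r_k**3
        out[:, 6] = np.where(r_k > 0.0, p / np.where(vol > 0, vol, 1.0), 0.0)
    z = neigh[:, :, 2]
    out[:, 7] = z.max(axis=1) - z.min(axis=1)                # Zdiff3D
    out[:, 8] = z.std(axis=1)                                # StdZ3D (population)
    return out


def _features_2d_batched(neigh: np.ndarray, query_xy: np.ndarray) -> np.ndarray:
    """(n, 3) block of projected-2D features.

    ``neigh`` is the same (n, k+1, 3) neighborhood stack used for the 3D
    block; ``query_xy`` the (n, 2) projections of the query points.
    """
    n, p = neigh.shape[0], neigh.shape[1]
    proj = neigh[:, :, :2]
    d = np.linalg.norm(proj - query_xy[:, None, :], axis=2)
    r2 = d.max(axis=1)                                       # Radius2D
    with np.errstate(divide="ignore"):
        area = np.pi * r2**2
        dens = np.where(r2 > 0.0, p / np.where(area > 0, area, 1.0), 0.0)
    centered = proj - proj.mean(axis=1, keepdims=True)
    cov = np.einsum("npi,npj->nij", centered, centered) / p
    ev = np.clip(np.linalg.eigvalsh(cov), 0.0, None)         # ascending (2,)
    tot = ev.sum(axis=1)
    lin2d = np.where(tot > 0.0, ev[:, 1] / np.where(tot > 0, tot, 1.0), 0.5)
    return np.stack([r2, dens, lin2d], axis=1)


def features_3d(
    triple: EigenTriple, neighborhood_coords: np.ndarray, r_k: float
) -> dict[str, float]:
    """The nine 3D features of one neighborhood (query point included)."""
    pts = np.asarray(neighborhood_coords, dtype=np.float64)
    if pts.shape[0] < 3:
        raise ValueError("3D features need at least 3 points")
    block = _features_3d_batched(
        triple.lambdas[None], triple.normal[None], pts[None],
        np.asarray([r_k], dtype=np.float64),
    )[0]
    return dict(zip(FEATURE_NAMES_3D, block.tolist()))


def features_2d(neighborhood_coords: np.ndarray, query_point) -> dict[str, float]:
    """The three projected-2D features of one neighborhood."""
    pts = np.asarray(neighborhood_coords, dtype=np.float64)
    if pts.shape[0] < 2:
        raise ValueError("2D features need at least 2 points")
    q = np.asarray(query_point, dtype=np.float64)[:2]
    block = _features_2d_batched(pts[None], q[None])[0]
    return dict(zip(FEATURE_NAMES_2D, block.tolist()))


def features_at_scale(
    cloud: LabeledPointCloud, neighborhoods: NeighborhoodTable, k: int
) -> np.ndarray:
    """(n_q, 12) feature block of every queried point at one scale."""
    q = neighborhoods.query_indices
    nbr = neighborhoods.neighbors_at(k)
    neigh = np.concatenate(
        [cloud.coords[q][:, None, :], cloud.coords[nbr]], axis=1
    )
    lam, vec = _batched_cov_eigh(neigh)
    normals = _normals_from_eigh(lam, vec)
    r_k = neighborhoods.radius_at(k)
    f3 = _features_3d_batched(lam, normals, neigh, r_k)
    f2 = _features_2d_batched(neigh, cloud.coords[q][:, :2])
    return np.concatenate([f3, f2], axis=1)


@dataclass
class FeatureMatrix:
    """n_points x (12 * m) stacked features with a canonical column layout.

    Row i concatenates the 12-feature block of point i at each of its m
    selected scales, slots ordered by ascending k.  ``slot_scales[i, j]``
    records the actual k behind slot j of row i (it varies per point for
    the multi-optimal strategy).
    """

    values: np.ndarray          # (n_q, 12*m)
    columns: tuple[str, ...]
    query_indices: np.ndarray
    slot_scales: np.ndarray     # (n_q, m) int

    @property
    def m(self) -> int:
        return self.slot_scales.shape[1]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, columns=list(self.columns),
            index=pd.Index(self.query_indices, name="point"),
        )


def assemble_feature_matrix(
    cloud: LabeledPointCloud,
    selection: ScaleSelection,
    neighborhoods: NeighborhoodTable | None = None,
    precomputed_blocks: dict[int, np.ndarray] | None = None,
) -> FeatureMatrix:
    """Stack per-scale feature blocks according to a scale selection.

    Feature blocks are computed once per distinct k appearing anywhere in
    the selection, then gathered row-wise, so the multi-optimal strategy
    (different scales per point) costs no more than a fixed-scale stack.
    ``precomputed_blocks`` lets experiment drivers reuse blocks across many
    selections over the same query set.
    """
    if neighborhoods is None:
        neighborhoods = query_neighbors(cloud, selection.query_indices,
                                        selection.grid)
    if not np.array_equal(neighborhoods.query_indices, selection.query_indices):
        raise ValueError("selection and neighborhood table cover different points")

    n_q, m = selection.selected.shape
    blocks: dict[int, np.ndarray] = dict(precomputed_blocks or {})
    for k in np.unique(selection.selected):
        if int(k) not in blocks:
            blocks[int(k)] = features_at_scale(cloud, neighborhoods, int(k))

    values = np.empty((n_q, N_FEATURES * m), dtype=np.float64)
    for j in range(m):
        col = slice(j * N_FEATURES, (j + 1) * N_FEATURES)
        slot_k = selection.selected[:, j]
        for k in np.unique(slot_k):
            rows = slot_k == k
            values[rows, col] = blocks[int(k)][rows]

    bad = ~np.isfinite(values)
    if bad.any():
        i, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite feature {FEATURE_NAMES[c % N_FEATURES]!r} for point "
            f"{selection.query_indices[i]} at scale "
            f"{selection.selected[i, c // N_FEATURES]}"
        )
    columns = tuple(
        f"{name}@scale_slot_{j}" for j in range(m) for name in FEATURE_NAMES
    )
    return FeatureMatrix(
        values=values, columns=columns,
        query_indices=selection.query_indices,
        slot_scales=selection.selected.copy(),
    )
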