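"""Independent straight-from-definition oracles used by the test suite.

Everything here is deliberately naive — full distance matrices, explicit
per-neighborhood covariance sums, scalar feature formulas — and shares no
code path with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def brute_knn(coords: np.ndarray, i: int, k: int) -> np.ndarray:
    """k nearest neighbors of point i by full distance sort, ties by index."""
    d = np.linalg.norm(coords - coords[i], axis=1)
    order = sorted(range(len(coords)), key=lambda j: (d[j], j))
    order = [j for j in order if j != i]
    return np.asarray(order[:k])


def brute_knn_all(coords: np.ndarray, k: int) -> np.ndarray:
    """(N, k) neighbor table from the full pairwise distance matrix."""
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    n = len(coords)
    idx = np.arange(n)
    d[idx, idx] = np.inf
    # lexsort: primary key distance, secondary index
    order = np.lexsort((np.broadcast_to(idx, (n, n)), d), axis=1)
    return order[:, :k]


def brute_cov_eigenvalues(points: np.ndarray) -> np.ndarray:
    """Ascending eigenvalues of the population covariance (explicit sums)."""
    pts = np.asarray(points, dtype=np.float64)
    mean = pts.sum(axis=0) / len(pts)
    cov = np.zeros((3, 3))
    for p in pts:
        v = p - mean
        cov += np.outer(v, v)
    cov /= len(pts)
    return np.sort(np.linalg.eigvalsh(cov))


def brute_entropy(lambdas: np.ndarray) -> float:
    """Eigen-entropy directly from the defining formula, 0 ln 0 = 0."""
    total = float(np.sum(lambdas))
    if total <= 0.0:
        return float(np.log(3.0))
    e = 0.0
    for lam in lambdas:
        a = lam / total
        if a > 0.0:
            e -= a * np.log(a)
    return e


def brute_features12(
    query: np.ndarray, neighbor_coords: np.ndarray
) -> dict[str, float]:
    """All 12 features of one neighborhood straight from their definitions.

    ``neighbor_coords`` are the k neighbors; the neighborhood is the query
    point plus those k points (k + 1 points total).
    """
    query = np.asarray(query, dtype=np.float64)
    nbr = np.asarray(neighbor_coords, dtype=np.float64)
    hood = np.vstack([query[None, :], nbr])
    k = len(nbr)

    lam = np.clip(brute_cov_eigenvalues(hood), 0.0, None)
    l1, l2, l3 = lam
    total = l1 + l2 + l3

    # surface normal: eigenvector of the smallest eigenvalue
    mean = hood.mean(axis=0)
    cov = (hood - mean).T @ (hood - mean) / len(hood)
    w, v = np.linalg.eigh(cov)
    normal = v[:, 0]

    r_k = float(np.linalg.norm(nbr - query, axis=1).max())
    z = hood[:, 2]

    proj = hood[:, :2]
    r2 = float(np.linalg.norm(proj - query[:2], axis=1).max())
    cov2 = (proj - proj.mean(axis=0)).T @ (proj - proj.mean(axis=0)) / len(proj)
    ev2 = np.sort(np.linalg.eigvalsh(cov2))
    ev2 = np.clip(ev2, 0.0, None)
    tot2 = ev2.sum()

    return {
        "Linearity3D": l3 / total if total > 0 else 1.0 / 3.0,
        "Planarity3D": l2 / total if total > 0 else 1.0 / 3.0,
        "Omnivariance3D": float((l1 * l2 * l3) ** (1.0 / 3.0)),
        "Anisotropy3D": (l3 - l1) / l3 if l3 > 0 else 0.0,
        "Verticality3D": abs(float(normal[2])),
        "Radius3D": r_k,
        "Density3D": (k + 1) / (4.0 / 3.0 * np.pi * r_k**3) if r_k > 0 else 0.0,
        "Zdiff3D": float(z.max() - z.min()),
        "StdZ3D": float(np.sqrt(((z - z.mean()) ** 2).mean())),
        "Radius2D": r2,
        "Density2D": (k + 1) / (np.pi * r2**2) if r2 > 0 else 0.0,
        "Linearity2D": ev2[1] / tot2 if tot2 > 0 else 0.5,
    }


def brute_nearest_core(
    coords: np.ndarray, core_indices: np.ndarray, core_labels: np.ndarray
) -> np.ndarray:
    """O(N * n_core) nearest-core label assignment, ties to smaller core index."""
    out = np.empty(len(coords), dtype=core_labels.dtype)
    core_coords = coords[core_indices]
    for i, p in enumerate(coords):
        d = np.linalg.norm(core_coords - p, axis=1)
        best = min(range(len(core_indices)), key=lambda j: (d[j], j))
        out[i] = core_labels[best]
    return out
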