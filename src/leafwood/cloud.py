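"""Labeled point clouds, ASCII XYZ / PLY input-output, and core-point subsampling.

A tree point cloud is an ``N x 3`` array of coordinates in meters with an
optional per-point class label: ``0`` = leaf, ``1`` = wood.  Points whose
class is unknown (prediction-only input) carry the sentinel ``-1``.

Two plain-text formats are supported:

* **XYZ** — whitespace-delimited, 3 columns (x y z) or 4 columns
  (x y z label); lines starting with ``#`` are comments.
* **PLY** — ``format ascii 1.0`` with float ``x``/``y``/``z`` vertex
  properties and an optional integer ``label`` property.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

LEAF = 0
WOOD = 1
UNLABELED = -1

LABEL_NAMES = {LEAF: "leaf", WOOD: "wood", UNLABELED: "unlabeled"}

__all__ = [
    "LEAF",
    "WOOD",
    "UNLABELED",
    "LABEL_NAMES",
    "LabeledPointCloud",
    "CorePointSet",
    "read_point_cloud",
    "write_point_cloud",
    "subsample_core_points",
]


@dataclass
class LabeledPointCloud:
    """3D point cloud with per-point leaf/wood/unlabeled classes.

    Parameters
    ----------
    coords : (N, 3) float array
        Point coordinates in meters.
    labels : (N,) int array, optional
        ``0`` leaf, ``1`` wood, ``-1`` unlabeled.  Defaults to all
        unlabeled.
    source_id : str
        Free-form provenance tag (file name, generator spec, ...).
    """

    coords: np.ndarray
    labels: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3); got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("point cloud must contain at least one point")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain non-finite values")
        if self.labels is None:
            self.labels = np.full(len(self.coords), UNLABELED, dtype=np.int64)
        else:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self.coords),):
                raise ValueError(
                    f"labels length {self.labels.shape} does not match "
                    f"{len(self.coords)} points"
                )
            bad = ~np.isin(self.labels, (LEAF, WOOD, UNLABELED))
            if bad.any():
                raise ValueError(
                    f"unknown label value(s) {np.unique(self.labels[bad])!r}; "
                    f"expected 0 (leaf), 1 (wood) or -1 (unlabeled)"
                )

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_points(self) -> int:
        return len(self.coords)

    @property
    def is_labeled(self) -> bool:
        """True when every point has a leaf/wood class."""
        return bool((self.labels != UNLABELED).all())

    def label_counts(self) -> dict[str, int]:
        return {
            name: int((self.labels == value).sum())
            for value, name in LABEL_NAMES.items()
        }


@dataclass(frozen=True)
class CorePointSet:
    """Random subsample of the cloud on which features are computed.

    ``indices`` are unique positions into the parent cloud; points outside
    the set later inherit the label of their nearest core point.
    """

    indices: np.ndarray
    fraction: float
    seed: int
    n_total: int = field(default=0)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("core point indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def subsample_core_points(
    cloud: LabeledPointCloud, fraction: float, seed: int
) -> CorePointSet:
    """Draw a simple random sample of ``round(fraction * N)`` core points.

    The sample is without replacement, unstratified, and deterministic for
    a given seed.  Size is rounded half-away-from-zero and clamped to at
    least one point.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1]; got {fraction}")
    n = len(cloud)
    size = max(1, _round_half_away(fraction * n))
    size = min(size, n)
    rng = np.random.default_rng(seed)
    indices = np.sort(rng.choice(n, size=size, replace=False))
    return CorePointSet(indices=indices, fraction=fraction, seed=seed, n_total=n)


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------


def _read_xyz(path: str) -> LabeledPointCloud:
    coords: list[tuple[float, float, float]] = []
    labels: list[int] = []
    ncols: int | None = None
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise ValueError(
                    f"{path}:{lineno}: expected 3 or 4 columns, got {len(parts)}"
                )
            if ncols is None:
                ncols = len(parts)
            elif len(parts) != ncols:
                raise ValueError(
                    f"{path}:{lineno}: inconsistent column count "
                    f"({len(parts)} vs {ncols})"
                )
            try:
                x, y, z = float(parts[0]), float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinate: {exc}")
            coords.append((x, y, z))
            if ncols == 4:
                try:
                    lab = int(parts[3])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: malformed label {parts[3]!r}"
                    )
                if lab not in (LEAF, WOOD, UNLABELED):
                    raise ValueError(
                        f"{path}:{lineno}: unknown label value {lab}"
                    )
                labels.append(lab)
    if not coords:
        raise ValueError(f"{path}: no points found")
    arr = np.asarray(coords, dtype=np.float64)
    labs = np.asarray(labels, dtype=np.int64) if labels else None
    return LabeledPointCloud(coords=arr, labels=labs, source_id=str(path))


def _write_xyz(cloud: LabeledPointCloud, path: str) -> None:
    has_labels = bool((cloud.labels != UNLABELED).any())
    with open(path, "w") as fh:
        if has_labels:
            for (x, y, z), lab in zip(cloud.coords, cloud.labels):
                fh.write(f"{x:.6f} {y:.6f} {z:.6f} {lab:d}\n")
        else:
            for x, y, z in cloud.coords:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# PLY (ascii 1.0, x/y/z float + optional label int)
# ---------------------------------------------------------------------------

_PLY_FLOAT = {"float", "float32", "float64", "double"}
_PLY_INT = {"char", "uchar", "short", "ushort", "int", "uint",
            "int8", "uint8", "int16", "uint16", "int32", "uint32"}


def _read_ply(path: str) -> LabeledPointCloud:
    with open(path, "r") as fh:
        magic = fh.readline().strip()
        if magic != "ply":
            raise ValueError(f"{path}: not a PLY file (missing 'ply' magic)")
        n_vertex = None
        props: list[str] = []
        in_vertex = False
        lineno = 1
        for raw in fh:
            lineno += 1
            line = raw.strip()
            if line.startswith("comment") or not line:
                continue
            if line.startswith("format"):
                if "ascii" not in line:
                    raise ValueError(f"{path}: only 'format ascii 1.0' is supported")
            elif line.startswith("element"):
                _, name, count = line.split()
                in_vertex = name == "vertex"
                if in_vertex:
                    n_vertex = int(count)
            elif line.startswith("property") and in_vertex:
                parts = line.split()
                if parts[1] == "list":
                    raise ValueError(f"{path}:{lineno}: list vertex properties unsupported")
                props.append(parts[2])
            elif line == "end_header":
                break
        if n_vertex is None:
            raise ValueError(f"{path}: no vertex element in header")
        for axis in ("x", "y", "z"):
            if axis not in props:
                raise ValueError(f"{path}: vertex element lacks '{axis}' property")
        ix, iy, iz = props.index("x"), props.index("y"), props.index("z")
        il = props.index("label") if "label" in props else None
        coords = np.empty((n_vertex, 3), dtype=np.float64)
        labels = np.full(n_vertex, UNLABELED, dtype=np.int64) if il is not None else None
        for i in range(n_vertex):
            raw = fh.readline()
            lineno += 1
            parts = raw.split()
            if len(parts) != len(props):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(props)} values, got {len(parts)}"
                )
            try:
                coords[i, 0] = float(parts[ix])
                coords[i, 1] = float(parts[iy])
                coords[i, 2] = float(parts[iz])
                if il is not None:
                    labels[i] = int(parts[il])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed vertex row: {exc}")
    return LabeledPointCloud(coords=coords, labels=labels, source_id=str(path))


def _write_ply(cloud: LabeledPointCloud, path: str) -> None:
    has_labels = bool((cloud.labels != UNLABELED).any())
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if has_labels:
            fh.write("property int label\n")
        fh.write("end_header\n")
        if has_labels:
            for (x, y, z), lab in zip(cloud.coords, cloud.labels):
                fh.write(f"{x:.6f} {y:.6f} {z:.6f} {lab:d}\n")
        else:
            for x, y, z in cloud.coords:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    lower = str(path).lower()
    if lower.endswith(".ply"):
        return "ply"
    return "xyz"


def read_point_cloud(path: str, fmt: str | None = None) -> LabeledPointCloud:
    """Read an XYZ or PLY point cloud; format inferred from the extension."""
    fmt = _infer_format(path, fmt)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "ply":
        return _read_ply(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'xyz' or 'ply'")


def write_point_cloud(
    cloud: LabeledPointCloud, path: str, fmt: str | None = None
) -> None:
    """Write a cloud to XYZ or PLY; coordinates at 6 decimal places (1 um)."""
    fmt = _infer_format(path, fmt)
    if fmt == "xyz":
        _write_xyz(cloud, path)
    elif fmt == "ply":
        _write_ply(cloud, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'xyz' or 'ply'")
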