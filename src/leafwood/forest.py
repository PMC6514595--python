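"""Random-forest leaf/wood classification and nearest-core label propagation.

The forest is trained on the features of a labeled subset of the core
points and applied to all core points; every remaining point of the cloud
then inherits the label of its Euclidean-nearest core point.  Defaults
follow the standard protocol for this task: 100 trees, sqrt(#features)
candidate features per split, minimum leaf size 10.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.ensemble import RandomForestClassifier

from .cloud import LEAF, UNLABELED, WOOD, CorePointSet, LabeledPointCloud
from .features import FeatureMatrix

__all__ = [
    "RFConfig",
    "SeparationModel",
    "split_train_eval",
    "train_rf",
    "predict",
    "propagate_labels",
]


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters.

    ``n_features_per_split=None`` resolves to floor(sqrt(n_features_total))
    at training time.
    """

    ntree: int = 100
    n_features_per_split: int | None = None
    mleaf: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mleaf < 1:
            raise ValueError("mleaf must be >= 1")
        if self.n_features_per_split is not None and self.n_features_per_split < 1:
            raise ValueError("n_features_per_split must be >= 1")

    def resolve_max_features(self, n_features_total: int) -> int:
        if self.n_features_per_split is None:
            return max(1, int(math.floor(math.sqrt(n_features_total))))
        if self.n_features_per_split > n_features_total:
            raise ValueError(
                f"n_features_per_split={self.n_features_per_split} exceeds "
                f"the {n_features_total} available features"
            )
        return self.n_features_per_split

    def to_dict(self) -> dict:
        return {
            "ntree": self.ntree,
            "n_features_per_split": self.n_features_per_split,
            "mleaf": self.mleaf,
            "seed": self.seed,
        }


@dataclass
class SeparationModel:
    """Trained forest plus the feature layout it expects."""

    forest: RandomForestClassifier
    config: RFConfig
    columns: tuple[str, ...]
    n_train: int
    class_counts: dict[str, int] = field(default_factory=dict)

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str) -> "SeparationModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, SeparationModel):
            raise ValueError(f"{path} does not contain a SeparationModel")
        return model


def split_train_eval(
    core: CorePointSet,
    labels: np.ndarray,
    train_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/eval split of the core points.

    Simple random sampling of ``round(train_fraction * n_core)`` training
    points; both returned arrays are cloud-level indices.  Both classes
    must appear in the training part (a single-class forest would be
    degenerate).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1); got {train_fraction}")
    labels = np.asarray(labels)
    core_labels = labels[core.indices]
    if (core_labels == UNLABELED).any():
        raise ValueError("all core points must be labeled for training")
    n_core = len(core)
    n_train = int(math.floor(train_fraction * n_core + 0.5))
    n_train = min(max(1, n_train), n_core - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_core)
    train = np.sort(core.indices[perm[:n_train]])
    evaluate = np.sort(core.indices[perm[n_train:]])
    present = set(np.unique(labels[train]).tolist())
    if not {LEAF, WOOD} <= present:
        raise ValueError(
            "training split lacks a class; increase train_fraction or reseed"
        )
    return train, evaluate


def train_rf(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    config: RFConfig | None = None,
    columns: tuple[str, ...] | None = None,
) -> SeparationModel:
    """Fit a random forest on (row-aligned) features and leaf/wood labels."""
    if config is None:
        config = RFConfig()
    if isinstance(features, FeatureMatrix):
        X = features.values
        columns = features.columns
    else:
        X = np.asarray(features, dtype=np.float64)
        if columns is None:
            columns = tuple(f"f{j}" for j in range(X.shape[1]))
    y = np.asarray(labels)
    if len(y) != X.shape[0]:
        raise ValueError("feature rows and labels have different lengths")
    if (y == UNLABELED).any():
        raise ValueError("training labels must all be leaf or wood")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if not np.isfinite(X).all():
        raise ValueError("training features contain non-finite values")
    forest = RandomForestClassifier(
        n_estimators=config.ntree,
        max_features=config.resolve_max_features(X.shape[1]),
        min_samples_leaf=config.mleaf,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return SeparationModel(
        forest=forest,
        config=config,
        columns=tuple(columns),
        n_train=X.shape[0],
        class_counts={"leaf": int((y == LEAF).sum()), "wood": int((y == WOOD).sum())},
    )


def predict(model: SeparationModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Majority-vote leaf/wood prediction; exact vote ties go to wood."""
    if isinstance(features, FeatureMatrix):
        if features.columns != model.columns:
            raise ValueError(
                "feature matrix column layout does not match the model "
                f"({len(features.columns)} vs {len(model.columns)} columns "
                f"or differing names)"
            )
        X = features.values
    else:
        X = np.asarray(features, dtype=np.float64)
        if X.shape[1] != len(model.columns):
            raise ValueError(
                f"expected {len(model.columns)} feature columns, got {X.shape[1]}"
            )
    proba = model.forest.predict_proba(X)
    wood_col = int(np.flatnonzero(model.forest.classes_ == WOOD)[0])
    return np.where(proba[:, wood_col] >= 0.5, WOOD, LEAF).astype(np.int64)


def propagate_labels(
    cloud: LabeledPointCloud,
    core: CorePointSet | np.ndarray,
    core_labels: np.ndarray,
) -> np.ndarray:
    """Give every cloud point the label of its nearest core point.

    Core points keep their own label (their nearest core point is
    themselves at distance zero).  Exact distance ties are broken toward
    the smaller core index by re-checking the few nearest candidates.
    """
    core_idx = core.indices if isinstance(core, CorePointSet) else np.asarray(core)
    core_labels = np.asarray(core_labels)
    if len(core_idx) == 0:
        raise ValueError("core point set is empty")
    if len(core_labels) != len(core_idx):
        raise ValueError("core_labels length must match the core set")
    if (core_labels == UNLABELED).any():
        raise ValueError("every core point must carry a leaf/wood label")

    core_coords = cloud.coords[core_idx]
    tree = cKDTree(core_coords)
    k = min(4, len(core_idx))
    dist, pos = tree.query(cloud.coords, k=k)
    if k == 1:
        nearest = pos
    else:
        # Among candidates at exactly the minimal distance, take the one
        # with the smallest core index (ordering within the core set).
        tied = dist == dist[:, :1]
        masked = np.where(tied, pos, len(core_idx))
        nearest = masked.min(axis=1)
    return core_labels[nearest]
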