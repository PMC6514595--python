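"""Model/Results interface wiring the full separation pipeline.

``LeafWoodModel`` holds a point cloud plus the pipeline configuration;
``fit()`` runs core-point subsampling, neighborhood queries, eigen-entropy
scale selection, feature extraction, forest training, core prediction and
nearest-core propagation, and returns a ``SeparationResults`` with the
full-cloud labels, confusion counts, per-stage timings and a ``summary()``
table.

>>> from leafwood import LeafWoodModel, generate_tree, SyntheticTreeSpec
>>> cloud = generate_tree(SyntheticTreeSpec(seed=1))
>>> res = LeafWoodModel(cloud, method="multi_optimal", m=5, seed=1).fit()
>>> print(res.summary())                                   # doctest: +SKIP
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np

from .cloud import (
    UNLABELED,
    CorePointSet,
    LabeledPointCloud,
    read_point_cloud,
    subsample_core_points,
)
from .evaluation import SeparationResult, accuracy
from .features import FeatureMatrix, assemble_feature_matrix
from .forest import (
    RFConfig,
    SeparationModel,
    predict,
    propagate_labels,
    split_train_eval,
    train_rf,
)
from .neighbors import ScaleGrid, build_scale_grid, query_neighbors
from .scales import ScaleSelection, entropy_table, select_scales

__all__ = ["LeafWoodModel", "SeparationResults"]


@dataclass
class SeparationResults:
    """Everything one separation run produced.

    ``labels`` is the full-cloud prediction (propagated from core points);
    ``core_result`` the held-out core-point confusion (the evaluation the
    protocol reports); ``full_result`` the whole-cloud confusion against
    the reference labels when the input cloud was fully labeled.
    """

    labels: np.ndarray
    core: CorePointSet
    core_labels: np.ndarray
    selection: ScaleSelection
    model: SeparationModel
    core_result: SeparationResult | None
    full_result: SeparationResult | None
    timings: dict[str, float]
    config: dict
    train_indices: np.ndarray | None = None
    eval_indices: np.ndarray | None = None

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Leaf/wood separation results",
            "=" * 60,
            f"points: {len(self.labels):>10d}    core points: {len(self.core):>8d}",
            f"method: {cfg['method']} (m={cfg['m']}), "
            f"grid k={cfg['grid'][0]}..{cfg['grid'][-1]} ({len(cfg['grid'])} scales)",
            f"forest: ntree={cfg['rf']['ntree']}, mleaf={cfg['rf']['mleaf']}, "
            f"n_train={self.model.n_train}",
        ]
        if self.core_result is not None:
            r = self.core_result
            lines += [
                "-" * 60,
                "held-out core points:",
                f"  wood {r.Tw}/{r.w} correct, leaf {r.Tl}/{r.l} correct",
                f"  accuracy = (Tw+Tl)/(w+l) = {r.accuracy:.4f}",
            ]
        if self.full_result is not None:
            r = self.full_result
            lines += [
                "full cloud (after nearest-core propagation):",
                f"  wood {r.Tw}/{r.w} correct, leaf {r.Tl}/{r.l} correct",
                f"  accuracy = {r.accuracy:.4f}",
            ]
        lines += [
            "-" * 60,
            "timings (s): " + ", ".join(
                f"{k}={v:.2f}" for k, v in self.timings.items()
            ),
        ]
        return "\n".join(lines)

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "config": self.config,
            "n_points": int(len(self.labels)),
            "n_core": int(len(self.core)),
            "core_result": self.core_result.to_dict() if self.core_result else None,
            "full_result": self.full_result.to_dict() if self.full_result else None,
            "timings": self.timings,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class LeafWoodModel:
    """Leaf/wood separator for a single tree point cloud.

    Parameters
    ----------
    cloud : LabeledPointCloud
        Input tree.  Training requires labels; a saved model can be applied
        to unlabeled clouds via ``fit(pretrained=...)``.
    grid : ScaleGrid, optional
        Candidate scales; default k = 10..100 step 10.
    method : {"multi_optimal", "optimal", "multi_scale_random"}
    m : int
        Number of selected scales per point (ignored for ``optimal``).
    core_fraction, train_fraction : float
        Fraction of points used as core points, and of core points used
        for training.
    rf_config : RFConfig, optional
    seed : int
        Master seed; stage seeds are derived deterministically.
    """

    def __init__(
        self,
        cloud: LabeledPointCloud,
        grid: ScaleGrid | None = None,
        method: str = "multi_optimal",
        m: int = 5,
        core_fraction: float = 0.1,
        train_fraction: float = 0.1,
        rf_config: RFConfig | None = None,
        seed: int = 0,
    ) -> None:
        self.cloud = cloud
        self.grid = grid if grid is not None else build_scale_grid()
        self.method = method
        self.m = 1 if method == "optimal" else m
        self.core_fraction = core_fraction
        self.train_fraction = train_fraction
        self.seed = seed
        self.rf_config = rf_config if rf_config is not None else RFConfig(seed=seed + 2)

    @classmethod
    def from_file(cls, path: str, fmt: str | None = None, **kwargs) -> "LeafWoodModel":
        return cls(read_point_cloud(path, fmt), **kwargs)

    def _config_dict(self) -> dict:
        return {
            "method": self.method,
            "m": self.m,
            "grid": list(self.grid),
            "core_fraction": self.core_fraction,
            "train_fraction": self.train_fraction,
            "rf": self.rf_config.to_dict(),
            "seed": self.seed,
        }

    def _stage_seeds(self) -> dict[str, int]:
        return {"core": self.seed, "split": self.seed + 1,
                "scales": self.seed + 3}

    def compute_features(
        self, core: CorePointSet
    ) -> tuple[FeatureMatrix, ScaleSelection]:
        """Scale selection + stacked features for a given core set."""
        nbrs = query_neighbors(self.cloud, core.indices, self.grid)
        etable = entropy_table(self.cloud, neighborhoods=nbrs)
        selection = select_scales(
            etable, self.method, m=self.m, seed=self._stage_seeds()["scales"]
        )
        fm = assemble_feature_matrix(self.cloud, selection, nbrs)
        return fm, selection

    def fit(self, pretrained: SeparationModel | None = None) -> SeparationResults:
        """Run the pipeline; train a forest unless ``pretrained`` is given."""
        seeds = self._stage_seeds()
        timings: dict[str, float] = {}

        t = time.perf_counter()
        core = subsample_core_points(self.cloud, self.core_fraction, seeds["core"])
        timings["core_sampling"] = time.perf_counter() - t

        t = time.perf_counter()
        fm, selection = self.compute_features(core)
        timings["scales_and_features"] = time.perf_counter() - t

        train_idx = eval_idx = None
        core_result = None
        if pretrained is None:
            t = time.perf_counter()
            train_idx, eval_idx = split_train_eval(
                core, self.cloud.labels, self.train_fraction, seeds["split"]
            )
            pos = {int(ci): p for p, ci in enumerate(core.indices)}
            train_pos = np.asarray([pos[int(i)] for i in train_idx])
            model = train_rf(
                fm.values[train_pos], self.cloud.labels[train_idx],
                self.rf_config, columns=fm.columns,
            )
            timings["training"] = time.perf_counter() - t
        else:
            model = pretrained
            if model.columns != fm.columns:
                raise ValueError("pretrained model feature layout mismatch")

        t = time.perf_counter()
        core_pred = predict(model, fm)
        timings["core_prediction"] = time.perf_counter() - t

        if eval_idx is not None:
            pos = {int(ci): p for p, ci in enumerate(core.indices)}
            eval_pos = np.asarray([pos[int(i)] for i in eval_idx])
            core_result = accuracy(core_pred[eval_pos], self.cloud.labels[eval_idx])

        t = time.perf_counter()
        labels = propagate_labels(self.cloud, core, core_pred)
        timings["propagation"] = time.perf_counter() - t

        full_result = None
        if self.cloud.is_labeled:
            full_result = accuracy(labels, self.cloud.labels)

        return SeparationResults(
            labels=labels,
            core=core,
            core_labels=core_pred,
            selection=selection,
            model=model,
            core_result=core_result,
            full_result=full_result,
            timings=timings,
            config=self._config_dict(),
            train_indices=train_idx,
            eval_indices=eval_idx,
        )
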