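"""Accuracy, speedup ratio, and the scale-strategy comparison experiment."""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cloud import LEAF, UNLABELED, WOOD, LabeledPointCloud, subsample_core_points
from .features import assemble_feature_matrix, features_at_scale
from .forest import RFConfig, predict, split_train_eval, train_rf
from .neighbors import ScaleGrid, build_scale_grid, query_neighbors
from .scales import entropy_table, select_scales

__all__ = [
    "SeparationResult",
    "ExperimentReport",
    "accuracy",
    "speedup_ratio",
    "run_comparison",
]


@dataclass(frozen=True)
class SeparationResult:
    """Confusion counts and overall accuracy of one separation.

    ``Tw``/``Tl`` are correctly identified wood/leaf points; ``w``/``l``
    the wood/leaf totals of the reference.  Accuracy = (Tw + Tl) / (w + l).
    """

    Tw: int
    Tl: int
    w: int
    l: int

    @property
    def accuracy(self) -> float:
        return (self.Tw + self.Tl) / (self.w + self.l)

    def to_dict(self) -> dict:
        return {
            "Tw": self.Tw, "Tl": self.Tl, "w": self.w, "l": self.l,
            "accuracy": self.accuracy,
        }


def accuracy(predicted: np.ndarray, reference: np.ndarray) -> SeparationResult:
    """Confusion counts of a prediction against fully labeled reference."""
    predicted = np.asarray(predicted)
    reference = np.asarray(reference)
    if predicted.shape != reference.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} predicted vs "
            f"{reference.shape} reference"
        )
    if (reference == UNLABELED).any():
        raise ValueError("reference labels must all be leaf or wood")
    wood = reference == WOOD
    leaf = reference == LEAF
    return SeparationResult(
        Tw=int((predicted[wood] == WOOD).sum()),
        Tl=int((predicted[leaf] == LEAF).sum()),
        w=int(wood.sum()),
        l=int(leaf.sum()),
    )


def speedup_ratio(t_a: float, t_b: float) -> float:
    """Runtime ratio Tb / Ta of method b over (faster) method a."""
    if t_a <= 0:
        raise ValueError("t_a must be positive")
    return t_b / t_a


@dataclass
class ExperimentReport:
    """Tabular outcome of the scale-strategy comparison.

    One row per (method, m) with accuracy; the random multi-scale baseline
    contributes worst/best/mean rows over its repeated models.
    """

    table: pd.DataFrame
    n_random_models: int
    seeds: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> str:
        lines = ["Scale-strategy comparison (held-out core-point accuracy)", ""]
        lines.append(self.table.to_string(index=False, float_format="%.4f"))
        if self.timings:
            lines.append("")
            lines.append("Stage timings (s): " + ", ".join(
                f"{k}={v:.2f}" for k, v in self.timings.items()
            ))
        return "\n".join(lines)


def run_comparison(
    cloud: LabeledPointCloud,
    grid: ScaleGrid | None = None,
    m_values: list[int] | None = None,
    n_random_models: int = 50,
    seed: int = 0,
    core_fraction: float = 0.1,
    train_fraction: float = 0.1,
    rf_config: RFConfig | None = None,
) -> ExperimentReport:
    """Compare multi-optimal, optimal and random multi-scale strategies.

    All strategies at all m share one core-point sample, one train/eval
    split and one forest seed, so accuracy differences reflect scale
    selection alone.  For each m the random baseline is refit
    ``n_random_models`` times with fresh random scale subsets and reported
    as worst/best/mean.
    """
    if not cloud.is_labeled:
        raise ValueError("comparison requires a fully labeled cloud")
    if grid is None:
        grid = build_scale_grid()
    if m_values is None:
        m_values = list(range(2, len(grid) + 1))
    if rf_config is None:
        rf_config = RFConfig(seed=seed + 2)

    t0 = time.perf_counter()
    core = subsample_core_points(cloud, core_fraction, seed)
    nbrs = query_neighbors(cloud, core.indices, grid)
    etable = entropy_table(cloud, neighborhoods=nbrs)
    # One feature block per candidate scale serves every strategy below.
    blocks = {k: features_at_scale(cloud, nbrs, k) for k in grid}
    t_features = time.perf_counter() - t0

    train_idx, eval_idx = split_train_eval(core, cloud.labels, train_fraction,
                                           seed + 1)
    core_pos = {int(ci): p for p, ci in enumerate(core.indices)}
    train_pos = np.asarray([core_pos[int(i)] for i in train_idx])
    eval_pos = np.asarray([core_pos[int(i)] for i in eval_idx])
    y_train = cloud.labels[train_idx]
    y_eval = cloud.labels[eval_idx]

    def fit_eval(selection) -> float:
        fm = assemble_feature_matrix(cloud, selection, nbrs,
                                     precomputed_blocks=blocks)
        model = train_rf(fm.values[train_pos], y_train, rf_config,
                         columns=fm.columns)
        pred = predict(model, fm.values[eval_pos])
        return accuracy(pred, y_eval).accuracy

    rows = []
    t0 = time.perf_counter()
    opt_acc = fit_eval(select_scales(etable, "optimal"))
    rows.append({"method": "optimal", "m": 1, "statistic": "accuracy",
                 "accuracy": opt_acc})
    rng = np.random.default_rng(seed + 3)
    for m in m_values:
        rows.append({
            "method": "multi_optimal", "m": m, "statistic": "accuracy",
            "accuracy": fit_eval(select_scales(etable, "multi_optimal", m=m)),
        })
        if n_random_models > 0:
            accs = []
            for _ in range(n_random_models):
                sub_seed = int(rng.integers(2**31 - 1))
                sel = select_scales(etable, "multi_scale_random", m=m,
                                    seed=sub_seed)
                accs.append(fit_eval(sel))
            accs = np.asarray(accs)
            # clamp summation round-off so worst <= mean <= best holds exactly
            mean = float(np.clip(accs.mean(), accs.min(), accs.max()))
            for stat, value in (("worst", accs.min()), ("best", accs.max()),
                                ("mean", mean)):
                rows.append({"method": "multi_scale_random", "m": m,
                             "statistic": stat, "accuracy": float(value)})
    t_models = time.perf_counter() - t0

    return ExperimentReport(
        table=pd.DataFrame(rows),
        n_random_models=n_random_models,
        seeds={"core": seed, "split": seed + 1, "rf": rf_config.seed,
               "random_scales": seed + 3},
        timings={"features": t_features, "models": t_models},
    )
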