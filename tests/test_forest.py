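"""Train/eval splitting, forest training and prediction, label propagation."""

import numpy as np
import pytest

from leafwood import (
    LEAF,
    WOOD,
    LabeledPointCloud,
    RFConfig,
    predict,
    propagate_labels,
    split_train_eval,
    subsample_core_points,
    train_rf,
)

from oracles import brute_nearest_core


@pytest.fixture
def balanced_cloud(rng):
    coords = rng.normal(size=(1000, 3))
    labels = np.concatenate([np.full(500, LEAF), np.full(500, WOOD)])
    rng.shuffle(labels)
    return LabeledPointCloud(coords=coords, labels=labels)


def _toy_features(rng, n_per_class=50, gap=10.0):
    X = np.vstack([
        rng.normal(0.0, 1.0, size=(n_per_class, 4)),
        rng.normal(gap, 1.0, size=(n_per_class, 4)),
    ])
    y = np.concatenate([np.full(n_per_class, LEAF), np.full(n_per_class, WOOD)])
    return X, y


class TestSplitTrainEval:
    def test_counting(self, balanced_cloud):
        core = subsample_core_points(balanced_cloud, 1.0, seed=0)
        train, ev = split_train_eval(core, balanced_cloud.labels, 0.1, seed=1)
        assert len(train) == 100 and len(ev) == 900
        assert set(train).isdisjoint(ev)
        assert set(train) | set(ev) == set(core.indices.tolist())

    def test_deterministic(self, balanced_cloud):
        core = subsample_core_points(balanced_cloud, 0.5, seed=0)
        a = split_train_eval(core, balanced_cloud.labels, 0.2, seed=3)
        b = split_train_eval(core, balanced_cloud.labels, 0.2, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_class_proportions_unbiased(self, balanced_cloud):
        core = subsample_core_points(balanced_cloud, 1.0, seed=0)
        fracs = []
        for seed in range(200):
            train, _ = split_train_eval(core, balanced_cloud.labels, 0.1,
                                        seed=seed)
            fracs.append((balanced_cloud.labels[train] == WOOD).mean())
        se = np.sqrt(0.25 / 100) / np.sqrt(200)
        assert abs(np.mean(fracs) - 0.5) < 3 * se

    def test_missing_class_in_train_rejected(self, rng):
        coords = rng.normal(size=(100, 3))
        labels = np.full(100, LEAF)
        labels[0] = WOOD
        pc = LabeledPointCloud(coords=coords, labels=labels)
        core = subsample_core_points(pc, 1.0, seed=0)
        with pytest.raises(ValueError, match="lacks a class"):
            # a 1% train draw almost surely misses the single wood point
            split_train_eval(core, pc.labels, 0.01, seed=1)

    def test_unlabeled_core_rejected(self, rng):
        pc = LabeledPointCloud(coords=rng.normal(size=(10, 3)))
        core = subsample_core_points(pc, 1.0, seed=0)
        with pytest.raises(ValueError, match="labeled"):
            split_train_eval(core, pc.labels, 0.5, seed=0)


class TestTrainPredict:
    def test_separable_toy_perfect_on_train(self, rng):
        X, y = _toy_features(rng)
        model = train_rf(X, y, RFConfig(seed=0))
        np.testing.assert_array_equal(predict(model, X), y)

    def test_degenerate_forest_is_majority_vote(self, rng):
        X, y = _toy_features(rng, n_per_class=30)
        # one tree that can never split -> constant predictor
        model = train_rf(X, y, RFConfig(ntree=1, mleaf=len(y), seed=0))
        pred = predict(model, X)
        assert len(np.unique(pred)) == 1

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError, match="single class"):
            train_rf(X, np.full(20, WOOD), RFConfig(seed=0))

    def test_nonfinite_features_rejected(self, rng):
        X, y = _toy_features(rng)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train_rf(X, y, RFConfig(seed=0))

    def test_row_permutation_equivariance(self, rng):
        X, y = _toy_features(rng)
        model = train_rf(X, y, RFConfig(seed=0))
        perm = rng.permutation(len(X))
        np.testing.assert_array_equal(predict(model, X[perm]),
                                      predict(model, X)[perm])

    def test_duplicated_row_same_prediction(self, rng):
        X, y = _toy_features(rng)
        model = train_rf(X, y, RFConfig(seed=0))
        X2 = np.vstack([X[:1], X[:1]])
        p = predict(model, X2)
        assert p[0] == p[1]

    def test_column_count_mismatch_rejected(self, rng):
        X, y = _toy_features(rng)
        model = train_rf(X, y, RFConfig(seed=0))
        with pytest.raises(ValueError, match="feature columns"):
            predict(model, X[:, :3])

    def test_default_max_features_is_floor_sqrt(self):
        cfg = RFConfig()
        assert cfg.resolve_max_features(60) == 7
        assert cfg.resolve_max_features(12) == 3

    def test_save_load_round_trip(self, rng, tmp_path):
        X, y = _toy_features(rng)
        model = train_rf(X, y, RFConfig(seed=0))
        path = tmp_path / "model.pkl"
        model.save(str(path))
        from leafwood import SeparationModel

        back = SeparationModel.load(str(path))
        np.testing.assert_array_equal(predict(back, X), predict(model, X))


class TestPropagateLabels:
    def test_identity_when_all_points_are_core(self, balanced_cloud):
        core = subsample_core_points(balanced_cloud, 1.0, seed=0)
        out = propagate_labels(balanced_cloud, core,
                               balanced_cloud.labels[core.indices])
        np.testing.assert_array_equal(out, balanced_cloud.labels)

    def test_single_core_point_floods_cloud(self, rng):
        pc = LabeledPointCloud(coords=rng.normal(size=(50, 3)))
        out = propagate_labels(pc, np.array([7]), np.array([WOOD]))
        assert (out == WOOD).all()

    def test_matches_brute_force(self, rng):
        pc = LabeledPointCloud(coords=rng.uniform(size=(2000, 3)))
        core = subsample_core_points(pc, 0.1, seed=4)
        core_labels = rng.integers(0, 2, size=len(core))
        out = propagate_labels(pc, core, core_labels)
        expected = brute_nearest_core(pc.coords, core.indices, core_labels)
        np.testing.assert_array_equal(out, expected)

    def test_empty_core_rejected(self, rng):
        pc = LabeledPointCloud(coords=rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="empty"):
            propagate_labels(pc, np.array([], dtype=int), np.array([], dtype=int))
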