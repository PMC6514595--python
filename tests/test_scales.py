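"""Eigen-decomposition, eigen-entropy, and scale selection strategies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafwood import (
    LabeledPointCloud,
    build_scale_grid,
    eigen_decompose,
    eigen_entropy,
    entropy_table,
    sample_leaf_cluster,
    select_scales,
)
from leafwood.scales import LN3, EntropyTable

from oracles import brute_cov_eigenvalues, brute_entropy

# frozen: -(1/6 ln 1/6 + 1/3 ln 1/3 + 1/2 ln 1/2) for eigenvalues (1, 2, 3)
ENTROPY_123 = 1.0114042647073518


class TestEigenDecompose:
    def test_collinear_z_points(self):
        pts = np.array([[0, 0, z] for z in range(5)], dtype=float)
        t = eigen_decompose(pts)
        np.testing.assert_allclose(t.lambdas, [0.0, 0.0, 2.0], atol=1e-12)

    def test_coplanar_grid_normal_is_vertical(self):
        xs, ys = np.meshgrid(np.arange(4.0), np.arange(4.0))
        pts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(16)])
        t = eigen_decompose(pts)
        assert t.lambdas[0] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(np.abs(t.normal), [0, 0, 1], atol=1e-12)

    def test_matches_brute_force_covariance(self, rng):
        pts = rng.normal(size=(200, 3)) @ np.diag([3.0, 1.0, 0.2])
        t = eigen_decompose(pts)
        expected = brute_cov_eigenvalues(pts)
        np.testing.assert_allclose(t.lambdas, expected, rtol=1e-9)

    def test_alphas_normalized(self, rng):
        t = eigen_decompose(rng.normal(size=(50, 3)))
        assert t.alphas.sum() == pytest.approx(1.0)
        assert ((t.alphas >= 0) & (t.alphas <= 1)).all()

    def test_coincident_points_give_uniform_alphas(self):
        pts = np.zeros((10, 3))
        t = eigen_decompose(pts)
        np.testing.assert_allclose(t.alphas, 1 / 3)
        assert eigen_entropy(t) == pytest.approx(LN3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            eigen_decompose(np.zeros((2, 3)))


class TestEigenEntropy:
    def test_uniform_alphas_give_ln3(self):
        assert eigen_entropy(np.array([1 / 3, 1 / 3, 1 / 3])) == \
            pytest.approx(np.log(3), abs=1e-12)

    def test_pure_line_gives_zero(self):
        assert eigen_entropy(np.array([0.0, 0.0, 1.0])) == 0.0

    def test_eigenvalues_1_2_3(self):
        alphas = np.array([1 / 6, 1 / 3, 1 / 2])
        assert eigen_entropy(alphas) == pytest.approx(ENTROPY_123, abs=1e-12)
        assert brute_entropy(np.array([1.0, 2.0, 3.0])) == \
            pytest.approx(ENTROPY_123, abs=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(0.0, 1e6), min_size=3, max_size=3))
    def test_entropy_bounded_for_any_eigenvalues(self, lams):
        lam = np.sort(np.asarray(lams))
        total = lam.sum()
        alphas = lam / total if total > 0 else np.full(3, 1 / 3)
        e = eigen_entropy(alphas)
        assert 0.0 <= e <= LN3 + 1e-12


class TestEntropyTable:
    def test_straight_wire_is_near_zero_everywhere(self, rng):
        z = np.linspace(0, 10, 300)
        coords = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        pc = LabeledPointCloud(coords=coords)
        tab = entropy_table(pc, grid=build_scale_grid(10, 50, 10))
        assert (tab.values < 0.05).all()

    def test_isotropic_ball_interior_near_ln3(self):
        pc = sample_leaf_cluster((0, 0, 0), 1.0, 3000, seed=11)
        # interior points only: avoid the boundary where scatter is clipped
        interior = np.flatnonzero(np.linalg.norm(pc.coords, axis=1) < 0.5)[:100]
        tab = entropy_table(pc, query_indices=interior,
                            grid=build_scale_grid(60, 60, 1))
        assert tab.values.mean() > 0.9 * LN3

    def test_values_bounded(self, small_tree):
        tab = entropy_table(small_tree,
                            query_indices=np.arange(0, len(small_tree), 37),
                            grid=build_scale_grid(10, 40, 10))
        assert (tab.values >= 0).all() and (tab.values <= LN3 + 1e-12).all()


def _table(values, ks):
    grid = build_scale_grid(min(ks), max(ks), ks[1] - ks[0])
    return EntropyTable(
        query_indices=np.arange(len(values)), grid=grid,
        values=np.asarray(values, dtype=float),
    )


class TestSelectScales:
    def test_argmin_selection(self):
        tab = _table([[0.9, 0.5, 0.7]], [10, 20, 30])
        sel = select_scales(tab, "multi_optimal", m=1)
        assert sel.selected.tolist() == [[20]]

    def test_m_equals_grid_returns_all_scales_ascending(self):
        tab = _table([[0.9, 0.5, 0.7]], [10, 20, 30])
        sel = select_scales(tab, "multi_optimal", m=3)
        assert sel.selected.tolist() == [[10, 20, 30]]

    def test_tie_breaks_toward_smaller_k(self):
        tab = _table([[0.5, 0.5, 0.9]], [10, 20, 30])
        sel = select_scales(tab, "multi_optimal", m=1)
        assert sel.selected.tolist() == [[10]]

    def test_optimal_equals_multi_optimal_m1(self, small_tree):
        tab = entropy_table(small_tree,
                            query_indices=np.arange(0, len(small_tree), 11),
                            grid=build_scale_grid(10, 50, 10))
        a = select_scales(tab, "optimal")
        b = select_scales(tab, "multi_optimal", m=1)
        np.testing.assert_array_equal(a.selected, b.selected)

    def test_nested_selections_across_m(self):
        rng = np.random.default_rng(0)
        tab = _table(rng.uniform(0, LN3, size=(40, 5)), [10, 20, 30, 40, 50])
        for m in range(1, 5):
            a = select_scales(tab, "multi_optimal", m=m)
            b = select_scales(tab, "multi_optimal", m=m + 1)
            for ra, rb in zip(a.selected, b.selected):
                assert set(ra) <= set(rb)

    def test_random_subset_shared_by_all_points(self):
        rng = np.random.default_rng(1)
        tab = _table(rng.uniform(0, 1, size=(20, 5)), [10, 20, 30, 40, 50])
        sel = select_scales(tab, "multi_scale_random", m=3, seed=77)
        assert (sel.selected == sel.selected[0]).all()
        assert list(sel.selected[0]) == sorted(sel.selected[0])
        sel2 = select_scales(tab, "multi_scale_random", m=3, seed=77)
        np.testing.assert_array_equal(sel.selected, sel2.selected)

    def test_m_out_of_range_rejected(self):
        tab = _table([[0.1, 0.2]], [10, 20])
        with pytest.raises(ValueError):
            select_scales(tab, "multi_optimal", m=3)
        with pytest.raises(ValueError, match="seed"):
            select_scales(tab, "multi_scale_random", m=2)

    def test_wood_and_leaf_prefer_different_scales(self, benchmark_tree):
        from leafwood import WOOD

        idx = np.arange(0, len(benchmark_tree), 10)
        tab = entropy_table(benchmark_tree, query_indices=idx,
                            grid=build_scale_grid(10, 100, 10))
        sel = select_scales(tab, "optimal")
        wood = benchmark_tree.labels[idx] == WOOD
        med_w = np.median(sel.selected[wood])
        med_l = np.median(sel.selected[~wood])
        assert med_w != med_l
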