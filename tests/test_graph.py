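import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtvdmri import DWIVolume, GradientTable, GraphConfig, spatial_patch_grid
from gtvdmri.graph import (
    affinity_weight,
    angular_neighbors,
    build_patch_graph,
    write_edge_list,
)

CFG = GraphConfig()


class TestAffinityWeight:
    def test_identical_nodes_give_one(self):
        q = np.array([0.0, 0.0, 1.0])
        w = affinity_weight((0, 0, 0), q, 1000, (0, 0, 0), q, 1000, CFG)
        assert w == pytest.approx(1.0, abs=1e-15)

    def test_antipodal_direction_equivalent(self):
        q = np.array([0.6, 0.8, 0.0])
        w1 = affinity_weight((0, 0, 0), q, 1000, (2, 0, 0), q, 1000, CFG)
        w2 = affinity_weight((0, 0, 0), q, 1000, (2, 0, 0), -q, 1000, CFG)
        assert w1 == pytest.approx(w2, rel=1e-15)

    def test_spatial_factor_worked_example(self):
        # 2 mm offset along x with sigma_x = 8: exp(-4/128)
        q = np.array([1.0, 0.0, 0.0])
        w = affinity_weight((0, 0, 0), q, 1000, (2, 0, 0), q, 1000, CFG)
        assert w == pytest.approx(np.exp(-4.0 / 128.0), rel=1e-12)
        assert w == pytest.approx(0.96923, abs=5e-6)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        xa, xb = rng.normal(size=3), rng.normal(size=3)
        qa, qb = rng.normal(size=3), rng.normal(size=3)
        qa /= np.linalg.norm(qa)
        qb /= np.linalg.norm(qb)
        ba, bb = rng.uniform(500, 3000, size=2)
        w_ab = affinity_weight(xa, qa, ba, xb, qb, bb, CFG)
        w_ba = affinity_weight(xb, qb, bb, xa, qa, ba, CFG)
        assert w_ab == pytest.approx(w_ba, rel=1e-12)
        assert 0 < w_ab <= 1

    def test_monotone_in_each_factor(self):
        e1 = np.array([1.0, 0.0, 0.0])
        # spatial distance
        dists = [0.0, 1.0, 2.0, 5.0]
        ws = [
            affinity_weight((0, 0, 0), e1, 1000, (d, 0, 0), e1, 1000, CFG)
            for d in dists
        ]
        assert all(a >= b for a, b in zip(ws, ws[1:]))
        # angular separation
        thetas = np.linspace(0, np.pi / 2, 5)
        ws = [
            affinity_weight(
                (0, 0, 0), e1, 1000, (0, 0, 0),
                (np.cos(t), np.sin(t), 0.0), 1000, CFG,
            )
            for t in thetas
        ]
        assert all(a >= b for a, b in zip(ws, ws[1:]))
        # b-value separation (fixed normalization scale)
        dbs = [0.0, 200.0, 500.0, 1000.0]
        ws = [
            affinity_weight(
                (0, 0, 0), e1, 1000, (0, 0, 0), e1, 1000 + db, CFG, b_scale=2000.0
            )
            for db in dbs
        ]
        assert all(a >= b for a, b in zip(ws, ws[1:]))

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError):
            affinity_weight(
                (0, 0, 0), (2.0, 0, 0), 1000, (0, 0, 0), (1.0, 0, 0), 1000, CFG
            )


class TestAngularNeighbors:
    def test_k1_is_self_only(self, dw_table):
        for j, nb in enumerate(angular_neighbors(dw_table, 1)):
            np.testing.assert_array_equal(nb, [j])

    def test_orthonormal_tie_break(self):
        gt = GradientTable(
            [1000.0] * 3, [[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]]
        )
        nb = angular_neighbors(gt, 2)
        # Each direction picks the lowest-index orthogonal candidate; after
        # symmetrization direction 0 is linked to both 1 and 2.
        np.testing.assert_array_equal(nb[0], [0, 1, 2])
        np.testing.assert_array_equal(nb[1], [0, 1])
        np.testing.assert_array_equal(nb[2], [0, 2])

    def test_antipodal_duplicate_is_first_neighbor(self):
        gt = GradientTable(
            [1000.0] * 3, [[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0]]
        )
        nb = angular_neighbors(gt, 2)
        assert 1 in nb[0]  # the antipode of direction 0 maximizes <q,q'>^2

    def test_k_too_large_raises(self, dw_table):
        with pytest.raises(ValueError):
            angular_neighbors(dw_table, len(dw_table) + 1)


def tiny_volume(dims, gradients, voxel_size=(2.0, 2.0, 2.0)):
    data = np.zeros(tuple(dims) + (len(gradients),))
    return DWIVolume(data, gradients, voxel_size)


class TestBuildPatchGraph:
    def test_single_node_no_edges(self):
        gt = GradientTable([1000.0], [[1.0, 0, 0]])
        g = build_patch_graph((0, 0, 0), 1, tiny_volume((1, 1, 1), gt), CFG)
        assert g.n_nodes == 1
        assert g.n_edges == 0

    def test_two_voxel_single_edge_weight(self):
        gt = GradientTable([1000.0], [[1.0, 0, 0]])
        g = build_patch_graph((0, 0, 0), 2, tiny_volume((2, 1, 1), gt), CFG)
        assert g.n_nodes == 2
        assert g.n_edges == 1
        assert g.weights[0] == pytest.approx(
            np.exp(-(2.0**2) / (2 * CFG.sigma_x**2)), rel=1e-12
        )

    def test_full_patch_node_count_and_weight_range(self, gtab30):
        g = build_patch_graph((0, 0, 0), 5, tiny_volume((5, 5, 5), gtab30), CFG)
        assert g.n_nodes == 125 * 30  # b=0 volume excluded
        assert np.all(g.weights > 0)
        assert np.all(g.weights <= 1)
        assert np.all(g.edges[:, 0] < g.edges[:, 1])
        # no duplicate edges
        assert len({(a, b) for a, b in g.edges}) == g.n_edges

    def test_edge_set_matches_brute_force(self):
        """O(N^2) re-derivation of the neighborhood rule on a small patch."""
        gt = GradientTable([1000.0] * 4, np.random.default_rng(2).normal(size=(4, 3)))
        cfg = GraphConfig(angular_k=2)
        vol = tiny_volume((2, 2, 2), gt, voxel_size=(2.0, 2.0, 3.0))
        g = build_patch_graph((0, 0, 0), 2, vol, cfg)

        nb = angular_neighbors(gt, 2)
        adj = np.zeros((4, 4), dtype=bool)
        for j, lst in enumerate(nb):
            adj[j, lst] = True
        expected = {}
        nodes = [(x, y, z, j) for x, y, z in itertools.product(range(2), repeat=3)
                 for j in range(4)]
        for a, b in itertools.combinations(range(len(nodes)), 2):
            xa, ya, za, ja = nodes[a]
            xb, yb, zb, jb = nodes[b]
            if max(abs(xa - xb), abs(ya - yb), abs(za - zb)) > cfg.spatial_radius:
                continue
            if not adj[ja, jb]:
                continue
            w = affinity_weight(
                (2 * xa, 2 * ya, 3 * za), gt.bvecs[ja], 1000,
                (2 * xb, 2 * yb, 3 * zb), gt.bvecs[jb], 1000, cfg,
            )
            expected[(a, b)] = w
        got = {tuple(e): w for e, w in zip(g.edges, g.weights)}
        assert set(got) == set(expected)
        for key in expected:
            assert got[key] == pytest.approx(expected[key], rel=1e-10)

    def test_axis_relabel_invariance(self, dw_table):
        """Permuting spatial axes consistently leaves the weight multiset unchanged."""
        vol_a = tiny_volume((2, 3, 4), dw_table, voxel_size=(1.0, 2.0, 3.0))
        vol_b = tiny_volume((4, 2, 3), dw_table, voxel_size=(3.0, 1.0, 2.0))
        ga = build_patch_graph((0, 0, 0), 4, vol_a, CFG)
        gb = build_patch_graph((0, 0, 0), 4, vol_b, CFG)
        assert ga.n_edges == gb.n_edges
        np.testing.assert_allclose(
            np.sort(ga.weights), np.sort(gb.weights), rtol=1e-12
        )

    def test_b0_volumes_excluded(self, gtab30):
        g = build_patch_graph((0, 0, 0), 2, tiny_volume((2, 2, 2), gtab30), CFG)
        assert 0 not in set(g.nodes[:, 3])  # volume 0 is the b=0 image

    def test_weight_floor_drops_edges(self, dw_table):
        vol = tiny_volume((3, 3, 3), dw_table)
        g_all = build_patch_graph((0, 0, 0), 3, vol, GraphConfig(weight_floor=0.0))
        floor = float(np.median(g_all.weights))
        g_cut = build_patch_graph((0, 0, 0), 3, vol, GraphConfig(weight_floor=floor))
        assert g_cut.n_edges < g_all.n_edges
        assert np.all(g_cut.weights > floor)

    def test_edge_list_export(self, tmp_path, dw_table):
        g = build_patch_graph((0, 0, 0), 2, tiny_volume((2, 1, 1), dw_table), CFG)
        out = tmp_path / "edges.txt"
        write_edge_list(g, out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == g.n_edges
        a, b, w = lines[0].split()
        assert int(a) < int(b)
        assert 0 < float(w) <= 1


class TestPatchGrid:
    def test_patch_equals_volume(self):
        grid = spatial_patch_grid((5, 5, 5), 5, 2)
        np.testing.assert_array_equal(grid.origins, [[0, 0, 0]])

    def test_forced_final_origin(self):
        grid = spatial_patch_grid((9, 9, 9), 5, 2)
        per_axis = sorted(set(grid.origins[:, 0]))
        assert per_axis == [0, 2, 4]  # 4 + 5 = 9 already touches the boundary

    def test_full_coverage_default_grid(self):
        grid = spatial_patch_grid((16, 16, 16), 5, 2)
        counts = grid.coverage_counts()
        assert counts.min() >= 1

    def test_invalid_step_raises(self):
        with pytest.raises(ValueError):
            spatial_patch_grid((8, 8, 8), 5, 0)
        with pytest.raises(ValueError):
            spatial_patch_grid((8, 8, 8), 2, 5)
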