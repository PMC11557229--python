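"""Skeletonization, graph conversion, junction pruning and smoothing."""

import networkx as nx
import numpy as np
import pytest

from fibromorph.phantoms import _paint_tube
from fibromorph.skeleton import (
    SkeletonGraph,
    extract_skeleton,
    filter_components,
    prune_junctions,
    robust_medial_axis,
    smooth,
    to_graph,
)
from fibromorph.volumes import BinaryVolume


def _tube_volume(a, b, r=3.0, shape=(48, 48, 16), voxel=2.0):
    g = np.zeros(shape, dtype=np.uint8)
    _paint_tube(g, np.asarray(a, float), np.asarray(b, float), r)
    return BinaryVolume(g, voxel)


def _graph_from_points(points, edges, voxel=1.0):
    g = nx.Graph()
    for i, p in enumerate(points):
        g.add_node(i, pos=np.asarray(p, dtype=float))
    g.add_edges_from(edges)
    return SkeletonGraph(graph=g, voxel_size=voxel)


class TestRobustMedialAxis:
    def test_straight_tube_axis_recovered(self):
        vol = _tube_volume((0, 24, 8), (47, 24, 8))
        mask = robust_medial_axis(vol)
        coords = np.argwhere(mask.grid > 0)
        interior = coords[(coords[:, 0] > 4) & (coords[:, 0] < 43)]
        dist = np.linalg.norm(interior[:, 1:] - np.array([24, 8]), axis=1)
        assert dist.max() <= 1.0

    def test_skeleton_within_fibre_phase(self):
        vol = _tube_volume((0, 10, 8), (47, 40, 8))
        mask = robust_medial_axis(vol)
        assert (vol.grid[mask.grid > 0] == 1).all()

    def test_single_voxel(self):
        g = np.zeros((8, 8, 8), dtype=np.uint8)
        g[3, 3, 3] = 1
        mask = robust_medial_axis(BinaryVolume(g, 1.0))
        np.testing.assert_array_equal(mask.grid, g)

    def test_empty_volume_empty_skeleton(self):
        mask = robust_medial_axis(BinaryVolume(np.zeros((6, 6, 6), np.uint8), 1.0))
        assert mask.grid.sum() == 0

    def test_rotation_equivariance_on_symmetric_tube(self):
        vol = _tube_volume((0, 24, 8), (47, 24, 8))
        rot = BinaryVolume(np.rot90(vol.grid, 1, axes=(0, 1)).copy(), vol.voxel_size)
        skel_rot = robust_medial_axis(rot).grid
        rot_skel = np.rot90(robust_medial_axis(vol).grid, 1, axes=(0, 1))
        np.testing.assert_array_equal(skel_rot, rot_skel)


class TestToGraph:
    def test_adjacent_pair_single_edge(self):
        g = np.zeros((4, 4, 4), dtype=np.uint8)
        g[1, 1, 1] = g[2, 1, 1] = 1
        sg = to_graph(BinaryVolume(g, 2.0))
        assert sg.n_vertices == 2 and sg.n_edges == 1
        (u, v), = sg.graph.edges()
        length = np.linalg.norm(sg.graph.nodes[u]["pos"] - sg.graph.nodes[v]["pos"])
        assert length == pytest.approx(2.0)

    def test_l_shape_includes_diagonal(self):
        g = np.zeros((4, 4, 4), dtype=np.uint8)
        g[1, 1, 1] = g[2, 1, 1] = g[2, 2, 1] = 1
        sg = to_graph(BinaryVolume(g, 1.0))
        assert sg.n_vertices == 3 and sg.n_edges == 3  # the diagonal is present

    def test_empty_mask(self):
        sg = to_graph(BinaryVolume(np.zeros((3, 3, 3), np.uint8), 1.0))
        assert sg.n_vertices == 0 and sg.n_edges == 0


class TestPruneJunctions:
    def test_t_junction_removes_perpendicular_stub(self):
        pts = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (1, 1, 0)]
        sg = _graph_from_points(pts, [(0, 1), (1, 2), (1, 3)])
        out = prune_junctions(sg)
        assert out.graph.has_edge(0, 1) and out.graph.has_edge(1, 2)
        assert not out.graph.has_edge(1, 3)

    def test_path_graph_identity(self):
        pts = [(i, 0, 0) for i in range(5)]
        sg = _graph_from_points(pts, [(i, i + 1) for i in range(4)])
        out = prune_junctions(sg)
        assert set(out.graph.edges()) == set(sg.graph.edges())

    def test_max_degree_two_postcondition(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            mask = (rng.random((8, 8, 8)) < 0.2).astype(np.uint8)
            sg = to_graph(BinaryVolume(mask, 1.0))
            out = prune_junctions(sg)
            assert all(d <= 2 for _, d in out.graph.degree())
            # pruning never creates vertices or edges
            assert out.n_vertices == sg.n_vertices
            assert out.n_edges <= sg.n_edges


class TestSmooth:
    def test_straight_path_is_fixed_point(self):
        pts = [(float(i), 0, 0) for i in range(6)]
        sg = _graph_from_points(pts, [(i, i + 1) for i in range(5)])
        out = smooth(sg, rounds=10, lam=0.5)
        for i, p in enumerate(pts):
            np.testing.assert_allclose(out.graph.nodes[i]["pos"], p)

    def test_zigzag_curvature_decreases_each_round(self):
        pts = [(i, i % 2, 0.0) for i in range(10)]
        sg = _graph_from_points(pts, [(i, i + 1) for i in range(9)])

        def curvature(s):
            pos = s.positions()
            total = 0.0
            for n in s.graph.nodes:
                nbrs = list(s.graph.neighbors(n))
                if len(nbrs) == 2:
                    total += np.linalg.norm(
                        pos[nbrs[0]] + pos[nbrs[1]] - 2 * pos[n]
                    )
            return total

        prev = curvature(sg)
        cur = sg
        for _ in range(5):
            cur = smooth(cur, rounds=1, lam=0.5)
            c = curvature(cur)
            assert c < prev
            prev = c

    def test_four_cycle_single_round_arithmetic(self):
        pts = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]
        sg = _graph_from_points(pts, [(0, 1), (1, 2), (2, 3), (3, 0)])
        out = smooth(sg, rounds=1, lam=0.5)
        # each vertex moves halfway to the mean of its two neighbours
        expected0 = 0.5 * np.array([0, 0, 0]) + 0.5 * (
            np.array([1, 0, 0]) + np.array([0, 1, 0])
        ) / 2
        np.testing.assert_allclose(out.graph.nodes[0]["pos"], expected0)

    def test_edge_set_unchanged(self):
        pts = [(i, (i * i) % 3, 0.0) for i in range(8)]
        sg = _graph_from_points(pts, [(i, i + 1) for i in range(7)])
        out = smooth(sg, rounds=10, lam=0.5)
        assert set(out.graph.edges()) == set(sg.graph.edges())


class TestComponentFilter:
    def test_nineteen_vs_twenty_edges(self):
        pts = [(i, 0, 0) for i in range(20)] + [(i, 5, 0) for i in range(21)]
        edges = [(i, i + 1) for i in range(19)]  # 19-edge path
        edges += [(20 + i, 21 + i) for i in range(20)]  # 20-edge path
        sg = _graph_from_points(pts, edges)
        out = filter_components(sg, min_edges=20)
        assert out.n_edges == 20
        assert len(set(out.components.values())) == 1


class TestExtractSkeleton:
    def test_disjoint_tubes_become_paths(self):
        g = np.zeros((64, 64, 16), dtype=np.uint8)
        for y in (10, 30, 50):
            _paint_tube(g, np.array([0.0, y, 8.0]), np.array([63.0, y, 8.0]), 3.0)
        sg = extract_skeleton(BinaryVolume(g, 2.0))
        comps = set(sg.components.values())
        assert len(comps) == 3
        assert all(d <= 2 for _, d in sg.graph.degree())

    @pytest.mark.parametrize("azimuth", [0, 30, 60, 90])
    def test_axis_recovery_at_azimuths(self, azimuth):
        phi = np.radians(azimuth)
        c = np.array([31.3, 31.7, 8.2])  # off-lattice axis, as in real data
        u = np.array([np.cos(phi), np.sin(phi), 0.0])
        a, b = c - 40 * u, c + 40 * u
        g = np.zeros((64, 64, 16), dtype=np.uint8)
        _paint_tube(g, a, b, 3.0)
        vol = BinaryVolume(g, 2.0)
        sg = extract_skeleton(vol)
        assert sg.n_edges > 0
        pos = np.array(list(sg.positions().values())) / vol.voxel_size
        t = (pos - c) @ u
        interior = np.abs(t) < 24
        dist = np.linalg.norm((pos - c) - np.outer(t, u), axis=1)[interior]
        assert dist.mean() < 1.0

    def test_empty_volume_empty_graph(self):
        sg = extract_skeleton(BinaryVolume(np.zeros((8, 8, 8), np.uint8), 1.0))
        assert sg.n_vertices == 0
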