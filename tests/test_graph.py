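"""Graph-based estimator: cleanup, skeleton, graph topology, measurement."""

from __future__ import annotations

import numpy as np
import pytest

import pvvkit as pk
from pvvkit.graph import (
    DenoiseParams,
    build_graph,
    denoise_skeleton,
    extract_skeleton,
    graph_pvv,

    morphological_close,
    threshold_components_3d,
)

from conftest import make_skeleton


def _mask(data, spacing=(1.0, 1.0, 1.0)):
    return pk.VoxelGrid(np.asarray(data, bool), spacing)


class TestThresholdComponents3D:
    def test_single_voxel_below_threshold_removed(self):
        data = np.zeros((8, 8, 8))
        data[4, 4, 4] = 1
        g = pk.VoxelGrid(data.astype(bool), (0.5, 0.5, 3.0))  # 0.75 mm^3 voxel
        assert threshold_components_3d(g, 50.0).data.sum() == 0

    def test_zero_threshold_identity(self):
        rng = np.random.default_rng(0)
        g = _mask(rng.random((10, 10, 10)) > 0.5)
        assert np.array_equal(threshold_components_3d(g, 0.0).data, g.data)

    def test_speckles_removed_tree_untouched(self, small_tree):
        _, _, mask, lung = small_tree
        cluttered, report = pk.add_clutter(mask, lung,
                                           pk.ClutterSpec(n_speckles=80, seed=1))
        cleaned = threshold_components_3d(cluttered, 50.0)
        assert np.array_equal(cleaned.data, mask.data)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_components_3d(_mask(np.zeros((4, 4, 4))), -1.0)


class TestMorphologicalClose:
    def test_crack_closed_into_one_component(self):
        from scipy import ndimage

        data = np.zeros((20, 20, 20), bool)
        data[5:15, 5:15, 4:9] = True
        data[5:15, 5:15, 10:16] = True  # 1-voxel transverse crack at z=9
        g = _mask(data)
        _, n0 = ndimage.label(data, np.ones((3, 3, 3)))
        closed = morphological_close(g, 1.0)
        _, n1 = ndimage.label(closed.data, np.ones((3, 3, 3)))
        assert (n0, n1) == (2, 1)

    def test_zero_radius_identity(self):
        rng = np.random.default_rng(1)
        g = _mask(rng.random((10, 10, 10)) > 0.5)
        assert np.array_equal(morphological_close(g, 0.0).data, g.data)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        g = _mask(rng.random((16, 16, 16)) > 0.6)
        once = morphological_close(g, 1.5)
        twice = morphological_close(once, 1.5)
        assert np.array_equal(once.data, twice.data)


class TestExtractSkeleton:
    def test_empty_mask_empty_skeleton(self):
        sk = extract_skeleton(_mask(np.zeros((8, 8, 8))))
        assert len(sk) == 0

    def test_solid_ball_reduces_to_few_voxels(self):
        x, y, z = np.meshgrid(*[np.arange(20) - 9.5] * 3, indexing="ij")
        ball = x**2 + y**2 + z**2 <= 49
        sk = extract_skeleton(_mask(ball))
        assert 1 <= len(sk) <= 5

    def test_cylinder_chain_and_radius(self, cylinder_factory):
        mask, _, _ = cylinder_factory(radius=2.0, tilt=0.0)
        sk = extract_skeleton(mask)
        # one chain: every voxel has <= 2 neighbors, components == 1
        assert sk.n_components == 1
        diag = np.linalg.norm(mask.spacing)
        assert abs(np.median(sk.radius) - 2.0) < diag

    def test_topology_preserved_components(self, small_tree):
        from scipy import ndimage

        _, _, mask, lung = small_tree
        cluttered, _ = pk.add_clutter(mask, lung, pk.ClutterSpec(n_speckles=30, seed=3))
        sk = extract_skeleton(cluttered)
        _, n_mask = ndimage.label(cluttered.data, np.ones((3, 3, 3)))
        assert sk.n_components == n_mask

    def test_skeleton_inside_mask_with_positive_radius(self, small_tree):
        _, _, mask, _ = small_tree
        sk = extract_skeleton(mask)
        assert mask.data[tuple(sk.voxels.T)].all()
        assert (sk.radius > 0).all()

    def test_lattice_symmetric_cylinder_not_annihilated(self):
        # the degenerate case where parallel thinning deletes everything:
        # axis exactly midway between voxel centers
        n = 32
        x, y = np.meshgrid(np.arange(n) - 15.5, np.arange(n) - 15.5, indexing="ij")
        disk = x**2 + y**2 <= 36
        data = np.zeros((n, n, 40), bool)
        data[:, :, 5:35] = disk[:, :, None]
        sk = extract_skeleton(_mask(data))
        zspan = sk.voxels[:, 2].max() - sk.voxels[:, 2].min()
        # tips retract by about one voxel-space radius (6 px) per end
        assert len(sk) > 0 and zspan >= 30 - 2 * 6 - 2


class TestDenoiseSkeleton:
    def test_zero_floors_identity(self, small_tree):
        _, _, mask, lung = small_tree
        sk = extract_skeleton(mask)
        out = denoise_skeleton(sk, lung, DenoiseParams(min_radius_core=0,
                                                       min_radius_boundary=0))
        assert len(out) == len(sk)

    def test_thin_voxel_at_pleural_surface_removed(self):
        # hand-built: lung occupies a box; skeleton voxel on its boundary
        lung = np.zeros((20, 20, 20), bool)
        lung[5:15, 5:15, 5:15] = True
        skel = make_skeleton([(5, 10, 10), (10, 10, 10)], radius=0.5,
                             shape=(20, 20, 20))
        out = denoise_skeleton(skel, _mask(lung),
                               DenoiseParams(min_radius_boundary=1.0,
                                             boundary_shell_depth=3.0))
        kept = set(map(tuple, out.voxels))
        assert (5, 10, 10) not in kept   # surface voxel, r=0.5 < 1.0
        assert (10, 10, 10) in kept      # deep voxel, floor decayed to ~core

    def test_speckle_skeletons_removed_true_branches_kept(self):
        # acquisition-regime grid: 0.5 mm pixels keep speckle EDT radii
        # below the pleural radius floor
        tree, _ = pk.generate_tree(pk.TreeSpec(generations=3, seed=5))
        mask, lung = pk.rasterize(tree)
        cluttered, _ = pk.add_clutter(
            mask, lung,
            pk.ClutterSpec(n_speckles=50, speckle_radius_range=(0.3, 0.5),
                           shell_depth=3.0, seed=3),
        )
        sk = extract_skeleton(cluttered)
        out = denoise_skeleton(sk, lung)
        tree_vox = set(map(tuple, np.argwhere(mask.data)))
        kept = [tuple(v) in tree_vox for v in out.voxels]
        assert all(kept), "a clutter skeleton voxel survived"
        before_tree = sum(tuple(v) in tree_vox for v in sk.voxels)
        assert len(out) == before_tree, "a true-branch voxel was removed"

    def test_voxels_outside_lung_warn(self):
        lung = np.zeros((10, 10, 10), bool)
        lung[4:6, 4:6, 4:6] = True
        skel = make_skeleton([(0, 0, 0)], radius=5.0, shape=(10, 10, 10))
        with pytest.warns(UserWarning, match="outside"):
            out = denoise_skeleton(skel, _mask(lung), DenoiseParams())
        assert len(out) == 1  # radius 5 clears any floor


class BruteForceGraphOracle:
    """Independent node/edge counter on a skeleton voxel set.

    Enumerates 26-adjacency directly: endpoints are voxels with exactly one
    neighbor, junction clusters are flood-filled groups of voxels with >= 3
    neighbors, and edges are counted by removing node voxels and counting
    the leftover chain fragments plus direct node-node adjacencies.
    """

    def __init__(self, voxels):
        self.vox = [tuple(v) for v in voxels]
        vs = set(self.vox)
        self.nbrs = {
            v: [
                (v[0] + a, v[1] + b, v[2] + c)
                for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
                if (a, b, c) != (0, 0, 0) and (v[0] + a, v[1] + b, v[2] + c) in vs
            ]
            for v in self.vox
        }

    def counts(self):
        deg = {v: len(n) for v, n in self.nbrs.items()}
        endpoints = [v for v, d in deg.items() if d == 1]
        junction_vox = {v for v, d in deg.items() if d >= 3}
        clusters = []
        seen = set()
        for v in junction_vox:
            if v in seen:
                continue
            stack, comp = [v], set()
            seen.add(v)
            while stack:
                u = stack.pop()
                comp.add(u)
                for w in self.nbrs[u]:
                    if w in junction_vox and w not in seen:
                        seen.add(w)
                        stack.append(w)
            clusters.append(comp)
        n_nodes = len(endpoints) + len(clusters)
        # edges: chain fragments after node removal
        node_vox = set(endpoints) | junction_vox
        chain = {v for v in self.vox if v not in junction_vox and deg[v] == 2}
        chain |= set()  # degree-2 only
        remaining = {v for v in self.vox if v not in node_vox}
        comps = []
        seen = set()
        for v in remaining:
            if v in seen:
                continue
            stack, comp = [v], set()
            seen.add(v)
            while stack:
                u = stack.pop()
                comp.add(u)
                for w in self.nbrs[u]:
                    if w in remaining and w not in seen:
                        seen.add(w)
                        stack.append(w)
            comps.append(comp)
        n_edges = len(comps)
        # direct node-to-node contacts (distinct super-nodes)
        def node_id(v):
            if v in junction_vox:
                for i, c in enumerate(clusters):
                    if v in c:
                        return ("j", i)
            return ("e", v)
        direct = set()
        for v in node_vox:
            for w in self.nbrs[v]:
                if w in node_vox and node_id(v) != node_id(w):
                    direct.add(frozenset((node_id(v), node_id(w))))
        return n_nodes, n_edges + len(direct), len(endpoints), len(clusters)


class TestBuildGraph:
    def test_straight_chain(self):
        skel = make_skeleton([(i, 5, 5) for i in range(20)])
        g = build_graph(skel)
        oracle = BruteForceGraphOracle(skel.voxels).counts()
        assert (g.number_of_nodes(), g.number_of_edges()) == oracle[:2] == (2, 1)
        assert g.n_endpoints == 2

    def test_y_bifurcation(self):
        vox = ([(5, 5, i) for i in range(10)]
               + [(5 + i, 5, 9 + i) for i in range(1, 8)]
               + [(5 - i, 5, 9 + i) for i in range(1, 8)])
        skel = make_skeleton(vox)
        g = build_graph(skel)
        n_nodes, n_edges, n_end, n_junc = BruteForceGraphOracle(skel.voxels).counts()
        assert (g.number_of_nodes(), g.number_of_edges()) == (n_nodes, n_edges)
        assert (g.n_junctions, g.n_endpoints) == (n_junc, n_end) == (1, 3)
        assert g.number_of_edges() == 3

    def test_double_bifurcation(self):
        vox = ([(5, 5, i) for i in range(10)]
               + [(5 + i, 5, 9 + i) for i in range(1, 8)]
               + [(5 - i, 5, 9 + i) for i in range(1, 8)]
               + [(12 + i, 5, 16) for i in range(1, 6)]
               + [(12, 5, 16 + i) for i in range(1, 6)])
        skel = make_skeleton(vox)
        g = build_graph(skel)
        oracle = BruteForceGraphOracle(skel.voxels).counts()
        assert (g.number_of_nodes(), g.number_of_edges()) == oracle[:2] == (6, 5)
        assert g.n_junctions == 2

    def test_closed_loop_zero_endpoints(self):
        loop = [(5, 5, 0), (6, 5, 1), (6, 5, 2), (5, 5, 3), (4, 5, 2), (4, 5, 1)]
        g = build_graph(make_skeleton(loop))
        assert g.n_endpoints == 0
        # Euler: one cycle -> V == E
        assert g.number_of_nodes() == g.number_of_edges() == 1

    def test_empty_skeleton(self):
        g = build_graph(make_skeleton(np.empty((0, 3))))
        assert g.number_of_nodes() == 0

    def test_paths_partition_skeleton(self):
        vox = ([(5, 5, i) for i in range(10)]
               + [(5 + i, 5, 9 + i) for i in range(1, 8)]
               + [(5 - i, 5, 9 + i) for i in range(1, 8)])
        skel = make_skeleton(vox)
        g = build_graph(skel)
        owned = []
        for n, d in g.nodes(data=True):
            owned += [tuple(skel.voxels[i]) for i in d["voxels"]]
        for *_, d in g.edges(data=True):
            owned += [tuple(v) for v in d["path"]]
        assert sorted(owned) == sorted(tuple(v) for v in skel.voxels)


class TestMeasureBranches:
    def test_cylinder_volume_within_10pct(self, cylinder_factory):
        for tilt in (0.0, 45.0):
            mask, lung, truth = cylinder_factory(radius=2.0, tilt=tilt)
            res, g = graph_pvv(mask, lung)
            assert res.pvv_total * 1000 == pytest.approx(
                truth.total_volume, rel=0.10
            ), f"tilt={tilt}"

    def test_orientation_independence(self, cylinder_factory):
        r0 = graph_pvv(*cylinder_factory(tilt=0.0)[:2])[0].pvv_total
        r45 = graph_pvv(*cylinder_factory(tilt=45.0)[:2])[0].pvv_total
        assert abs(r45 - r0) / r0 < 0.10

    def test_edge_metrics_consistency(self, small_tree):
        _, _, mask, lung = small_tree
        res, g = graph_pvv(mask, lung)
        for *_, d in g.edges(data=True):
            assert d["length"] > 0
            assert d["area"] == pytest.approx(np.pi * d["radius"] ** 2)
            assert d["volume_ml"] == pytest.approx(
                d["area"] * d["length"] / 1000.0
            )


class TestVtkExport:
    def test_polyline_export_roundtrip_counts(self, small_tree, tmp_path):
        from pvvkit.graph import extract_skeleton, graph_to_vtk

        _, _, mask, lung = small_tree
        res, g = graph_pvv(mask, lung)
        skel = extract_skeleton(mask)
        out = tmp_path / "graph.vtk"
        graph_to_vtk(g, skel, out)
        text = out.read_text().splitlines()
        assert text[0].startswith("# vtk")
        n_lines = int(next(l for l in text if l.startswith("LINES")).split()[1])
        assert n_lines == sum(1 for *_, d in g.edges(data=True)
                              if len(d["path_full"]) >= 2)


class TestGraphPVV:
    def test_empty_mask_zero_result(self):
        res, g = graph_pvv(_mask(np.zeros((8, 8, 4)), (0.5, 0.5, 3.0)))
        assert res.pvv_total == 0 and g.number_of_edges() == 0

    def test_partition_exactness(self, small_tree):
        _, _, mask, lung = small_tree
        res, _ = graph_pvv(mask, lung)
        assert res.pvv5 + res.pvv10 + res.pvv10plus == pytest.approx(res.pvv_total)

    def test_murray_tree_recovery_and_bins(self, small_tree):
        _, truth, mask, lung = small_tree
        res, _ = graph_pvv(mask, lung)
        assert res.pvv_total * 1000 == pytest.approx(truth.total_volume, rel=0.15)

    def test_clutter_changes_nothing(self, small_tree):
        _, _, mask, lung = small_tree
        cluttered, _ = pk.add_clutter(mask, lung, pk.ClutterSpec(n_speckles=100, seed=2))
        r_clean, _ = graph_pvv(mask, lung)
        r_clut, _ = graph_pvv(cluttered, lung)
        assert r_clut.pvv_total == r_clean.pvv_total

    def test_graph_below_slicewise_on_cluttered_masks(self, small_tree):
        _, _, mask, lung = small_tree
        cluttered, _ = pk.add_clutter(mask, lung, pk.ClutterSpec(n_speckles=100, seed=2))
        r_graph, _ = graph_pvv(cluttered, lung)
        r_slice = pk.slicewise_pvv(cluttered)
        assert r_graph.pvv_total <= r_slice.pvv_total

    def test_mismatched_grids_rejected(self, small_tree):
        _, _, mask, _ = small_tree
        other = pk.VoxelGrid(np.zeros((8, 8, 8), bool), (1, 1, 1))
        with pytest.raises(ValueError, match="grid"):
            graph_pvv(mask, other)

    def test_voxel_volume_mode_conserves_mask_volume(self, cylinder_factory):
        mask, lung, _ = cylinder_factory(radius=2.0, tilt=30.0)
        res, _ = graph_pvv(mask, lung, volume_mode="voxel")
        assert res.pvv_total == pytest.approx(mask.mask_volume_ml(), rel=0.02)
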