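"""Morphology builders: printed dimensions, path sampling, slice invariants."""

import numpy as np
import pytest

from magsim.morphology import (ArcPath, DEFAULT_WAYPOINT_BOXES, GBCMorphParams,
                               MNTBMorphParams, WAYPOINT_BOX_SIZE, build_gbc,
                               build_mntb, sample_axon_path, sample_waypoints,
                               spline_polyline)
from magsim.slice_builder import build_slice, load_layout, save_layout, tree_to_swc


class TestGBC:
    def test_printed_dimensions(self):
        tree = build_gbc()
        soma = tree.indices("soma")
        assert np.allclose(tree.diameter[soma], 20.0)
        assert np.isclose(tree.lengths[soma].sum(), 20.0)
        prim = tree.indices("primary_dendrite")
        assert np.allclose(tree.diameter[prim], 3.0)
        assert np.isclose(tree.lengths[prim].sum(), 50.0)
        sec = tree.indices("secondary_dendrite")
        assert np.allclose(tree.diameter[sec], 2.0)
        assert np.isclose(tree.lengths[sec].sum(), 100.0)   # two 50 μm branches

    def test_axon_taper(self):
        tree = build_gbc()
        inter = tree.indices("internode")
        d = tree.diameter[inter]
        assert np.isclose(d[0], 3.0) and np.isclose(d[-1], 3.3, atol=0.01)
        assert np.all(np.diff(d) >= -1e-12)
        nodes = tree.indices("node")
        dn = tree.diameter[nodes]
        assert np.isclose(dn[0], 1.5) and dn[-1] > 1.9
        assert np.all(np.diff(dn) >= -1e-12)                # monotone taper

    def test_node_lengths_exactly_one_micron(self):
        tree = build_gbc()
        assert np.allclose(tree.lengths[tree.indices("node")], 1.0, atol=1e-6)

    def test_internode_lengths_shrink_near_calyx(self):
        p = GBCMorphParams()
        lens = p.internode_lengths()
        tail = lens[p.n_constant_internodes:]
        assert np.all(np.diff(tail) < 0) and np.isclose(tail[-1], 40.0)

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            build_gbc(GBCMorphParams(soma_diameter=-1.0))


class TestMNTB:
    def test_printed_dimensions(self):
        tree = build_mntb(rng=np.random.default_rng(0))
        soma = tree.indices("mntb_soma")
        assert np.allclose(tree.diameter[soma], 20.0)
        inter = tree.indices("mntb_internode")
        assert np.allclose(tree.diameter[inter], 2.0)
        # 5 internodes of 100 μm each
        sec_ids = np.unique(tree.section_id[inter])
        assert len(sec_ids) == 5
        for s in sec_ids:
            # chord-vs-arc shortfall on the curved path is < 1 μm per internode
            assert np.isclose(tree.lengths[tree.section_id == s].sum(), 100.0, atol=1.0)
        assert len(tree.indices("mntb_node")) == 5

    def test_zero_branch_request_rejected(self):
        with pytest.raises(ValueError):
            build_mntb(MNTBMorphParams(n_dendrite_branches=0),
                       rng=np.random.default_rng(0))


class TestAxonPath:
    def test_endpoint_is_calyx_waypoint(self):
        poly = sample_axon_path(np.random.default_rng(5), calyx_center_x=412.0)
        assert np.allclose(poly[-1], [412.0, 0.0, 0.0])

    def test_deterministic_from_seed(self):
        p1 = sample_axon_path(np.random.default_rng(9))
        p2 = sample_axon_path(np.random.default_rng(9))
        assert np.array_equal(p1, p2)

    def test_waypoints_inside_boxes_brute_force(self):
        # membership check over many seeds
        half = WAYPOINT_BOX_SIZE / 2
        for seed in range(1000):
            w = sample_waypoints(np.random.default_rng(seed))
            assert np.all(np.abs(w - DEFAULT_WAYPOINT_BOXES) <= half + 1e-12)

    def test_degenerate_control_points_rejected(self):
        with pytest.raises(ValueError):
            spline_polyline(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))

    def test_segment_density(self):
        poly = sample_axon_path(np.random.default_rng(3), max_seg=10.0)
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        assert seg.max() <= 10.0 + 1e-9


class TestSlice:
    def test_population_counts_and_pairing(self, small_slice):
        lay = small_slice
        assert len(lay.gbc_cells) == len(lay.mntb_cells) == 6
        assert sorted(lay.pairing.tolist()) == list(range(6))

    def test_calyx_centers_inside_ellipse_and_span(self, small_slice):
        c = small_slice.calyx_centers
        assert small_slice.in_ellipse(c[:, :2]).all()
        lo, hi = small_slice.params.active_span
        assert np.all((c[:, 2] >= lo) & (c[:, 2] <= hi))

    def test_bit_identical_rebuild(self, small_slice):
        lay2 = build_slice(n_cells=6, seed=3)
        assert np.array_equal(small_slice.calyx_centers, lay2.calyx_centers)
        for a, b in zip(small_slice.gbc_cells, lay2.gbc_cells):
            assert np.array_equal(a.prox, b.prox) and np.array_equal(a.dist, b.dist)

    def test_single_pair(self):
        lay = build_slice(n_cells=1, seed=0)
        assert lay.n_cells == 1
        assert lay.in_ellipse(lay.calyx_centers[:, :2]).all()

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            build_slice(n_cells=0, seed=0)

    def test_calyx_center_sampling_is_uniform(self):
        lay = build_slice(n_cells=200, seed=11)
        c = lay.calyx_centers
        p = lay.params
        # Monte-Carlo check: empirical means near the ellipse/span centers
        assert abs(c[:, 0].mean() - p.ellipse_center_x) < 3 * p.semi_major / np.sqrt(200)
        assert abs(c[:, 1].mean()) < 3 * p.semi_minor / np.sqrt(200)
        assert abs(c[:, 2].mean() - 175.0) < 3 * 300 / np.sqrt(12 * 200)

    def test_gbc_translated_by_calyx_offset(self, small_slice):
        # pre-shift path ends at (x_c, 0, 0); the built cell ends at (x_c, y_c, z_c)
        for tree, (xc, yc, zc) in zip(small_slice.gbc_cells, small_slice.calyx_centers):
            ph = tree.indices("post_heminode")
            assert np.allclose(tree.dist[ph[-1]], [xc, yc, zc], atol=1e-6)

    def test_serialization_roundtrip(self, small_slice, tmp_path):
        path = tmp_path / "slice.h5"
        save_layout(small_slice, str(path))
        lay2 = load_layout(str(path))
        assert lay2.n_cells == small_slice.n_cells
        assert np.allclose(lay2.calyx_centers, small_slice.calyx_centers)
        assert np.array_equal(lay2.gbc_cells[0].label, small_slice.gbc_cells[0].label)
        assert np.allclose(lay2.gbc_cells[2].prox, small_slice.gbc_cells[2].prox)

    def test_swc_export(self, small_slice, tmp_path):
        swc = tmp_path / "cell.swc"
        tree_to_swc(small_slice.gbc_cells[0], str(swc), sidecar=str(tmp_path / "l.json"))
        lines = [l for l in swc.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == len(small_slice.gbc_cells[0])
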