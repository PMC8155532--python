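"""Field forward model: Biot-Savart limits, superposition, LFP decay, ECD."""

from types import SimpleNamespace

import numpy as np
import pytest

from magsim.fields import (ECDTrace, SensorGrid, SourceGeometry, VolumeConductor,
                           compute_ecd, compute_field_map, compute_lfp,
                           segment_bfield)
from magsim.morphology import CompartmentTree

MU0_4PI = 1e-7


def toy_cell(offset=(0.0, 0.0, 100.0)):
    """Three-compartment chain along x used as a brute-force field source."""
    off = np.asarray(offset, dtype=float)
    prox = np.array([[0, 0, 0], [50, 0, 0], [100, 0, 0]], dtype=float) + off
    dist = np.array([[50, 0, 0], [100, 0, 0], [150, 10, 0]], dtype=float) + off
    return CompartmentTree(parent=np.array([-1, 0, 1]), prox=prox, dist=dist,
                           diameter=np.array([2.0, 2.0, 1.5]),
                           label=np.array(["node"] * 3, dtype="<U20"),
                           section_id=np.arange(3))


def toy_trace(tree, i_axial, i_m=None, n_frames=1):
    n = len(tree)
    ia = np.tile(np.asarray(i_axial, dtype=float)[None, :, None], (n_frames, 1, 1))
    im = (np.tile(np.asarray(i_m, dtype=float)[None, :, None], (n_frames, 1, 1))
          if i_m is not None else np.zeros_like(ia))
    tpl = SimpleNamespace(tree=tree)
    return SimpleNamespace(t=np.arange(n_frames) * 0.025, v=ia * 0.0,
                           i_axial=ia, i_m=im, template=tpl)


class TestBiotSavart:
    def test_infinite_wire_limit(self):
        b = segment_bfield(1.0, [-50000, 0, 0], [50000, 0, 0], [[0.0, 10.0, 0.0]])
        assert np.isclose(np.linalg.norm(b), 20.0, rtol=1e-6)   # μ0 I/(2πd)
        assert np.isclose(b[0, 2], 20.0, rtol=1e-6)             # right-hand rule

    def test_zero_current(self):
        b = segment_bfield(0.0, [0, 0, 0], [100, 0, 0], [[0, 20, 0]])
        assert np.all(b == 0.0)

    def test_antiparallel_symmetry_cancellation(self):
        # equal and opposite x-currents at ±y: on the y = 0 symmetry plane the
        # y components cancel exactly (the loop-like z components double)
        p = [[50.0, 0.0, 40.0]]
        b1 = segment_bfield(1.0, [0, 10, 0], [100, 10, 0], p)
        b2 = segment_bfield(-1.0, [0, -10, 0], [100, -10, 0], p)
        total = b1 + b2
        assert abs(total[0, 1]) < 1e-12 and abs(total[0, 0]) < 1e-12
        assert np.isclose(total[0, 2], 2.0 * b1[0, 2], rtol=1e-12)

    def test_finite_segment_less_than_infinite_wire(self):
        b_fin = segment_bfield(1.0, [-50, 0, 0], [50, 0, 0], [[0, 10, 0]])
        assert 0 < np.linalg.norm(b_fin) < 20.0


class TestFieldMap:
    def grid(self):
        return SensorGrid(extent=(400.0, 200.0), shape=(8, 5), standoff=25.0)

    def test_matches_brute_force_summation(self):
        tree = toy_cell()
        geom = SourceGeometry([tree])
        currents = np.array([0.0, 2.0, -1.0])   # i_axial[0] is unused (root)
        tr = toy_trace(tree, currents)
        fm = compute_field_map([(tr, geom)], frame=0, grid=self.grid(),
                               include_lfp=False)
        pts = self.grid().points()
        mids = tree.midpoints
        brute = np.zeros((len(pts), 3))
        for k in (1, 2):
            a, b = mids[tree.parent[k]], mids[k]
            d = b - a
            L = np.linalg.norm(d)
            u = d / L
            for i, p in enumerate(pts):
                w = p - a
                t0 = w @ u
                rho_v = w - t0 * u
                rho = np.linalg.norm(rho_v)
                f = (L - t0) / np.hypot(L - t0, rho) + t0 / np.hypot(t0, rho)
                amp = MU0_4PI * currents[k] * 1e-9 / (rho * 1e-6) * f * 1e12
                brute[i] += amp * np.cross(u, rho_v / rho)
        assert np.allclose(fm.b, brute, rtol=1e-12, atol=1e-12)

    def test_superposition_exact(self):
        t1, t2 = toy_cell((0, 0, 100)), toy_cell((30, 40, 200))
        g1, g2 = SourceGeometry([t1]), SourceGeometry([t2])
        tr1 = toy_trace(t1, [0.0, 1.5, 0.5])
        tr2 = toy_trace(t2, [0.0, -0.7, 2.0])
        fa = compute_field_map([(tr1, g1)], 0, self.grid(), include_lfp=False)
        fb = compute_field_map([(tr2, g2)], 0, self.grid(), include_lfp=False)
        fab = compute_field_map([(tr1, g1), (tr2, g2)], 0, self.grid(),
                                include_lfp=False)
        assert np.allclose(fab.b, fa.b + fb.b, rtol=1e-12, atol=1e-14)

    def test_duplicated_cell_scales_linearly(self):
        tree = toy_cell()
        geom3 = SourceGeometry([tree, tree, tree])
        tr1 = toy_trace(tree, [0.0, 1.0, 1.0])
        n = len(tree)
        tr3 = SimpleNamespace(t=tr1.t, v=np.zeros((1, n, 3)),
                              i_axial=np.tile(tr1.i_axial, (1, 1, 3)),
                              i_m=np.zeros((1, n, 3)),
                              template=SimpleNamespace(tree=tree))
        f1 = compute_field_map([(tr1, SourceGeometry([tree]))], 0, self.grid(),
                               include_lfp=False)
        f3 = compute_field_map([(tr3, geom3)], 0, self.grid(), include_lfp=False)
        assert np.allclose(f3.b, 3.0 * f1.b, rtol=1e-12)

    def test_peak_field_decreases_with_standoff(self):
        tree = toy_cell()
        geom = SourceGeometry([tree])
        tr = toy_trace(tree, [0.0, 3.0, 3.0])
        peaks = []
        for standoff in (25.0, 50.0, 100.0):
            g = SensorGrid(extent=(400.0, 200.0), shape=(8, 5), standoff=standoff)
            fm = compute_field_map([(tr, geom)], 0, g, include_lfp=False)
            peaks.append(np.abs(fm.b).max())
        assert peaks[0] > peaks[1] > peaks[2]


class TestLFP:
    def test_sigma_to_infinity_suppresses_potential(self):
        tree = toy_cell()
        geom = SourceGeometry([tree])
        tr = toy_trace(tree, [0.0, 0.0, 0.0], i_m=[1.0, -0.5, -0.5])
        f1 = compute_lfp([(tr, geom)], 0, self.gridsmall(), VolumeConductor(sigma=0.5))
        f2 = compute_lfp([(tr, geom)], 0, self.gridsmall(), VolumeConductor(sigma=5e6))
        assert np.abs(f2.phi).max() < 1e-6 * np.abs(f1.phi).max()

    def gridsmall(self):
        return SensorGrid(extent=(200.0, 100.0), shape=(4, 3), standoff=25.0)

    def test_balanced_cell_has_dipolar_far_field(self):
        """Σ I_m = 0 per cell ⇒ φ decays at least as 1/r²."""
        tree = toy_cell((0.0, 0.0, 0.0))
        geom = SourceGeometry([tree])
        tr = toy_trace(tree, [0.0, 0.0, 0.0], i_m=[1.0, 0.0, -1.0])
        conductor = VolumeConductor()
        rr = np.array([1e3, 2e3, 4e3, 8e3, 16e3])
        phis = []
        for r in rr:
            g = SensorGrid(extent=(2.0, 2.0), shape=(1, 1), center=(75.0, 0.0),
                           standoff=r)
            phis.append(np.abs(compute_lfp([(tr, geom)], 0, g, conductor).phi[0]))
        slope = np.polyfit(np.log(rr), np.log(phis), 1)[0]
        assert slope <= -1.95


class TestECD:
    def test_quiescent_trace_zero_dipole(self):
        tree = toy_cell()
        geom = SourceGeometry([tree])
        tr = toy_trace(tree, [0.0, 0.0, 0.0], n_frames=4)
        q = compute_ecd([(tr, geom)])
        assert np.all(q.q == 0.0) and q.magnitude.max() == 0.0

    def test_dipole_is_current_times_length(self):
        tree = toy_cell()
        geom = SourceGeometry([tree])
        tr = toy_trace(tree, [0.0, 1.0, 0.0])
        q = compute_ecd([(tr, geom)])
        # one active segment between midpoints of comps 0 and 1 (50 μm along x)
        assert np.allclose(q.q[0], [0.05, 0.0, 0.0], atol=1e-12)

    def test_peak_latency(self):
        q = ECDTrace(t=np.array([0.0, 0.1, 0.2, 0.3]),
                     q=np.array([[0, 0, 0], [1, 0, 0], [3, 0, 0], [2, 0, 0.0]]))
        assert q.peak_frame() == 2
        assert np.isclose(q.peak_latency(onset=0.1), 0.1)


class TestSensorGrid:
    def test_printed_grid_geometry(self):
        g = SensorGrid()
        assert g.shape == (50, 25)
        assert g.pitch == (40.0, 40.0)
        pts = g.points()
        assert len(pts) == 1250
        assert np.allclose(pts[:, 2], -25.0)            # coplanar at the standoff
        assert np.isclose(pts[:, 0].max() - pts[:, 0].min(), 2000.0 - 40.0)
        assert np.isclose(pts[:, 1].max() - pts[:, 1].min(), 1000.0 - 40.0)
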