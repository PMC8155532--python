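"""Forward computation of extracellular magnetic fields, local field
potentials and the equivalent current dipole from compartment currents.

Following the two-step forward scheme for an unbounded homogeneous volume
conductor: axial currents are the sources of the magnetic field (exact
finite-segment Biot-Savart per current path between compartment midpoints),
transmembrane currents are the sources of the electric potential (point-source
summation φ = Σ I_m / (4πσr)).  A dimensionless scaling factor stands in for
the slab/anisotropy/bath boundary corrections (default 1).

The equivalent current dipole is Q(t) = Σ_k I_k(t) · L⃗_k over all axial
current segments, reported in nA·mm.

Units: geometry in μm, currents in nA, B in pT, φ in μV.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

MU0_OVER_4PI = 1e-7          # T·m/A


@dataclass
class SensorGrid:
    """Planar sensor grid below the slice (z = -standoff)."""
    extent: tuple = (2000.0, 1000.0)    # μm (x, y)
    shape: tuple = (50, 25)
    center: tuple = (0.0, 0.0)
    standoff: float = 25.0              # μm below the slice bottom (z = 0)

    @property
    def pitch(self) -> tuple:
        return (self.extent[0] / self.shape[0], self.extent[1] / self.shape[1])

    def points(self) -> np.ndarray:
        nx, ny = self.shape
        px, py = self.pitch
        x = self.center[0] + (np.arange(nx) - (nx - 1) / 2) * px
        y = self.center[1] + (np.arange(ny) - (ny - 1) / 2) * py
        xx, yy = np.meshgrid(x, y, indexing="ij")
        zz = np.full_like(xx, -self.standoff)
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


@dataclass
class VolumeConductor:
    sigma: float = 0.5          # extracellular conductivity, S/m (ACSF-perfused slice)
    scale: float = 1.0          # slab/anisotropy/bath correction factor

    def validate(self):
        if self.sigma <= 0 or self.scale <= 0:
            raise ValueError("sigma and scale must be positive")


@dataclass
class FieldMap:
    grid: SensorGrid
    b: np.ndarray               # (n_points, 3) pT
    phi: np.ndarray = None      # (n_points,) μV
    frame_time: float = None    # ms

    def component(self, axis: int) -> np.ndarray:
        return self.b[:, axis].reshape(self.grid.shape)

    def peak_component_magnitudes(self) -> np.ndarray:
        """max over the grid of |Bx|, |By|, |Bz| (pT)."""
        return np.abs(self.b).max(axis=0)


@dataclass
class ECDTrace:
    t: np.ndarray
    q: np.ndarray               # (n_frames, 3) nA·mm

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.q, axis=1)

    def peak_frame(self) -> int:
        return int(np.argmax(self.magnitude))

    def peak_latency(self, onset: float = 0.0) -> float:
        return float(self.t[self.peak_frame()] - onset)


# ---------------------------------------------------------------------------
# geometry bundles
# ---------------------------------------------------------------------------

class SourceGeometry:
    """Per-cell source geometry for a population sharing one template.

    Axial currents flow between compartment midpoints: segment k of cell c
    runs from ``mid[parent[k], c]`` to ``mid[k, c]`` and carries
    ``trace.i_axial[t, k, c]``.  Transmembrane point sources sit at the
    compartment midpoints."""

    def __init__(self, trees: list):
        mids = np.stack([t.midpoints for t in trees], axis=2)   # (N, 3, NC)
        parent = trees[0].parent
        self.mid = mids
        self.parent = parent
        child = np.arange(1, len(parent))
        self.seg_a = mids[parent[child]]                        # (N-1, 3, NC)
        self.seg_b = mids[child]
        self.seg_vec = self.seg_b - self.seg_a
        self.child = child

    def flat_segments(self):
        """Segments flattened over cells: endpoints (S, 3)."""
        a = np.moveaxis(self.seg_a, 2, 1).reshape(-1, 3, order="F")
        return a

    def segment_currents(self, i_axial_frame: np.ndarray) -> np.ndarray:
        """(N-1, NC) currents for one frame of trace.i_axial ((N, NC))."""
        return i_axial_frame[self.child]


# ---------------------------------------------------------------------------
# Biot-Savart
# ---------------------------------------------------------------------------

def segment_bfield(current: float, a, b, points, min_rho: float = 0.1) -> np.ndarray:
    """Magnetic field (pT) of one finite straight segment from a to b (μm)
    carrying ``current`` (nA, positive a→b), at ``points`` (n, 3).

    Exact closed form; field points closer than ``min_rho`` μm to the segment
    axis are clamped to ``min_rho``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return _bfield_accumulate(
        np.asarray([a], dtype=float), np.asarray([b], dtype=float),
        np.asarray([current], dtype=float), pts, min_rho)


def _bfield_accumulate(seg_a: np.ndarray, seg_b: np.ndarray, currents: np.ndarray,
                       points: np.ndarray, min_rho: float = 0.1,
                       chunk: int = 2_000_000) -> np.ndarray:
    """Sum of finite-segment Biot-Savart fields.

    seg_a, seg_b: (S, 3) μm; currents: (S,) nA; points: (P, 3) μm → (P, 3) pT.
    Work is chunked over segment×point pairs."""
    S, P = len(seg_a), len(points)
    out = np.zeros((P, 3))
    if S == 0:
        return out
    d = seg_b - seg_a
    L = np.linalg.norm(d, axis=1)
    keep = (L > 1e-9) & (currents != 0.0)
    seg_a, d, L, currents = seg_a[keep], d[keep], L[keep], currents[keep]
    S = len(seg_a)
    if S == 0:
        return out
    u = d / L[:, None]
    seg_per_chunk = max(int(chunk // max(P, 1)), 1)
    for s0 in range(0, S, seg_per_chunk):
        s1 = min(s0 + seg_per_chunk, S)
        a = seg_a[s0:s1][None, :, :]            # (1, s, 3)
        uu = u[s0:s1][None, :, :]
        ll = L[s0:s1][None, :]
        w = points[:, None, :] - a              # (P, s, 3)
        t0 = np.einsum("psk,psk->ps", w, np.broadcast_to(uu, w.shape))
        rho_vec = w - t0[:, :, None] * uu
        rho = np.linalg.norm(rho_vec, axis=2)
        rho = np.maximum(rho, min_rho)
        # azimuthal direction u × rho_hat
        phi_hat = np.cross(np.broadcast_to(uu, w.shape), rho_vec / rho[:, :, None])
        f = (ll - t0) / np.sqrt((ll - t0) ** 2 + rho ** 2) + t0 / np.sqrt(t0 ** 2 + rho ** 2)
        # μ0/4π · I/ρ · f ; I in nA (1e-9 A), ρ in μm (1e-6 m) → T; ×1e12 → pT
        amp = MU0_OVER_4PI * currents[s0:s1][None, :] * 1e-9 / (rho * 1e-6) * f * 1e12
        out += np.einsum("ps,psk->pk", amp, phi_hat)
    return out


# ---------------------------------------------------------------------------
# field maps, LFP, ECD
# ---------------------------------------------------------------------------

def compute_ecd(traces_geoms: list) -> ECDTrace:
    """Equivalent current dipole Q(t) = Σ I_k·L⃗_k (nA·mm) summed over the
    populations in ``traces_geoms`` (list of (StateTrace, SourceGeometry))."""
    t_axis = traces_geoms[0][0].t
    q = np.zeros((len(t_axis), 3))
    for trace, geom in traces_geoms:
        ia = np.asarray(trace.i_axial[:, geom.child, :], dtype=float)  # (T, N-1, NC)
        q += np.einsum("tsc,skc->tk", ia, geom.seg_vec) * 1e-3         # μm→mm
    return ECDTrace(t=t_axis, q=q)


def compute_field_map(traces_geoms: list, frame: int, grid: SensorGrid = None,
                      conductor: VolumeConductor = None,
                      include_lfp: bool = True) -> FieldMap:
    """B (and optionally φ) on the sensor grid for one output frame.

    B superposes exact finite-segment Biot-Savart contributions of all axial
    currents; φ superposes transmembrane point sources.  Both are multiplied
    by the volume-conductor scaling factor."""
    grid = grid or SensorGrid()
    conductor = conductor or VolumeConductor()
    conductor.validate()
    pts = grid.points()

    b = np.zeros((len(pts), 3))
    phi = np.zeros(len(pts)) if include_lfp else None
    for trace, geom in traces_geoms:
        nc = trace.v.shape[2]
        a = np.moveaxis(geom.seg_a, 2, 0).reshape(-1, 3)        # (NC*(N-1), 3)
        bseg = np.moveaxis(geom.seg_b, 2, 0).reshape(-1, 3)
        cur = np.asarray(trace.i_axial[frame, geom.child, :], dtype=float).T.reshape(-1)
        b += _bfield_accumulate(a, bseg, cur, pts)
        if include_lfp:
            phi += _lfp_accumulate(trace, geom, frame, pts, conductor)
    b *= conductor.scale
    if include_lfp:
        phi *= conductor.scale
    return FieldMap(grid=grid, b=b, phi=phi,
                    frame_time=float(traces_geoms[0][0].t[frame]))


def _lfp_accumulate(trace, geom, frame, pts, conductor, chunk: int = 4_000_000):
    im = np.asarray(trace.i_m[frame], dtype=float)              # (N, NC)
    src = np.moveaxis(geom.mid, 2, 0).reshape(-1, 3)            # (NC*N, 3)
    cur = im.T.reshape(-1)
    radius = np.repeat(trace.template.tree.diameter / 2.0, im.shape[1]
                       ).reshape(im.shape).T.reshape(-1)
    out = np.zeros(len(pts))
    per = max(int(chunk // max(len(pts), 1)), 1)
    for s0 in range(0, len(src), per):
        s1 = min(s0 + per, len(src))
        r = np.linalg.norm(pts[:, None, :] - src[None, s0:s1, :], axis=2)
        r = np.maximum(r, radius[None, s0:s1])
        # φ = I/(4πσ r): I nA = 1e-9 A, r μm = 1e-6 m → V; ×1e6 → μV
        out += np.sum(cur[None, s0:s1] / r, axis=1)
    return out * 1e-9 / (4.0 * np.pi * conductor.sigma * 1e-6) * 1e6


def compute_lfp(traces_geoms: list, frame: int, grid: SensorGrid = None,
                conductor: VolumeConductor = None) -> FieldMap:
    """Electric potential φ on the sensor grid for one frame (B not computed)."""
    grid = grid or SensorGrid()
    conductor = conductor or VolumeConductor()
    conductor.validate()
    pts = grid.points()
    phi = np.zeros(len(pts))
    for trace, geom in traces_geoms:
        phi += _lfp_accumulate(trace, geom, frame, pts, conductor)
    return FieldMap(grid=grid, b=np.zeros((len(pts), 3)), phi=phi * conductor.scale,
                    frame_time=float(traces_geoms[0][0].t[frame]))
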