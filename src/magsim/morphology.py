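"""Compartmental morphologies of the GBC-MNTB auditory pathway.

Single cells are represented as trees of straight cylindrical compartments
(`CompartmentTree`).  Two builders are provided:

* :func:`build_gbc` — a globular bushy cell (VCN): spherical soma, one primary
  and two secondary dendrites, axon hillock, initial segment, a tapered
  myelinated axon ending in a heminode / post-heminode, and a calyx of Held
  modelled as a half ring.
* :func:`build_mntb` — an MNTB principal cell: spherical soma, a short branched
  dendrite, and an axon of five internodes/nodes heading toward the LSO.

Axons are laid out along smooth 3-D polylines (natural cubic splines through
randomly drawn waypoints, see :func:`sample_axon_path`), so the electrical
1-D structure of every cell of a given type is identical while its embedding
in the slice differs.

Units: micrometres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

SECTION_LABELS = (
    "soma",
    "primary_dendrite",
    "secondary_dendrite",
    "hillock",
    "initial_segment",
    "internode",
    "node",
    "heminode",
    "post_heminode",
    "calyx",
    "mntb_soma",
    "mntb_dendrite",
    "mntb_internode",
    "mntb_node",
)


@dataclass
class CompartmentTree:
    """A cell as connected cylindrical compartments.

    ``parent[i]`` is the index of the parent compartment (-1 for the root).
    ``prox``/``dist`` are the proximal/distal end points (N, 3), ``diameter``
    the cylinder diameter, ``label`` the section label of each compartment and
    ``section_id`` groups compartments belonging to the same anatomical
    section (e.g. one internode split into several cylinders).
    """

    parent: np.ndarray
    prox: np.ndarray
    dist: np.ndarray
    diameter: np.ndarray
    label: np.ndarray
    section_id: np.ndarray
    n_segments: np.ndarray = None  # per-compartment; builders emit 1 each

    def __post_init__(self):
        if self.n_segments is None:
            self.n_segments = np.ones(len(self.parent), dtype=int)
        self.validate()

    def __len__(self) -> int:
        return len(self.parent)

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.dist - self.prox, axis=1)

    @property
    def areas(self) -> np.ndarray:
        """Lateral membrane area (μm²)."""
        return np.pi * self.diameter * self.lengths

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.prox + self.dist)

    def indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.label == label)

    def validate(self) -> None:
        n = len(self.parent)
        if n == 0:
            raise ValueError("empty tree")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        if np.any(self.parent >= np.arange(n)):
            raise ValueError("parents must precede children (topological order)")
        if np.any(self.diameter <= 0):
            raise ValueError("all diameters must be positive")
        if np.any(self.lengths <= 0):
            raise ValueError("all compartment lengths must be positive")
        unknown = set(np.unique(self.label)) - set(SECTION_LABELS)
        if unknown:
            raise ValueError(f"unknown section labels: {unknown}")

    def translated(self, offset) -> "CompartmentTree":
        offset = np.asarray(offset, dtype=float)
        return replace(self, prox=self.prox + offset, dist=self.dist + offset)


@dataclass
class GBCMorphParams:
    """Printed defaults for the globular bushy cell morphology."""

    soma_diameter: float = 20.0
    primary_dendrite: tuple = (50.0, 3.0)          # (length, diameter)
    secondary_dendrite: tuple = (50.0, 2.0)        # two of these
    hillock_length: float = 15.0
    hillock_diameter: tuple = (2.5, 1.0)           # tapers proximal→distal
    initial_segment: tuple = (20.0, 1.0)
    n_constant_internodes: int = 9
    constant_internode_length: float = 200.0
    # systematic shortening over the final ~800 μm of the axon
    taper_internode_lengths: tuple = (180.0, 150.0, 120.0, 95.0, 75.0, 60.0, 50.0, 40.0)
    internode_diameter: tuple = (3.0, 3.3)         # first → last
    node_diameter: tuple = (1.5, 2.0)              # first → last
    node_length: float = 1.0
    heminode: tuple = (8.0, 2.0)
    post_heminode: tuple = (5.0, 2.5)
    calyx_diameter: float = 13.0
    calyx_thickness: float = 2.0
    calyx_n_arcs: int = 8
    seg_length: float = 50.0                       # max cylinder length for long sections

    def internode_lengths(self) -> np.ndarray:
        return np.array(
            [self.constant_internode_length] * self.n_constant_internodes
            + list(self.taper_internode_lengths)
        )

    def validate(self):
        vals = [self.soma_diameter, *self.primary_dendrite, *self.secondary_dendrite,
                self.hillock_length, *self.hillock_diameter, *self.initial_segment,
                self.constant_internode_length, *self.taper_internode_lengths,
                *self.internode_diameter, *self.node_diameter, self.node_length,
                *self.heminode, *self.post_heminode, self.calyx_diameter,
                self.calyx_thickness, self.seg_length]
        if any(v <= 0 for v in vals):
            raise ValueError("all morphological dimensions must be positive")
        if self.calyx_n_arcs < 2:
            raise ValueError("calyx half ring needs at least 2 arc segments")


@dataclass
class MNTBMorphParams:
    """Printed defaults for the MNTB principal cell morphology."""

    soma_diameter: float = 20.0
    dendrite: tuple = (50.0, 3.0)
    dendrite_branch: tuple = (10.0, 2.0)           # two terminal branches
    n_dendrite_branches: int = 2
    n_internodes: int = 5
    internode: tuple = (100.0, 2.0)
    node: tuple = (1.0, 1.0)
    seg_length: float = 50.0

    def validate(self):
        vals = [self.soma_diameter, *self.dendrite, *self.dendrite_branch,
                *self.internode, *self.node, self.seg_length]
        if any(v <= 0 for v in vals):
            raise ValueError("all morphological dimensions must be positive")
        if self.n_dendrite_branches != 2:
            raise ValueError("principal-cell dendrite carries exactly two 10 μm branches")


# ---------------------------------------------------------------------------
# path utilities
# ---------------------------------------------------------------------------

def spline_polyline(waypoints: np.ndarray, max_seg: float = 10.0) -> np.ndarray:
    """Natural cubic spline through ``waypoints`` (M, 2|3), densified so that
    no segment is longer than ``max_seg`` μm.  The last point of the result is
    exactly the last waypoint."""
    pts = np.atleast_2d(np.asarray(waypoints, dtype=float))
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(chord < 1e-9):
        raise ValueError("degenerate (coincident) control points")
    t = np.concatenate([[0.0], np.cumsum(chord)])
    cs = CubicSpline(t, pts, bc_type="natural", axis=0)
    # oversample, then enforce max segment length
    n_dense = max(int(np.ceil(t[-1] / (0.25 * max_seg))), len(pts) * 8)
    dense = cs(np.linspace(0.0, t[-1], n_dense + 1))
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_out = max(int(np.ceil(s[-1] / max_seg)), 1)
    s_out = np.linspace(0.0, s[-1], n_out + 1)
    out = np.column_stack([np.interp(s_out, s, dense[:, k]) for k in range(3)])
    out[-1] = pts[-1]
    return out


class ArcPath:
    """Arc-length parameterisation of a polyline, with linear extrapolation
    beyond both ends (used when a cell's structural length exceeds the spline
    arc length)."""

    def __init__(self, polyline: np.ndarray):
        self.points = np.asarray(polyline, dtype=float)
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg < 1e-12):
            keep = np.concatenate([[True], seg >= 1e-12])
            self.points = self.points[keep]
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        self.s = np.concatenate([[0.0], np.cumsum(seg)])
        self.length = self.s[-1]
        self._t0 = (self.points[1] - self.points[0]) / np.linalg.norm(self.points[1] - self.points[0])
        self._t1 = (self.points[-1] - self.points[-2]) / np.linalg.norm(self.points[-1] - self.points[-2])

    def at(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.column_stack([np.interp(s, self.s, self.points[:, k]) for k in range(3)])
        below = s < 0
        above = s > self.length
        if np.any(below):
            out[below] = self.points[0] + np.outer(s[below], self._t0)
        if np.any(above):
            out[above] = self.points[-1] + np.outer(s[above] - self.length, self._t1)
        return out

    def tangent(self, s: float) -> np.ndarray:
        eps = 1.0
        p0, p1 = self.at([s - eps, s + eps])
        d = p1 - p0
        return d / np.linalg.norm(d)


DEFAULT_WAYPOINT_BOXES = np.array(
    # centers (x, y) of the seven predefined 25x25 μm² boxes tracing the
    # VCN→midline→MNTB arc of the axonal pathway; the trapezoid-body fibers
    # run nearly mediolaterally (flat in y) once past the ventral dip
    [
        (-1100.0, 250.0),
        (-950.0, 120.0),
        (-800.0, 40.0),
        (-650.0, -10.0),
        (-500.0, -35.0),
        (-350.0, -35.0),
        (-180.0, -20.0),
    ]
)
WAYPOINT_BOX_SIZE = 25.0


def sample_waypoints(rng: np.random.Generator,
                     waypoint_boxes: np.ndarray = None,
                     box_size: float = WAYPOINT_BOX_SIZE) -> np.ndarray:
    """One point drawn uniformly from each predefined waypoint box."""
    boxes = DEFAULT_WAYPOINT_BOXES if waypoint_boxes is None else np.asarray(waypoint_boxes, float)
    return boxes + rng.uniform(-box_size / 2, box_size / 2, size=boxes.shape)


def sample_axon_path(rng: np.random.Generator,
                     waypoint_boxes: np.ndarray = None,
                     calyx_center_x: float = 400.0,
                     box_size: float = WAYPOINT_BOX_SIZE,
                     max_seg: float = 10.0) -> np.ndarray:
    """Sample one random GBC axon path.

    One point is drawn uniformly from each 25×25 μm² waypoint box; the eighth
    point is the calyx waypoint ``(x_c, 0, 0)``.  Returns the densified spline
    polyline (z = 0 plane); the last point equals the calyx waypoint exactly.
    """
    pts = np.vstack([sample_waypoints(rng, waypoint_boxes, box_size),
                     [calyx_center_x, 0.0]])
    return spline_polyline(pts, max_seg=max_seg)


# ---------------------------------------------------------------------------
# tree assembly helpers
# ---------------------------------------------------------------------------

class _TreeBuilder:
    def __init__(self):
        self.parent, self.prox, self.dist = [], [], []
        self.diameter, self.label, self.section_id = [], [], []
        self._next_section = 0

    def add_chain(self, points: np.ndarray, diameters, label: str, parent: int,
                  new_section_per_point: bool = False) -> list[int]:
        """Add cylinders between consecutive ``points`` ((k+1, 3) for k
        cylinders).  ``diameters`` is scalar or per-cylinder.  Returns the new
        compartment indices."""
        points = np.asarray(points, dtype=float)
        k = len(points) - 1
        diams = np.broadcast_to(np.asarray(diameters, dtype=float), (k,))
        idx = []
        sec = self._next_section
        for j in range(k):
            if new_section_per_point or j == 0:
                sec = self._next_section
                self._next_section += 1
            i = len(self.parent)
            self.parent.append(parent)
            self.prox.append(points[j])
            self.dist.append(points[j + 1])
            self.diameter.append(diams[j])
            self.label.append(label)
            self.section_id.append(sec)
            idx.append(i)
            parent = i
        return idx

    def build(self) -> CompartmentTree:
        return CompartmentTree(
            parent=np.asarray(self.parent, dtype=int),
            prox=np.asarray(self.prox, dtype=float),
            dist=np.asarray(self.dist, dtype=float),
            diameter=np.asarray(self.diameter, dtype=float),
            label=np.asarray(self.label, dtype="<U20"),
            section_id=np.asarray(self.section_id, dtype=int),
        )


def _split(length: float, max_seg: float) -> np.ndarray:
    n = max(int(np.ceil(length / max_seg)), 1)
    return np.linspace(0.0, length, n + 1)


def _plane_normal_dir(tangent: np.ndarray) -> np.ndarray:
    """In-plane (z = const) unit vector perpendicular to the path tangent."""
    d = np.array([-tangent[1], tangent[0], 0.0])
    n = np.linalg.norm(d)
    if n < 1e-12:
        d = np.array([0.0, 1.0, 0.0])
        n = 1.0
    return d / n


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_gbc(params: GBCMorphParams = None,
              path: ArcPath = None,
              calyx_rotation: float = 0.0,
              dendrite_rotation: float = 0.0) -> CompartmentTree:
    """Build a globular bushy cell along ``path`` (soma → calyx).

    Without a path, the cell is laid out along the +x axis starting at the
    origin (convenient for single-cell studies).  The structural chain is
    soma → hillock → initial segment → alternating internodes and nodes of
    Ranvier (tapered) → heminode → post-heminode → calyx half ring.  The
    distal end of the chain coincides with the path end point (the calyx
    waypoint); the half ring is centred there and rotated about z by
    ``calyx_rotation``.
    """
    p = params or GBCMorphParams()
    p.validate()

    in_lens = p.internode_lengths()
    n_in = len(in_lens)
    # structural boundaries measured from the soma's proximal end
    soma_len = p.soma_diameter
    chain_lens = [soma_len, p.hillock_length, p.initial_segment[0]]
    for j in range(n_in):
        chain_lens.append(in_lens[j])
        chain_lens.append(p.node_length if j < n_in - 1 else p.heminode[0])
    chain_lens.append(p.post_heminode[0])
    L_struct = float(np.sum(chain_lens))

    if path is None:
        path = ArcPath(np.array([[0.0, 0.0, 0.0], [L_struct, 0.0, 0.0]]))
    # align the distal end of the chain with the path end
    s0 = path.length - L_struct

    b = _TreeBuilder()
    s = s0
    # soma (sphere → cylinder with length = diameter, equal-area convention)
    soma_idx = b.add_chain(path.at([s, s + soma_len]), p.soma_diameter, "soma", -1)
    soma_center = path.at(s + 0.5 * soma_len)[0]
    s += soma_len

    # dendrites: primary leaves the soma at a per-cell random in-plane angle
    # (``dendrite_rotation`` about z, relative to the path normal), secondaries
    # branch at ±45° from its distal end
    tang = path.tangent(s0 + 0.5 * soma_len)
    perp = _plane_normal_dir(tang)
    cr, sr = np.cos(dendrite_rotation), np.sin(dendrite_rotation)
    perp = np.array([cr * perp[0] - sr * perp[1], sr * perp[0] + cr * perp[1], 0.0])
    dlen, ddiam = p.primary_dendrite
    prim_pts = soma_center + np.outer(_split(dlen, 25.0) / dlen * dlen, perp)
    prim_idx = b.add_chain(prim_pts, ddiam, "primary_dendrite", soma_idx[0])
    tip = prim_pts[-1]
    slen, sdiam = p.secondary_dendrite
    for sign in (+1.0, -1.0):
        d = perp + sign * np.array([tang[0], tang[1], 0.0])
        d /= np.linalg.norm(d)
        pts = tip + np.outer(_split(slen, 25.0), d)
        b.add_chain(pts, sdiam, "secondary_dendrite", prim_idx[-1])

    # hillock (tapering) and initial segment, along the path
    hl = p.hillock_length
    edges = _split(hl, 5.0)
    mids = 0.5 * (edges[:-1] + edges[1:])
    d0, d1 = p.hillock_diameter
    hdiams = d0 + (d1 - d0) * mids / hl
    h_idx = b.add_chain(path.at(s + edges), hdiams, "hillock", soma_idx[-1])
    s += hl
    il, idiam = p.initial_segment
    is_idx = b.add_chain(path.at(s + _split(il, 10.0)), idiam, "initial_segment", h_idx[-1])
    s += il

    parent = is_idx[-1]
    frac = np.linspace(0.0, 1.0, n_in) if n_in > 1 else np.array([0.0])
    for j in range(n_in):
        din = p.internode_diameter[0] + (p.internode_diameter[1] - p.internode_diameter[0]) * frac[j]
        idx = b.add_chain(path.at(s + _split(in_lens[j], p.seg_length)), din,
                          "internode", parent)
        s += in_lens[j]
        if j < n_in - 1:
            dn = p.node_diameter[0] + (p.node_diameter[1] - p.node_diameter[0]) * frac[j]
            idx = b.add_chain(path.at(s + np.array([0.0, p.node_length])), dn,
                              "node", idx[-1])
            s += p.node_length
        else:
            idx = b.add_chain(path.at(s + np.array([0.0, p.heminode[0]])), p.heminode[1],
                              "heminode", idx[-1])
            s += p.heminode[0]
        parent = idx[-1]

    ph_idx = b.add_chain(path.at(s + np.array([0.0, p.post_heminode[0]])), p.post_heminode[1],
                         "post_heminode", parent)
    s += p.post_heminode[0]
    calyx_center = path.at(s)[0]

    # calyx of Held: half ring in the slice plane, rotated about z
    r = p.calyx_diameter / 2.0
    theta = calyx_rotation + np.linspace(0.0, np.pi, p.calyx_n_arcs + 1)
    ring = calyx_center + np.column_stack(
        [r * np.cos(theta) - r * np.cos(theta[0]),
         r * np.sin(theta) - r * np.sin(theta[0]),
         np.zeros_like(theta)]
    )
    b.add_chain(ring, p.calyx_thickness, "calyx", ph_idx[-1])

    return b.build()


def build_mntb(params: MNTBMorphParams = None,
               origin=(0.0, 0.0, 0.0),
               rotation: float = 0.0,
               rng: np.random.Generator = None) -> CompartmentTree:
    """Build an MNTB principal cell with its soma centred at ``origin``.

    The dendrite leaves the soma along the rotated +y direction; the axon is
    oriented 90° to the dendrite and follows a spline through five randomly
    drawn waypoints heading toward the LSO (rotated +x).  ``rotation`` is the
    cell's random rotation about the z axis.
    """
    p = params or MNTBMorphParams()
    p.validate()
    origin = np.asarray(origin, dtype=float)
    rng = rng or np.random.default_rng(0)

    c, sn = np.cos(rotation), np.sin(rotation)
    rot = np.array([[c, -sn, 0.0], [sn, c, 0.0], [0.0, 0.0, 1.0]])
    ey = rot @ np.array([0.0, 1.0, 0.0])   # dendrite direction
    ex = rot @ np.array([1.0, 0.0, 0.0])   # axon direction (toward LSO)

    b = _TreeBuilder()
    soma_len = p.soma_diameter
    soma_pts = origin - 0.5 * soma_len * ey + np.outer(np.array([0.0, soma_len]), ey)
    soma_idx = b.add_chain(soma_pts, p.soma_diameter, "mntb_soma", -1)

    dlen, ddiam = p.dendrite
    dpts = origin + np.outer(_split(dlen, 25.0), ey)
    d_idx = b.add_chain(dpts, ddiam, "mntb_dendrite", soma_idx[-1])
    blen, bdiam = p.dendrite_branch
    for sign in (+1.0, -1.0):
        d = ey + sign * ex
        d /= np.linalg.norm(d)
        b.add_chain(dpts[-1] + np.outer(np.array([0.0, blen]), d), bdiam,
                    "mntb_dendrite", d_idx[-1])

    # axon path: spline through 5 random waypoints on the way to the LSO
    il, idiam = p.internode
    nl, ndiam = p.node
    L_axon = p.n_internodes * (il + nl)
    step = L_axon / 5.0
    wps = [origin]
    for k in range(1, 6):
        jit = rng.uniform(-0.3 * step, 0.3 * step) * ey + rng.uniform(-0.15 * step, 0.15 * step) * ex
        wps.append(origin + k * step * ex + (jit if k < 5 else 0.0))
    path = ArcPath(spline_polyline(np.asarray(wps)))

    s = 0.0
    parent = soma_idx[0]
    for j in range(p.n_internodes):
        idx = b.add_chain(path.at(s + _split(il, p.seg_length)), idiam,
                          "mntb_internode", parent)
        s += il
        idx = b.add_chain(path.at(s + np.array([0.0, nl])), ndiam, "mntb_node", idx[-1])
        s += nl
        parent = idx[-1]

    return b.build()
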