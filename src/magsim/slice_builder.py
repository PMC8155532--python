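"""Randomized slice-scale population of paired GBC / MNTB principal cells.

The synthetic brainstem slice is 350 μm thick with 25 μm inactive layers at
the top and bottom faces (cells there are damaged by the cutting procedure),
leaving a 300 μm active span.  For each of the one-to-one GBC→MNTB pairs:

1. a calyx centre (x_c, y_c, z_c) is drawn uniformly from the MNTB ellipse
   (semi-axes 200/100 μm, centred 400 μm lateral of the midline) × the active
   z span [25, 325] μm;
2. the GBC axon path is a natural cubic spline through one random point per
   predefined 25×25 μm² waypoint box plus the calyx waypoint (x_c, 0, 0);
3. the complete GBC (soma + axon + calyx) is translated by (0, y_c, z_c);
4. the principal-cell soma is placed at the calyx centre and rotated about z
   by a uniform angle in [-π/2, π/2]; the calyx half ring is rotated about z
   by a uniform angle in [0, 2π).

Everything is reproducible bit-for-bit from the seed.

Coordinates: x = medio-lateral (midline at x = 0), y = in-plane orthogonal,
z = slice depth (slice bottom at z = 0; the sensor plane lies at z = -25 μm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .morphology import (
    DEFAULT_WAYPOINT_BOXES,
    WAYPOINT_BOX_SIZE,
    ArcPath,
    CompartmentTree,
    GBCMorphParams,
    MNTBMorphParams,
    build_gbc,
    build_mntb,
    sample_axon_path,
)


@dataclass
class SliceParams:
    slice_thickness: float = 350.0
    inactive_layer: float = 25.0
    ellipse_center_x: float = 400.0     # offset of the MNTB area from the midline
    semi_major: float = 200.0           # along x
    semi_minor: float = 100.0           # along y
    waypoint_boxes: np.ndarray = field(default_factory=lambda: DEFAULT_WAYPOINT_BOXES.copy())
    box_size: float = WAYPOINT_BOX_SIZE

    @property
    def active_span(self) -> tuple:
        return (self.inactive_layer, self.slice_thickness - self.inactive_layer)


@dataclass
class SliceLayout:
    """The full population plus the geometry that generated it."""

    gbc_cells: list
    mntb_cells: list
    pairing: np.ndarray                 # gbc i → mntb pairing[i] (identity map)
    calyx_centers: np.ndarray           # (N, 3)
    params: SliceParams
    seed: int

    @property
    def n_cells(self) -> int:
        return len(self.gbc_cells)

    def in_ellipse(self, xy: np.ndarray) -> np.ndarray:
        p = self.params
        return ((xy[:, 0] - p.ellipse_center_x) / p.semi_major) ** 2 + (
            xy[:, 1] / p.semi_minor
        ) ** 2 <= 1.0


def _sample_calyx_centers(rng, params: SliceParams, n: int) -> np.ndarray:
    """Uniform in the MNTB ellipse × the active z span (rejection sampling)."""
    out = np.empty((n, 3))
    k = 0
    while k < n:
        m = 2 * (n - k) + 8
        x = rng.uniform(-params.semi_major, params.semi_major, m)
        y = rng.uniform(-params.semi_minor, params.semi_minor, m)
        keep = (x / params.semi_major) ** 2 + (y / params.semi_minor) ** 2 <= 1.0
        x, y = x[keep][: n - k], y[keep][: n - k]
        out[k : k + len(x), 0] = params.ellipse_center_x + x
        out[k : k + len(x), 1] = y
        k += len(x)
    lo, hi = params.active_span
    out[:, 2] = rng.uniform(lo, hi, n)
    return out


def build_slice(n_cells: int = 300,
                seed: int = 0,
                params: SliceParams = None,
                gbc_params: GBCMorphParams = None,
                mntb_params: MNTBMorphParams = None) -> SliceLayout:
    """Construct the randomized slice population (see module docstring)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    params = params or SliceParams()
    gbc_params = gbc_params or GBCMorphParams()
    mntb_params = mntb_params or MNTBMorphParams()

    rng = np.random.default_rng(seed)
    centers = _sample_calyx_centers(rng, params, n_cells)

    gbcs, mntbs = [], []
    for i in range(n_cells):
        xc, yc, zc = centers[i]
        poly = sample_axon_path(rng, params.waypoint_boxes, calyx_center_x=xc,
                                box_size=params.box_size)
        calyx_rot = rng.uniform(0.0, 2.0 * np.pi)
        dend_rot = rng.uniform(0.0, 2.0 * np.pi)
        gbc = build_gbc(gbc_params, path=ArcPath(poly), calyx_rotation=calyx_rot,
                        dendrite_rotation=dend_rot)
        gbcs.append(gbc.translated([0.0, yc, zc]))
        mntb_rot = rng.uniform(-np.pi / 2, np.pi / 2)
        mntbs.append(build_mntb(mntb_params, origin=(xc, yc, zc),
                                rotation=mntb_rot, rng=rng))

    return SliceLayout(
        gbc_cells=gbcs,
        mntb_cells=mntbs,
        pairing=np.arange(n_cells),
        calyx_centers=centers,
        params=params,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_SWC_TYPE = {"soma": 1, "mntb_soma": 1, "primary_dendrite": 3, "secondary_dendrite": 3,
             "mntb_dendrite": 3, "hillock": 2, "initial_segment": 2, "internode": 2,
             "node": 2, "heminode": 2, "post_heminode": 2, "calyx": 7,
             "mntb_internode": 2, "mntb_node": 2}


def tree_to_swc(tree: CompartmentTree, path: str, sidecar: str = None) -> None:
    """Write an SWC-style compartment table (id, type, x, y, z, radius, parent)
    using distal end points, plus an optional JSON sidecar with section labels."""
    mid = tree.dist
    with open(path, "w") as f:
        f.write("# id type x y z radius parent\n")
        for i in range(len(tree)):
            t = _SWC_TYPE.get(str(tree.label[i]), 0)
            x, y, z = mid[i]
            f.write(f"{i + 1} {t} {x:.3f} {y:.3f} {z:.3f} "
                    f"{tree.diameter[i] / 2:.3f} {tree.parent[i] + 1 if tree.parent[i] >= 0 else -1}\n")
    if sidecar:
        with open(sidecar, "w") as f:
            json.dump({"labels": [str(x) for x in tree.label],
                       "section_id": tree.section_id.tolist()}, f)


def _save_tree(grp, tree: CompartmentTree) -> None:
    grp.create_dataset("parent", data=tree.parent)
    grp.create_dataset("prox", data=tree.prox)
    grp.create_dataset("dist", data=tree.dist)
    grp.create_dataset("diameter", data=tree.diameter)
    grp.create_dataset("label", data=np.char.encode(tree.label.astype("<U20")))
    grp.create_dataset("section_id", data=tree.section_id)


def _load_tree(grp) -> CompartmentTree:
    return CompartmentTree(
        parent=grp["parent"][:],
        prox=grp["prox"][:],
        dist=grp["dist"][:],
        diameter=grp["diameter"][:],
        label=np.char.decode(grp["label"][:]).astype("<U20"),
        section_id=grp["section_id"][:],
    )


def save_layout(layout: SliceLayout, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = layout.seed
        f.attrs["n_cells"] = layout.n_cells
        f.attrs["slice_thickness"] = layout.params.slice_thickness
        f.attrs["inactive_layer"] = layout.params.inactive_layer
        f.attrs["ellipse_center_x"] = layout.params.ellipse_center_x
        f.attrs["semi_major"] = layout.params.semi_major
        f.attrs["semi_minor"] = layout.params.semi_minor
        f.create_dataset("calyx_centers", data=layout.calyx_centers)
        f.create_dataset("pairing", data=layout.pairing)
        f.create_dataset("waypoint_boxes", data=layout.params.waypoint_boxes)
        for name, cells in (("gbc", layout.gbc_cells), ("mntb", layout.mntb_cells)):
            g = f.create_group(name)
            for i, tree in enumerate(cells):
                _save_tree(g.create_group(f"{i:04d}"), tree)


def load_layout(path: str) -> SliceLayout:
    with h5py.File(path, "r") as f:
        params = SliceParams(
            slice_thickness=float(f.attrs["slice_thickness"]),
            inactive_layer=float(f.attrs["inactive_layer"]),
            ellipse_center_x=float(f.attrs["ellipse_center_x"]),
            semi_major=float(f.attrs["semi_major"]),
            semi_minor=float(f.attrs["semi_minor"]),
            waypoint_boxes=f["waypoint_boxes"][:],
        )
        gbcs = [_load_tree(f["gbc"][k]) for k in sorted(f["gbc"])]
        mntbs = [_load_tree(f["mntb"][k]) for k in sorted(f["mntb"])]
        return SliceLayout(
            gbc_cells=gbcs,
            mntb_cells=mntbs,
            pairing=f["pairing"][:],
            calyx_centers=f["calyx_centers"][:],
            params=params,
            seed=int(f.attrs["seed"]),
        )
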