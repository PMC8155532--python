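"""Optogenetic stimulation: light transport in tissue and light-driven
excitation experiments.

Two light models are provided:

* :func:`km_transmittance` / :func:`km_irradiance` — the Kubelka-Munk (KM)
  closed form.  The transmittance factorizes as T(r,z) = G(r,z)·C(z)·M(x):
  G is the transverse source profile (flat-top fiber disc softened by a
  Gaussian whose width grows with the divergence angle), C = R0/R(z) is the
  geometric spread from conservation of radiant power, and
  M(x) = b / (a·sinh(bμs x) + b·cosh(bμs x)), a = 1 + μa/μs, b = √(a²−1),
  is the two-flux scattering/absorption attenuation along the travelled
  distance x = √(z²+r²).

* :func:`mc_irradiance` — Monte-Carlo photon-packet transport with
  Henyey-Greenstein anisotropic scattering, absorption-weighted voxel
  deposition and roulette termination.

On top of these, the module computes ChR2 irradiance thresholds
(strength-duration curves, rheobase, chronaxie) for the different parts of
the pathway, and slice-scale light-activation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .cable import CellTemplate, OpticalDrive, Stimuli, detect_spikes, run_simulation
from .chr2 import ChR2Params


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class OpticalTissue:
    """473 nm gray-matter defaults from the cited light-neuron model."""
    mu_s: float = 10.3          # scatter coefficient, mm⁻¹
    mu_a: float = 0.125         # absorption coefficient, mm⁻¹
    g: float = 0.88             # Henyey-Greenstein anisotropy (MC only)
    n: float = 1.36             # refractive index

    def validate(self):
        if self.mu_s <= 0 or self.mu_a < 0:
            raise ValueError("require mu_s > 0 and mu_a >= 0")
        if not -1 < self.g < 1:
            raise ValueError("anisotropy g must be in (-1, 1)")


@dataclass
class LightSource:
    """Optical fiber source.  ``position`` is the center of the fiber face
    (μm); the beam propagates along ``direction`` (default -z, i.e. from
    above the slice down)."""
    diameter: float = 200.0     # μm
    na: float = 0.37
    wavelength: float = 473.0   # nm
    irradiance: float = 1.0     # I0 at the source, W/mm²
    position: tuple = (400.0, 0.0, 375.0)
    direction: tuple = (0.0, 0.0, -1.0)

    def validate(self):
        if not 0 < self.na < 1:
            raise ValueError("NA must be in (0, 1)")
        if self.irradiance < 0:
            raise ValueError("irradiance must be non-negative")

    @property
    def radius_mm(self) -> float:
        return self.diameter / 2.0 * 1e-3

    def divergence(self, n_tissue: float) -> float:
        """Half divergence angle inside the tissue (rad)."""
        return np.arcsin(min(self.na / n_tissue, 1.0))


# ---------------------------------------------------------------------------
# Kubelka-Munk closed form
# ---------------------------------------------------------------------------

def km_scatter_attenuation(x_mm, tissue: OpticalTissue):
    """M(x): two-flux attenuation along the travelled distance x (mm)."""
    a = 1.0 + tissue.mu_a / tissue.mu_s
    b = np.sqrt(a * a - 1.0)
    arg = b * tissue.mu_s * np.asarray(x_mm, dtype=float)
    # lossless limit: mu_a = 0 gives a = 1, b = 0, M = 1
    with np.errstate(invalid="ignore", divide="ignore"):
        m = b / (a * np.sinh(arg) + b * np.cosh(arg))
    return np.where(b == 0.0, np.ones_like(arg), m)


def km_transmittance(r, z, tissue: OpticalTissue = None,
                     source: LightSource = None):
    """Transmittance T(r, z) ∈ [0, 1] at radial distance r and depth z (μm,
    z measured along the beam from the fiber face; z >= 0)."""
    tissue = tissue or OpticalTissue()
    source = source or LightSource()
    tissue.validate()
    source.validate()
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be non-negative (inside the tissue)")

    theta = source.divergence(tissue.n)
    r0 = source.diameter / 2.0                         # μm
    r_cone = r0 + z * np.tan(theta)                    # beam radius at depth z
    sigma = np.maximum(z * np.tan(theta), 1e-6)        # edge softening

    g_src = 0.5 * (1.0 + erf((r_cone - r) / (np.sqrt(2.0) * sigma)))
    g_sharp = (r <= r_cone).astype(float)
    g = np.where(z < 1e-9, g_sharp, g_src)

    c_geom = r0 / r_cone
    x_mm = np.sqrt(z * z + r * r) * 1e-3
    return g * c_geom * km_scatter_attenuation(x_mm, tissue)


def km_irradiance(points, tissue: OpticalTissue = None,
                  source: LightSource = None) -> np.ndarray:
    """Irradiance I(r, z) = T·I0 (W/mm²) at arbitrary 3-D points (μm).
    Points behind the fiber face receive zero."""
    tissue = tissue or OpticalTissue()
    source = source or LightSource()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pos = np.asarray(source.position, dtype=float)
    u = np.asarray(source.direction, dtype=float)
    u = u / np.linalg.norm(u)
    w = pts - pos
    zdist = w @ u
    rdist = np.linalg.norm(w - np.outer(zdist, u), axis=1)
    out = np.zeros(len(pts))
    ok = zdist >= 0
    if np.any(ok):
        out[ok] = source.irradiance * km_transmittance(rdist[ok], zdist[ok],
                                                       tissue, source)
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo photon transport
# ---------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    """Regular voxel grid; ``origin`` is the corner of voxel (0,0,0) in μm."""
    origin: tuple = (-100.0, -500.0, -500.0)
    shape: tuple = (40, 40, 40)
    spacing: float = 25.0       # μm

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.spacing * 1e-3) ** 3

    def centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.spacing


@dataclass
class IrradianceField:
    """Absorbed power density (W/mm³) and fluence rate (W/mm²) per voxel for
    unit source power bookkeeping; ``accounting`` records the weight budget."""
    grid: VoxelGrid
    absorbed: np.ndarray        # W/mm³
    fluence: np.ndarray         # W/mm²
    accounting: dict


def _hg_cos_theta(rng, g, n):
    if abs(g) < 1e-6:
        return rng.uniform(-1.0, 1.0, n)
    xi = rng.uniform(0.0, 1.0, n)
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)


def _rotate(u, cos_t, phi):
    """Rotate unit vectors u by polar angle arccos(cos_t), azimuth phi."""
    sin_t = np.sqrt(np.maximum(1.0 - cos_t ** 2, 0.0))
    cp, sp = np.cos(phi), np.sin(phi)
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    near_pole = np.abs(uz) > 0.99999
    denom = np.sqrt(np.maximum(1.0 - uz * uz, 1e-12))
    out = np.empty_like(u)
    out[:, 0] = sin_t * (ux * uz * cp - uy * sp) / denom + ux * cos_t
    out[:, 1] = sin_t * (uy * uz * cp + ux * sp) / denom + uy * cos_t
    out[:, 2] = -sin_t * cp * denom + uz * cos_t
    if np.any(near_pole):
        sgn = np.sign(uz[near_pole])
        out[near_pole, 0] = sin_t[near_pole] * cp[near_pole]
        out[near_pole, 1] = sin_t[near_pole] * sp[near_pole]
        out[near_pole, 2] = sgn * cos_t[near_pole]
    return out


def mc_irradiance(source: LightSource = None, tissue: OpticalTissue = None,
                  n_photons: int = 100_000, seed: int = 0,
                  grid: VoxelGrid = None, geometry: str = "fiber",
                  roulette_threshold: float = 1e-4, max_steps: int = 4000) -> IrradianceField:
    """Monte-Carlo random walk of photon packets (see module docstring).

    Packets start on the fiber face with directions uniform in the emission
    cone (or isotropically from a point for ``geometry='isotropic'``).  Each
    step deposits the fraction μa/(μa+μs) of the packet weight in the current
    voxel; the new direction is drawn from the Henyey-Greenstein phase
    function; packets below the roulette threshold survive with p = 0.1.
    Output is normalized so that voxel values are per unit of total source
    power: ``absorbed`` in W/mm³ and ``fluence`` = absorbed/μa in W/mm² for a
    1 W source; scale by the true source power for physical units.
    """
    source = source or LightSource()
    tissue = tissue or OpticalTissue()
    grid = grid or VoxelGrid()
    tissue.validate()
    if n_photons < 10_000:
        raise ValueError("n_photons must be at least 10^4")
    rng = np.random.default_rng(seed)

    pos0 = np.asarray(source.position, dtype=float)
    u0 = np.asarray(source.direction, dtype=float)
    u0 = u0 / np.linalg.norm(u0)

    if geometry == "fiber":
        # uniform positions on the fiber disc
        rr = source.diameter / 2.0 * np.sqrt(rng.uniform(0, 1, n_photons))
        aa = rng.uniform(0, 2 * np.pi, n_photons)
        e1 = np.array([1.0, 0.0, 0.0]) if abs(u0[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = e1 - (e1 @ u0) * u0
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u0, e1)
        pos = pos0 + rr[:, None] * (np.cos(aa)[:, None] * e1 + np.sin(aa)[:, None] * e2)
        # directions uniform in the emission cone (solid angle)
        theta_max = source.divergence(tissue.n)
        cos_t = 1.0 - rng.uniform(0, 1, n_photons) * (1.0 - np.cos(theta_max))
        phi = rng.uniform(0, 2 * np.pi, n_photons)
        direc = _rotate(np.tile(u0, (n_photons, 1)), cos_t, phi)
    elif geometry == "isotropic":
        pos = np.tile(pos0, (n_photons, 1))
        cos_t = rng.uniform(-1, 1, n_photons)
        phi = rng.uniform(0, 2 * np.pi, n_photons)
        z = cos_t
        s = np.sqrt(1 - z ** 2)
        direc = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    else:
        raise ValueError("geometry must be 'fiber' or 'isotropic'")

    w = np.ones(n_photons)
    absorbed = np.zeros(grid.shape)
    mu_t = tissue.mu_s + tissue.mu_a
    albedo_loss = tissue.mu_a / mu_t
    origin = np.asarray(grid.origin, dtype=float)
    upper = origin + np.asarray(grid.shape) * grid.spacing
    escaped = 0.0
    roulette_killed = 0.0
    roulette_boost = 0.0

    active = np.arange(n_photons)
    for _ in range(max_steps):
        if len(active) == 0:
            break
        n_act = len(active)
        step = -np.log(rng.uniform(1e-12, 1.0, n_act)) / mu_t * 1e3   # μm
        pos[active] += direc[active] * step[:, None]

        inside = np.all((pos[active] >= origin) & (pos[active] < upper), axis=1)
        esc = active[~inside]
        escaped += w[esc].sum()
        active = active[inside]
        if len(active) == 0:
            break

        idx = ((pos[active] - origin) / grid.spacing).astype(int)
        dep = w[active] * albedo_loss
        np.add.at(absorbed, (idx[:, 0], idx[:, 1], idx[:, 2]), dep)
        w[active] -= dep

        cos_t = _hg_cos_theta(rng, tissue.g, len(active))
        phi = rng.uniform(0, 2 * np.pi, len(active))
        direc[active] = _rotate(direc[active], cos_t, phi)
        norms = np.linalg.norm(direc[active], axis=1, keepdims=True)
        direc[active] /= norms

        low = w[active] < roulette_threshold
        if np.any(low):
            li = active[low]
            survive = rng.uniform(0, 1, len(li)) < 0.1
            roulette_killed += w[li[~survive]].sum()
            roulette_boost += w[li[survive]].sum() * 9.0
            w[li[survive]] *= 10.0
            w[li[~survive]] = 0.0
            active = np.concatenate([active[~low], li[survive]])

    residual = w[active].sum() if len(active) else 0.0
    accounting = {
        "launched": float(n_photons),
        "deposited": float(absorbed.sum()),
        "escaped": float(escaped),
        "residual": float(residual),
        "roulette_net": float(roulette_killed - roulette_boost),
    }
    # normalize to unit source power (1 W): weight fraction per voxel volume
    absorbed_w_mm3 = absorbed / n_photons / grid.voxel_volume_mm3
    with np.errstate(divide="ignore", invalid="ignore"):
        fluence = absorbed_w_mm3 / tissue.mu_a if tissue.mu_a > 0 else np.zeros_like(absorbed_w_mm3)
    return IrradianceField(grid=grid, absorbed=absorbed_w_mm3, fluence=fluence,
                           accounting=accounting)


# ---------------------------------------------------------------------------
# irradiance thresholds and strength-duration curves
# ---------------------------------------------------------------------------

TARGET_SECTIONS = {
    "gbc_soma": ("soma", "primary_dendrite", "secondary_dendrite", "hillock",
                 "initial_segment"),
    "calyx": ("calyx",),
    "mntb_soma": ("mntb_soma", "mntb_dendrite"),
    "axon_nodes": ("node", "heminode"),
}


def _detection_comp(template: CellTemplate, target: str) -> int:
    if target == "mntb_soma":
        return int(template.indices("mntb_node")[-1])
    return template.node_from_is(7)


def _spikes_for_irradiances(template: CellTemplate, target: str,
                            irradiances: np.ndarray, pulse_ms,
                            chr2_params: ChR2Params, latency: float = 8.0):
    """Run one population where each column is one (irradiance, duration)
    candidate; returns a boolean spike mask."""
    comps = np.flatnonzero(np.isin(template.label, TARGET_SECTIONS[target]))
    nc = len(irradiances)
    irr = np.tile(np.asarray(irradiances, dtype=float), (len(comps), 1))
    pulse = np.asarray(pulse_ms, dtype=float)
    t_off = 0.1 + (pulse if pulse.ndim else float(pulse))
    drive = OpticalDrive(irradiance=irr, t_on=0.1, t_off=t_off,
                         params=chr2_params, comps=comps)
    duration = float(np.max(t_off)) + latency
    trace = run_simulation(template, Stimuli(optical=drive), duration=duration,
                           n_cells=nc)
    det = _detection_comp(template, target)
    return np.array([len(detect_spikes(trace, det, c)) > 0 for c in range(nc)])


def irradiance_threshold(template: CellTemplate, target: str, pulse_ms: float,
                         chr2_params: ChR2Params = None, i_max: float = 10.0,
                         i_min: float = 1e-4, rel_tol: float = 0.01) -> float:
    """Threshold source-level irradiance (W/mm²) for AP generation when the
    ``target`` section is illuminated uniformly with a ``pulse_ms`` pulse.

    Batched bracketing + refinement to ``rel_tol`` relative precision.
    Returns ``np.inf`` if even ``i_max`` fails to elicit a spike (e.g.
    illumination of the myelinated axon)."""
    chr2_params = chr2_params or ChR2Params()
    lo, hi = i_min, i_max
    for _ in range(3):
        cand = np.geomspace(lo, hi, 10)
        spk = _spikes_for_irradiances(template, target, cand, pulse_ms, chr2_params)
        if not spk.any():
            if hi >= i_max:
                return np.inf
            lo, hi = hi, min(hi * 10, i_max)
            continue
        k = int(np.argmax(spk))
        if k == 0:
            if lo <= i_min * 1.01:
                return float(cand[0])
            lo, hi = max(lo / 10, i_min), lo
            continue
        lo, hi = cand[k - 1], cand[k]
        if hi / lo - 1.0 < rel_tol:
            break
    return float(np.sqrt(lo * hi))


@dataclass
class StrengthDurationResult:
    durations: np.ndarray
    thresholds: np.ndarray
    rheobase: float
    chronaxie: float
    monotone: bool


def chronaxie_from_curve(durations, thresholds) -> float:
    """Pulse duration at which the threshold is twice the rheobase (threshold
    at the longest duration), log-interpolated on the duration axis."""
    d = np.asarray(durations, dtype=float)
    th = np.asarray(thresholds, dtype=float)
    order = np.argsort(d)
    d, th = d[order], th[order]
    rheo = th[-1]
    target = 2.0 * rheo
    if th[0] <= target:
        return float(d[0])
    k = int(np.argmax(th <= target))
    ld = np.log(d)
    frac = (np.log(th[k - 1]) - np.log(target)) / (np.log(th[k - 1]) - np.log(th[k]))
    return float(np.exp(ld[k - 1] + frac * (ld[k] - ld[k - 1])))


def strength_duration(template: CellTemplate, target: str,
                      durations=(0.3, 0.5, 1.0, 2.0, 3.0, 5.0, 10.0, 20.0),
                      chr2_params: ChR2Params = None, i_max: float = 10.0,
                      i_min: float = 1e-4, rel_tol: float = 0.01,
                      n_cand: int = 10, n_rounds: int = 3) -> StrengthDurationResult:
    """Strength-duration curve of the light threshold for one pathway part.

    All durations are bracketed simultaneously: each refinement round runs a
    single population in which every column is one (duration, irradiance)
    candidate."""
    chr2_params = chr2_params or ChR2Params()
    durations = np.asarray(durations, dtype=float)
    if len(durations) < 6:
        raise ValueError("need at least 6 pulse durations")
    nd = len(durations)
    lo = np.full(nd, i_min)
    hi = np.full(nd, i_max)
    failed = np.zeros(nd, dtype=bool)
    for _ in range(n_rounds):
        cand = np.exp(np.linspace(np.log(lo), np.log(hi), n_cand)).T  # (nd, n_cand)
        irr = cand.ravel()
        dur = np.repeat(durations, n_cand)
        spk = _spikes_for_irradiances(template, target, irr, dur, chr2_params
                                      ).reshape(nd, n_cand)
        for j in range(nd):
            if not spk[j].any():
                failed[j] = True
                continue
            k = int(np.argmax(spk[j]))
            if k == 0:
                lo[j], hi[j] = lo[j], cand[j, 0]
            else:
                lo[j], hi[j] = cand[j, k - 1], cand[j, k]
    th = np.sqrt(lo * hi)
    th[failed] = np.inf
    order = np.argsort(durations)
    d, t = durations[order], th[order]
    monotone = bool(np.all(np.diff(t) <= t[:-1] * (2 * rel_tol + 0.02)))
    return StrengthDurationResult(
        durations=d, thresholds=t, rheobase=float(t[-1]),
        chronaxie=chronaxie_from_curve(d, t), monotone=monotone,
    )
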