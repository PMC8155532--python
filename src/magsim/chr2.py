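"""Channelrhodopsin-2 four-state photocycle (two closed, two open states).

States C1 → O1 → O2 → C2 → C1 with light-driven activation rates

    Ka_i(t) = ε_i · φ · u(t),

where φ is the photon flux per channel (irradiance × molecular cross-section
/ photon energy at 473 nm) and u(t) is the activation memory: u relaxes
toward 1 with time constant τ while light is on and decays back to 0 after
light-off, which reproduces the exponential activation during illumination
and the biexponential tail afterwards.  Occupancies obey C1+C2+O1+O2 = 1 at
all times (C1 is eliminated by the conservation law).

The photocurrent is

    I = i_max (O1 + γ O2) (1 − e^(−U/U0)) / (U/U1),   i_max = (V − E) g1 ρ,

with U the absolute transmembrane potential; the last factor is the
empirical inward rectification (analytic limit U1/U0 at U → 0).

Rate constants default to the cited four-state ChR2 literature; the
single-channel conductance is calibrated to the printed irradiance-threshold
anchors.  Everything is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PLANCK = 6.62607015e-34     # J s
C_LIGHT = 2.99792458e8      # m/s


@dataclass
class ChR2Params:
    eps1: float = 0.25          # quantum efficiency C1→O1
    eps2: float = 0.075         # quantum efficiency C2→O2
    tau: float = 2.0            # activation time constant, ms
    k_d1: float = 0.13          # O1→C2 decay, ms⁻¹
    k_d2: float = 0.025         # O2→C2 decay, ms⁻¹
    k_r: float = 4e-4           # C2→C1 thermal recovery, ms⁻¹
    e12: float = 0.053          # O1→O2, ms⁻¹
    e21: float = 0.023          # O2→O1, ms⁻¹
    gamma: float = 0.05         # conductance ratio O2/O1
    e_rev: float = 0.0          # mV
    u0: float = 40.0            # rectification constant, mV
    u1: float = 15.0            # rectification constant, mV
    g1: float = 5.5e-7          # single-channel conductance, μS (0.55 pS)
    rho: float = 1.3e10         # channel density, channels/cm²
    cross_section_um2: float = 1.2e-8
    wavelength_nm: float = 473.0
    lambda1: float = 0.011      # slow post-light current decay factor, ms⁻¹
    lambda2: float = 0.13       # fast post-light current decay factor, ms⁻¹

    def validate(self):
        for name in ("eps1", "eps2", "tau", "k_d1", "k_d2", "k_r", "e12", "e21",
                     "g1", "rho"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")

    @property
    def photon_flux_coef(self) -> float:
        """Photons per channel per ms at 1 W/mm² irradiance."""
        e_photon = PLANCK * C_LIGHT / (self.wavelength_nm * 1e-9)   # J
        sigma_mm2 = self.cross_section_um2 * 1e-6
        return sigma_mm2 / e_photon * 1e-3                          # per ms

    @property
    def g_density(self) -> float:
        """Membrane ChR2 conductance density g1·ρ (S/cm²)."""
        return self.g1 * 1e-6 * self.rho


def rectification(u, params: ChR2Params = None):
    """(1 − e^(−U/U0)) / (U/U1) with the analytic U → 0 limit U1/U0."""
    p = params or ChR2Params()
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-9
    us = np.where(small, 1.0, u)
    out = (1.0 - np.exp(-us / p.u0)) / (us / p.u1)
    return np.where(small, p.u1 / p.u0, out)


def chr2_current_density(o1, o2, v, params: ChR2Params = None):
    """ChR2 current density (nA per cm² of membrane); the absolute form used
    in simulations lives in :class:`ChR2PopulationState`."""
    p = params or ChR2Params()
    u = np.abs(np.asarray(v, dtype=float) - p.e_rev)
    imax = (v - p.e_rev) * p.g_density * 1e6          # μS/cm² × mV = nA/cm²
    return imax * (o1 + p.gamma * o2) * rectification(u, p)


def rate_matrix(params: ChR2Params, irradiance: float, u: float = 1.0) -> np.ndarray:
    """4×4 generator matrix d/dt [C1, O1, O2, C2] = K @ state at constant
    light-memory u and irradiance (W/mm²)."""
    p = params
    phi = irradiance * p.photon_flux_coef
    ka1, ka2 = p.eps1 * phi * u, p.eps2 * phi * u
    return np.array([
        [-ka1, 0.0, 0.0, p.k_r],
        [ka1, -(p.k_d1 + p.e12), p.e21, 0.0],
        [0.0, p.e12, -(p.k_d2 + p.e21), ka2],
        [0.0, p.k_d1, p.k_d2, -(ka2 + p.k_r)],
    ])


def post_light_current(t_after_off, i_slow, i_fast, params: ChR2Params = None):
    """Empirical biexponential description of the current tail after
    light-off (the state ODEs produce this shape; the helper is provided for
    fitting/diagnostics)."""
    p = params or ChR2Params()
    t = np.asarray(t_after_off, dtype=float)
    return i_slow * np.exp(-p.lambda1 * t) + i_fast * np.exp(-p.lambda2 * t)


class ChR2PopulationState:
    """Photocycle state for a set of expressing compartments × cells.

    ``step`` advances the occupancies by one time step (sequential
    exponential-Euler on the rate equations, conservation enforced through
    C1 = 1 − O1 − O2 − C2) and returns the photocurrent in nA (outward
    positive, i.e. negative = depolarizing)."""

    def __init__(self, params: ChR2Params, comps: np.ndarray, n_cells: int,
                 area_cm2: np.ndarray):
        params.validate()
        self.params = params
        self.comps = np.asarray(comps, dtype=int)
        shape = (len(self.comps), n_cells)
        self.o1 = np.zeros(shape)
        self.o2 = np.zeros(shape)
        self.c2 = np.zeros(shape)
        self.u = 0.0                      # light-activation memory
        self.g_abs = params.g_density * np.asarray(area_cm2) * 1e6   # μS

    @property
    def c1(self):
        return 1.0 - self.o1 - self.o2 - self.c2

    def occupancy_drift(self) -> float:
        total = self.c1 + self.o1 + self.o2 + self.c2
        return float(np.max(np.abs(total - 1.0)))

    def step(self, dt: float, v: np.ndarray, irradiance: np.ndarray,
             light_on) -> np.ndarray:
        """Advance one step.  ``light_on`` may be a bool or a per-cell boolean
        array (cells may have different pulse timing)."""
        p = self.params
        target = np.asarray(light_on, dtype=float)
        self.u = target + (self.u - target) * np.exp(-dt / p.tau)

        phi = np.asarray(irradiance) * p.photon_flux_coef
        ka1 = p.eps1 * phi * self.u
        ka2 = p.eps2 * phi * self.u

        c1 = self.c1
        b1 = p.k_d1 + p.e12
        a1 = ka1 * c1 + p.e21 * self.o2
        self.o1 = a1 / b1 + (self.o1 - a1 / b1) * np.exp(-b1 * dt)

        b2 = p.k_d2 + p.e21
        a2 = ka2 * self.c2 + p.e12 * self.o1
        self.o2 = a2 / b2 + (self.o2 - a2 / b2) * np.exp(-b2 * dt)

        b3 = np.maximum(ka2 + p.k_r, 1e-300)
        a3 = p.k_d1 * self.o1 + p.k_d2 * self.o2
        self.c2 = a3 / b3 + (self.c2 - a3 / b3) * np.exp(-b3 * dt)

        np.clip(self.o1, 0.0, 1.0, out=self.o1)
        np.clip(self.o2, 0.0, 1.0, out=self.o2)
        np.clip(self.c2, 0.0, 1.0, out=self.c2)
        if self.occupancy_drift() > 1e-9 + 1e-12:
            # conservation is structural; any violation indicates a blown step
            raise FloatingPointError("ChR2 occupancy conservation violated")

        u_abs = np.abs(v - p.e_rev)
        i = self.g_abs[:, None] * (v - p.e_rev) * (self.o1 + p.gamma * self.o2) \
            * rectification(u_abs, p)
        return i
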