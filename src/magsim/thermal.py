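"""Optothermal heating: explicit finite-difference solution of the
simplified Pennes bioheat equation

    ρc ∂T/∂t = ∇·(k ∇T) + φ μa,

with the perfusion/convection term omitted (appropriate for an acute slice
preparation bathed in ACSF).  The source term φ·μa (W/mm³) is the absorbed
light power density, typically taken from the Monte-Carlo light model as the
worst case.  Forward Euler with the 7-point Laplacian stencil; the time step
obeys the 3-D stability bound Δt ≤ Δx²ρc/(6k).  Boundaries are Dirichlet
ΔT = 0 (the bath acts as a heat sink); the temperature variable is the
increment over the ambient temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ThermalParams:
    rho: float = 1.04e3         # mass density, kg/m³
    c: float = 3.6e3            # specific heat, J/(kg·K)  (= 3.6 J/gK)
    k: float = 0.56             # thermal conductivity, W/(m·K)
    dx: float = 0.03            # spatial step, mm
    safety: float = 0.9         # fraction of the stability bound used

    def validate(self):
        if min(self.rho, self.c, self.k, self.dx) <= 0 or not 0 < self.safety <= 1:
            raise ValueError("thermal constants must be positive (safety in (0,1])")

    @property
    def dt_max(self) -> float:
        """Stability bound Δt ≤ Δx²ρc/(6k) in seconds (Δx converted to m)."""
        return (self.dx * 1e-3) ** 2 * self.rho * self.c / (6.0 * self.k)

    @property
    def alpha(self) -> float:
        """Thermal diffusivity k/(ρc), m²/s."""
        return self.k / (self.rho * self.c)


@dataclass
class PulseProtocol:
    """Continuous illumination (rate = 0) or pulsed (pulse_ms at rate_hz)."""
    pulse_ms: float = 0.0
    rate_hz: float = 0.0

    @property
    def continuous(self) -> bool:
        return self.rate_hz <= 0

    @property
    def duty_cycle(self) -> float:
        if self.continuous:
            return 1.0
        return min(self.pulse_ms * 1e-3 * self.rate_hz, 1.0)

    def on_fraction(self, t0: float, t1: float) -> float:
        """Exact fraction of [t0, t1] (s) during which the source is on."""
        if self.continuous:
            return 1.0
        period = 1.0 / self.rate_hz
        width = min(self.pulse_ms * 1e-3, period)

        def integral(t):
            n, frac = divmod(t, period)
            return n * width + min(frac, width)

        return (integral(t1) - integral(t0)) / max(t1 - t0, 1e-300)


@dataclass
class ThermalResult:
    t: np.ndarray               # s
    max_dT: np.ndarray          # °C, spatial maximum per sample
    dT: np.ndarray              # final 3-D field, °C
    params: ThermalParams


def solve_bioheat(source: np.ndarray, params: ThermalParams = None,
                  protocol: PulseProtocol = None, t_end: float = 10.0,
                  sample_every: float = 0.05, dt: float = None) -> ThermalResult:
    """Integrate the bioheat equation.

    ``source`` is the absorbed power density φμa (W/mm³) on a regular grid
    with spacing ``params.dx`` (mm); the array boundary is held at ΔT = 0.
    Pulsed protocols gate the source with the exact per-step on-fraction, so
    time steps longer than a single pulse still deposit the correct energy.
    """
    params = params or ThermalParams()
    params.validate()
    protocol = protocol or PulseProtocol()
    src = np.asarray(source, dtype=float)
    if src.ndim != 3:
        raise ValueError("source must be a 3-D grid")

    # optional smaller dt (e.g. to resolve short light pulses); never above
    # the stability bound
    dt = min(dt, params.safety * params.dt_max) if dt else params.safety * params.dt_max
    n_steps = max(int(np.ceil(t_end / dt)), 1)
    dt = t_end / n_steps
    dx_m = params.dx * 1e-3
    r = params.alpha * dt / dx_m ** 2            # stability requires r <= 1/6
    # source: W/mm³ = 1e9 W/m³; ΔT gain per second = φμa/(ρc)
    gain = src * 1e9 / (params.rho * params.c) * dt

    T = np.zeros_like(src)
    samples_t, samples_max = [0.0], [0.0]
    next_sample = sample_every
    running_max = 0.0
    for k in range(n_steps):
        lap = (
            np.roll(T, 1, 0) + np.roll(T, -1, 0)
            + np.roll(T, 1, 1) + np.roll(T, -1, 1)
            + np.roll(T, 1, 2) + np.roll(T, -1, 2)
            - 6.0 * T
        )
        on = protocol.on_fraction(k * dt, (k + 1) * dt)
        T = T + r * lap + gain * on
        # Dirichlet boundary
        T[0, :, :] = T[-1, :, :] = 0.0
        T[:, 0, :] = T[:, -1, :] = 0.0
        T[:, :, 0] = T[:, :, -1] = 0.0

        t_now = (k + 1) * dt
        m = float(T.max())
        if not np.isfinite(m) or m > 1e6:
            raise FloatingPointError("bioheat integration unstable")
        running_max = max(running_max, m)
        if t_now >= next_sample or k == n_steps - 1:
            # report the running max since the last sample so that the brief
            # within-pulse temperature spikes of pulsed protocols are captured
            samples_t.append(t_now)
            samples_max.append(running_max)
            next_sample += sample_every
            running_max = 0.0

    return ThermalResult(t=np.asarray(samples_t), max_dT=np.asarray(samples_max),
                         dT=T, params=params)


def fiber_source_grid(field, params: ThermalParams = None,
                      extent_mm: float = 3.0):
    """Resample an :class:`~magsim.optostim.IrradianceField` absorbed-power
    map (per 1 W source) onto a cubic thermal grid of ``extent_mm`` side with
    spacing ``params.dx``, centred on the optical grid centre.  Returns the
    source array in W/mm³ per watt of source power."""
    from scipy.interpolate import RegularGridInterpolator

    params = params or ThermalParams()
    g = field.grid
    axes = [g.centers(i) * 1e-3 for i in range(3)]        # mm
    interp = RegularGridInterpolator(axes, field.absorbed, bounds_error=False,
                                     fill_value=0.0)
    n = int(round(extent_mm / params.dx))
    center = np.array([(ax[0] + ax[-1]) / 2 for ax in axes])
    coords = [center[i] + (np.arange(n) - (n - 1) / 2) * params.dx for i in range(3)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    return interp(pts).reshape(n, n, n)
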