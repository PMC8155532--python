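"""Conductance-based compartmental cable solver.

The branched cable equation is integrated with a theta-method (default
Crank-Nicolson, θ = 0.5) using a Hines-ordered direct solve of the tree
system; gating variables advance by exponential Euler, staggered with the
voltage update.  The internal time step is 5 μs and output is decimated to
the 25 μs resolution used by all downstream stages.

All cells of one morphological type share the same one-dimensional electrical
structure, so a whole population is integrated at once on arrays of shape
(n_compartments, n_cells); per-cell stimuli (injected currents, extracellular
potentials, ChR2 irradiance, synaptic conductances) enter as per-column
drives.

Units: mV, ms, nA, μS, nF (so that C·dV/dt and g·V are both in nA).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from . import channels as chn
from .chr2 import ChR2Params, ChR2PopulationState
from .morphology import CompartmentTree

DT_INTERNAL = 0.005     # ms
DT_OUTPUT = 0.025       # ms


# ---------------------------------------------------------------------------
# membrane parameters
# ---------------------------------------------------------------------------

def default_densities() -> dict:
    """Maximal conductance densities (S/cm²) per section label.

    Somatic values follow the published type-II VCN bushy-cell complement;
    nodal, initial-segment and MNTB densities are calibrated to the printed
    behavioural anchors (conduction velocity 5-10 m/s, reliable 200 Hz
    following, single-AP MNTB response).
    """
    node = {"na": 3.4, "klt": 0.04, "kht": 1.0, "leak": 0.004}
    return {
        "soma": {"na": 0.083, "klt": 0.0167, "kht": 0.0125, "ih": 0.00167, "leak": 0.000167},
        "primary_dendrite": {"klt": 0.0017, "ih": 0.00017, "leak": 0.000167},
        "secondary_dendrite": {"klt": 0.0017, "ih": 0.00017, "leak": 0.000167},
        "hillock": {"na": 0.166, "klt": 0.0167, "kht": 0.0125, "leak": 0.000167},
        "initial_segment": {"na": 0.6, "klt": 0.0167, "kht": 0.0125, "leak": 0.000333},
        "internode": {"leak": 1e-5},
        "node": dict(node),
        "heminode": dict(node),
        "post_heminode": {},            # pure capacitor, per the pathway model
        "calyx": {"kht": 0.0125, "ih": 0.0005, "ca": 0.005, "leak": 0.00033},
        "mntb_soma": {"na_mntb": 0.7, "klt": 0.2, "kht": 0.1, "ih": 0.004, "leak": 0.0002},
        "mntb_dendrite": {"klt": 0.0017, "ih": 0.00017, "leak": 0.000167},
        "mntb_internode": {"leak": 1e-5},
        "mntb_node": dict(node),
    }


MYELIN_LABELS = ("internode", "mntb_internode")


@dataclass
class MembraneParams:
    celsius: float = 34.0
    cm: float = 0.9                    # μF/cm²
    cm_myelin: float = 0.009           # lumped myelin sheath capacitance, μF/cm²
    ra: float = 340.0                  # axial resistivity, Ω·cm
    e_rev: dict = dc_field(default_factory=lambda: {
        "na": 55.0, "na_mntb": 55.0, "klt": -70.0, "kht": -70.0, "ih": -43.0,
        "ca": 45.0, "leak": -65.0})
    densities: dict = dc_field(default_factory=default_densities)
    # electrical membrane area per unit of geometric cylinder area.  The calyx
    # of Held is represented geometrically as a thin half ring, but its real
    # cup-shaped terminal carries an order of magnitude more membrane; the
    # multiplier folds that surface into the ring compartments (it scales
    # capacitance and all conductances, leaving the current-path geometry —
    # and hence the field forward model — untouched).
    area_factor: dict = dc_field(default_factory=lambda: {"calyx": 12.0})
    q10_gates: float = chn.Q10_GATES
    q10_cond: float = chn.Q10_COND
    v_init: float = -64.0

    def validate(self):
        for lbl, mech in self.densities.items():
            for ch, g in mech.items():
                if g < 0:
                    raise ValueError(f"negative conductance for {lbl}/{ch}")


# ---------------------------------------------------------------------------
# compiled cell template
# ---------------------------------------------------------------------------

class CellTemplate:
    """A `CompartmentTree` compiled to solver arrays (absolute conductances,
    capacitances, axial couplings, per-channel compartment index sets)."""

    def __init__(self, tree: CompartmentTree, membrane: MembraneParams = None):
        membrane = membrane or MembraneParams()
        membrane.validate()
        self.tree = tree
        self.membrane = membrane
        n = len(tree)
        self.n = n
        self.parent = tree.parent.copy()
        self.label = tree.label

        factor = np.array([membrane.area_factor.get(str(l), 1.0) for l in tree.label])
        area = tree.areas * 1e-8 * factor       # effective membrane area, cm²
        self.area_cm2 = area
        cm_density = np.where(np.isin(tree.label, MYELIN_LABELS),
                              membrane.cm_myelin, membrane.cm)
        self.cm_nF = cm_density * area * 1e3

        qc = membrane.q10_cond ** ((membrane.celsius - chn.RATES_REF_CELSIUS) / 10.0)
        self.g_abs: dict[str, np.ndarray] = {}
        for i, lbl in enumerate(tree.label):
            for ch, dens in membrane.densities.get(str(lbl), {}).items():
                self.g_abs.setdefault(ch, np.zeros(n))[i] = dens * area[i] * 1e6 * qc
        self.chan_idx = {ch: np.flatnonzero(g > 0) for ch, g in self.g_abs.items()}

        # axial coupling conductance between each compartment and its parent
        L_cm = tree.lengths * 1e-4
        a_cm = tree.diameter / 2.0 * 1e-4
        r_half = membrane.ra * (L_cm / 2.0) / (np.pi * a_cm ** 2)   # Ω
        g_c = np.zeros(n)
        for i in range(1, n):
            g_c[i] = 1e6 / (r_half[i] + r_half[self.parent[i]])     # μS
        self.g_c = g_c
        cpl_diag = g_c.copy()
        np.add.at(cpl_diag, self.parent[1:], g_c[1:])
        self.cpl_diag = cpl_diag

        # geometry used by the field forward model
        self.midpoints = tree.midpoints
        self._resting_cache: Optional[tuple] = None

    # -- section helpers ----------------------------------------------------

    def indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.label == label)

    def node_compartments(self) -> np.ndarray:
        """Nodes of Ranvier ordered from the initial segment toward the calyx
        (GBC trees).  The heminode is not counted as a numbered node."""
        return self.indices("node")

    def node_from_is(self, k: int) -> int:
        """k-th node of Ranvier counted from the initial segment (1-based)."""
        return int(self.node_compartments()[k - 1])

    def node_from_calyx(self, k: int) -> int:
        """k-th node of Ranvier counted from the calyx (1-based)."""
        return int(self.node_compartments()[-k])

    def chr2_compartments(self, expression=("soma", "mntb_soma", "calyx", "node",
                                            "heminode", "mntb_node")) -> np.ndarray:
        return np.flatnonzero(np.isin(self.label, expression))

    # -- resting state ------------------------------------------------------

    def resting_state(self, t_settle: float = 120.0):
        """Relax a single unstimulated cell to rest; returns (V[n], gates)."""
        if self._resting_cache is None:
            v = np.full((self.n, 1), self.membrane.v_init)
            gates = _init_gates(self, v)
            v, gates = _integrate(self, v, gates, duration=t_settle, dt=0.025,
                                  stimuli=Stimuli(), record=False)
            self._resting_cache = (v[:, 0].copy(), {k: g[:, 0].copy() for k, g in gates.items()})
        return self._resting_cache


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

@dataclass
class CurrentPulse:
    """Intracellular current injection (nA) into ``comps``; rectangular
    pulse(s).  ``amplitude`` may be a scalar or per-cell array."""
    comps: np.ndarray
    amplitude: float | np.ndarray
    onset: float
    duration: float
    period: float = 0.0      # > 0 for pulse trains
    n_pulses: int = 1

    def active(self, t: float) -> float:
        if self.n_pulses <= 1 or self.period <= 0:
            return 1.0 if self.onset <= t < self.onset + self.duration else 0.0
        k = np.floor((t - self.onset) / self.period)
        if k < 0 or k >= self.n_pulses:
            return 0.0
        return 1.0 if (t - self.onset) - k * self.period < self.duration else 0.0


@dataclass
class ExtracellularDrive:
    """Quasi-static extracellular potential: a fixed spatial pattern (mV, shape
    (n_comps, n_cells)) gated by a rectangular pulse."""
    pattern: np.ndarray
    onset: float
    duration: float

    def gate(self, t: float) -> float:
        return 1.0 if self.onset <= t < self.onset + self.duration else 0.0


@dataclass
class OpticalDrive:
    """ChR2 photostimulation: irradiance (W/mm², shape (n_expressing, n_cells))
    on the template's ChR2-expressing compartments, with pulse timing."""
    irradiance: np.ndarray
    t_on: float
    t_off: float
    params: ChR2Params = dc_field(default_factory=ChR2Params)
    comps: np.ndarray = None            # defaults to template.chr2_compartments()
    period: float = 0.0
    n_pulses: int = 1

    def light_on(self, t: float):
        """Bool (or per-cell bool array, when ``t_off`` is an array) gating
        the light at time ``t``."""
        if self.n_pulses <= 1 or self.period <= 0:
            t_off = np.asarray(self.t_off)
            on = (self.t_on <= t) & (t < t_off)
            return on if t_off.ndim else bool(on)
        k = np.floor((t - self.t_on) / self.period)
        if k < 0 or k >= self.n_pulses:
            return False
        return bool((t - self.t_on) - k * self.period < (self.t_off - self.t_on))


@dataclass
class SynapticDrive:
    """Excitatory synaptic conductance (μS, reversal 0 mV): per-step time
    series g[t_index, cell] distributed over ``comps`` with ``weights``."""
    g: np.ndarray
    comps: np.ndarray
    weights: np.ndarray
    e_rev: float = 0.0


@dataclass
class Stimuli:
    current: list = dc_field(default_factory=list)
    extracellular: Optional[ExtracellularDrive] = None
    optical: Optional[OpticalDrive] = None
    synaptic: Optional[SynapticDrive] = None


# ---------------------------------------------------------------------------
# state trace
# ---------------------------------------------------------------------------

@dataclass
class StateTrace:
    """Per-compartment time series at the 25 μs output resolution.

    Arrays are compartment-major: shape (n_frames, n_comps, n_cells).
    ``i_axial[t, i]`` is the axial current flowing from ``parent[i]`` into
    compartment ``i`` (nA); ``i_m`` is the total transmembrane (ionic +
    capacitive) current (nA, outward positive).
    """
    t: np.ndarray
    v: np.ndarray
    i_axial: np.ndarray
    i_m: np.ndarray
    template: CellTemplate

    @property
    def n_cells(self) -> int:
        return self.v.shape[2] if self.v.ndim == 3 else 0


# ---------------------------------------------------------------------------
# integration internals
# ---------------------------------------------------------------------------

def _init_gates(tpl: CellTemplate, v: np.ndarray) -> dict:
    gates = {}
    for ch, idx in tpl.chan_idx.items():
        if ch == "leak":
            continue
        for g in chn.GATE_NAMES[ch]:
            inf, _ = chn.gate_dynamics(v[idx], ch, g, tpl.membrane.celsius,
                                       tpl.membrane.q10_gates)
            gates[(ch, g)] = inf
    return gates


def _channel_currents(tpl: CellTemplate, v, gates, G, b):
    """Accumulate ionic conductance and driving terms into G, b (in place)."""
    for ch, idx in tpl.chan_idx.items():
        gmax = tpl.g_abs[ch][idx][:, None]
        if ch == "leak":
            op = 1.0
        else:
            op = chn.OPEN_FRACTION[ch]({g: gates[(ch, g)] for g in chn.GATE_NAMES[ch]})
        gg = gmax * op
        G[idx] += gg
        b[idx] += gg * tpl.membrane.e_rev[ch]


def _axial_apply(tpl: CellTemplate, x: np.ndarray) -> np.ndarray:
    """y = A x where A is the axial coupling operator (net axial current into
    each compartment for intracellular potential x)."""
    y = np.zeros_like(x)
    par = tpl.parent
    d = tpl.g_c[1:, None] * (x[par[1:]] - x[1:])
    y[1:] += d
    np.add.at(y, par[1:], -d)
    return y


def _integrate(tpl: CellTemplate, v, gates, duration, dt, stimuli: Stimuli,
               record: bool = True, record_dt: float = DT_OUTPUT, theta: float = 0.5,
               chr2_state: ChR2PopulationState = None):
    n, nc = v.shape
    n_steps = int(round(duration / dt))
    rec_every = max(int(round(record_dt / dt)), 1)
    celsius = tpl.membrane.celsius
    q10g = tpl.membrane.q10_gates
    cm_dt = tpl.cm_nF[:, None] / dt
    thg = theta * tpl.g_c
    par = tpl.parent

    opt = stimuli.optical
    if opt is not None and chr2_state is None:
        comps = opt.comps if opt.comps is not None else tpl.chr2_compartments()
        chr2_state = ChR2PopulationState(opt.params, comps, nc, tpl.area_cm2[comps])

    frames, va_frames, im_frames, t_frames = [], [], [], []

    def _record(t_now, ve_now):
        x = v + ve_now
        d = np.zeros_like(v)
        d[1:] = tpl.g_c[1:, None] * (x[par[1:]] - x[1:])
        i_m = _axial_apply(tpl, x)
        i_inj = np.zeros_like(v)
        for cp in stimuli.current:
            if cp.active(t_now):
                i_inj[cp.comps] += np.asarray(cp.amplitude)
        i_m += i_inj
        frames.append(v.copy())
        va_frames.append(d)
        im_frames.append(i_m)
        t_frames.append(t_now)

    ve_zero = 0.0
    if record and n_steps >= 0:
        ve0 = (stimuli.extracellular.pattern * stimuli.extracellular.gate(0.0)
               if stimuli.extracellular is not None else np.zeros_like(v))
        _record(0.0, ve0)

    # stagger the gates half a step ahead of the voltage grid, so the
    # conductances used by each theta-step are centred in its interval
    for (ch, g), val in gates.items():
        idx = tpl.chan_idx[ch]
        inf, tau = chn.gate_dynamics(v[idx], ch, g, celsius, q10g)
        gates[(ch, g)] = inf + (val - inf) * np.exp(-0.5 * dt / tau)

    for k in range(n_steps):
        t = k * dt
        tmid = t + 0.5 * dt

        G = np.zeros_like(v)
        b = np.zeros_like(v)
        _channel_currents(tpl, v, gates, G, b)

        for cp in stimuli.current:
            if cp.active(tmid):
                b[cp.comps] += np.asarray(cp.amplitude)

        ve = None
        if stimuli.extracellular is not None:
            gate = stimuli.extracellular.gate(tmid)
            if gate != 0.0:
                ve = stimuli.extracellular.pattern * gate
                b += _axial_apply(tpl, ve)

        if chr2_state is not None:
            light = opt.light_on(tmid)
            i_chr2 = chr2_state.step(dt, v[chr2_state.comps], opt.irradiance, light)
            b[chr2_state.comps] -= i_chr2

        if stimuli.synaptic is not None:
            sy = stimuli.synaptic
            gs = sy.g[min(k, len(sy.g) - 1)]
            G[sy.comps] += sy.weights[:, None] * gs[None, :]
            # e_rev = 0 contributes no driving term unless nonzero
            if sy.e_rev != 0.0:
                b[sy.comps] += sy.weights[:, None] * gs[None, :] * sy.e_rev

        # theta-method linear solve: (C/dt + θ(G - A)) v_new =
        #   (C/dt - (1-θ)(G - A)) v_old + b
        Av = _axial_apply(tpl, v)
        rhs = cm_dt * v - (1.0 - theta) * (G * v - Av) + b
        diag = cm_dt + theta * (G + tpl.cpl_diag[:, None])

        # Hines elimination (parents precede children)
        for i in range(n - 1, 0, -1):
            p = par[i]
            f = thg[i] / diag[i]
            diag[p] = diag[p] - f * thg[i]
            rhs[p] = rhs[p] + f * rhs[i]
        v_new = np.empty_like(v)
        v_new[0] = rhs[0] / diag[0]
        for i in range(1, n):
            v_new[i] = (rhs[i] + thg[i] * v_new[par[i]]) / diag[i]
        v = v_new

        if not np.all(np.isfinite(v[0])):
            raise FloatingPointError(f"cable solve diverged at t = {t + dt:.3f} ms")

        # gate update (exponential Euler over [t+dt/2, t+3dt/2] using the new V)
        for (ch, g), val in gates.items():
            idx = tpl.chan_idx[ch]
            inf, tau = chn.gate_dynamics(v[idx], ch, g, celsius, q10g)
            gates[(ch, g)] = inf + (val - inf) * np.exp(-dt / tau)

        if record and (k + 1) % rec_every == 0:
            t_now = (k + 1) * dt
            ve_now = (stimuli.extracellular.pattern * stimuli.extracellular.gate(t_now)
                      if stimuli.extracellular is not None else ve_zero)
            _record(t_now, ve_now)

    if record:
        return StateTrace(
            t=np.asarray(t_frames),
            v=np.stack(frames) if frames else np.zeros((0, n, nc)),
            i_axial=np.stack(va_frames) if va_frames else np.zeros((0, n, nc), np.float32),
            i_m=np.stack(im_frames) if im_frames else np.zeros((0, n, nc), np.float32),
            template=tpl,
        )
    return v, gates


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def run_simulation(template: CellTemplate, stimuli: Stimuli = None,
                   duration: float = 10.0, n_cells: int = 1,
                   dt: float = DT_INTERNAL, record_dt: float = DT_OUTPUT,
                   theta: float = 0.5) -> StateTrace:
    """Integrate a population of ``n_cells`` electrically identical cells.

    Returns a :class:`StateTrace` sampled at ``record_dt`` (25 μs by default)
    regardless of the internal step.  A zero-length protocol yields an empty
    trace."""
    stimuli = stimuli or Stimuli()
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if duration == 0:
        z = np.zeros((0, template.n, n_cells))
        return StateTrace(t=np.zeros(0), v=z, i_axial=z.copy(), i_m=z.copy(),
                          template=template)
    v0, gates0 = template.resting_state()
    v = np.repeat(v0[:, None], n_cells, axis=1)
    gates = {}
    for key, g in gates0.items():
        gates[key] = np.repeat(g[:, None], n_cells, axis=1)
    return _integrate(template, v, gates, duration, dt, stimuli,
                      record=True, record_dt=record_dt, theta=theta)


def detect_spikes(trace: StateTrace, comp: int, cell: int = 0,
                  threshold: float = -20.0, refractory: float = 1.0) -> np.ndarray:
    """Upward threshold-crossing times (ms, linearly interpolated) at one
    compartment of one cell, with a refractory lockout."""
    v = np.asarray(trace.v[:, comp, cell], dtype=float)
    t = trace.t
    if len(v) < 2:
        return np.zeros(0)
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.flatnonzero(below & above)
    times = []
    last = -np.inf
    for k in idx:
        frac = (threshold - v[k]) / (v[k + 1] - v[k])
        tc = t[k] + frac * (t[k + 1] - t[k])
        if tc - last >= refractory:
            times.append(tc)
            last = tc
    return np.asarray(times)


def detect_spikes_population(trace: StateTrace, comp: int,
                             threshold: float = -20.0,
                             refractory: float = 1.0) -> list:
    """First-pass spike detection for every cell at one compartment; returns a
    list of per-cell spike-time arrays."""
    return [detect_spikes(trace, comp, c, threshold, refractory)
            for c in range(trace.n_cells)]
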