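"""Calyx of Held synaptic transmission.

Release model: 500 independent active zones, each holding at most one readily
releasable vesicle.  A presynaptic action potential triggers a fast (1 ms)
and a slow/residual (2 ms) calcium transient.  The fast transient opens the
fast gate briefly; the slow gate opens partially and decays slowly, so that
a closely following AP sees an elevated slow-gate level — the source of
paired-pulse facilitation.  The release probability of an occupied zone is
the product of the fast- and slow-gate open fractions.  Released zones empty
and refill through a constant background replenishment plus an enhanced,
residual-calcium-driven component, so sustained trains deplete the pool and
the EPSC train depresses after its initial facilitation.

Receptor model: a 6-state AMPA gating scheme (three closed states, fast and
slow open states, one desensitized state).  Each released vesicle produces a
1 ms square transmitter pulse driving its zone's receptor patch; the somatic
EPSC is the sum over zones.  Receptor patches engaged by different release
events are treated as independent (zone re-release within the receptor
desensitization recovery time is rare under the pool dynamics).

Release defaults are calibrated to the printed behavioural anchors (single
EPSC > 1 nA at −70 mV holding, ~0.6-0.7 ms calyx-to-soma delay, initial
facilitation followed by depression at 100-200 Hz); all rates overridable.
The deterministic mode propagates expected values and is the default;
stochastic mode draws seeded binomial release/refill counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# vesicle release
# ---------------------------------------------------------------------------

@dataclass
class ReleaseParams:
    n_zones: int = 500
    p_fast: float = 0.5         # peak open fraction of the fast gate per AP
    a_slow: float = 0.35        # slow-gate increment per AP (toward 1)
    tau_slow: float = 15.0      # slow-gate decay, ms
    ca_fast_ms: float = 1.0     # fast calcium transient duration
    ca_slow_ms: float = 2.0     # slow/residual calcium transient duration
    k_bg: float = 0.002         # background replenishment rate, ms⁻¹
    k_ca: float = 0.05          # extra replenishment during the slow transient, ms⁻¹
    delay: float = 0.35         # AP-to-release latency, ms
    ca_scale: float = 1.0       # extracellular-Ca multiplier on gate amplitudes

    def single_ap_release_probability(self) -> float:
        """Release probability of an occupied zone for an isolated AP."""
        return min(self.p_fast * self.ca_scale, 1.0) * min(self.a_slow * self.ca_scale, 1.0)


class ReleaseState:
    """Event-driven release dynamics (see module docstring).

    ``mode`` is 'deterministic' (expected values; reproducible) or
    'stochastic' (seeded binomial draws)."""

    def __init__(self, params: ReleaseParams = None, mode: str = "deterministic",
                 rng: np.random.Generator = None):
        self.p = params or ReleaseParams()
        if mode not in ("deterministic", "stochastic"):
            raise ValueError("mode must be 'deterministic' or 'stochastic'")
        self.mode = mode
        self.rng = rng or np.random.default_rng(0)
        self.reset()

    def reset(self):
        self.occupancy = 1.0            # mean occupied fraction (or count/n in stochastic)
        self._n_occ = self.p.n_zones
        self.slow_gate = 0.0
        self._t_last = -np.inf

    def _replenish(self, dt: float):
        p = self.p
        if dt <= 0:
            return
        # enhanced replenishment while the residual transient of the previous
        # AP is active, background afterwards
        t_ca = min(dt, p.ca_slow_ms)
        for span, k in ((t_ca, p.k_bg + p.k_ca), (dt - t_ca, p.k_bg)):
            if span <= 0:
                continue
            fill = 1.0 - np.exp(-k * span)
            if self.mode == "deterministic":
                self.occupancy += (1.0 - self.occupancy) * fill
            else:
                n_empty = self.p.n_zones - self._n_occ
                self._n_occ += self.rng.binomial(n_empty, fill)
                self.occupancy = self._n_occ / self.p.n_zones

    def on_presynaptic_spike(self, t: float):
        """Process an AP arriving at time ``t`` (ms); returns the number of
        released vesicles (float in deterministic mode) and the release time
        ``t + delay``."""
        p = self.p
        self._replenish(t - self._t_last if np.isfinite(self._t_last) else 1e9)
        self.slow_gate *= np.exp(-(t - self._t_last) / p.tau_slow) if np.isfinite(self._t_last) else 0.0
        a_s = min(p.a_slow * p.ca_scale, 1.0)
        self.slow_gate += a_s * (1.0 - self.slow_gate)
        p_rel = min(p.p_fast * p.ca_scale, 1.0) * self.slow_gate
        p_rel = min(max(p_rel, 0.0), 1.0)
        if self.mode == "deterministic":
            released = self.occupancy * p.n_zones * p_rel
            self.occupancy *= 1.0 - p_rel
        else:
            released = self.rng.binomial(self._n_occ, p_rel)
            self._n_occ -= int(released)
            self.occupancy = self._n_occ / self.p.n_zones
        self._t_last = t
        return released, t + p.delay


# ---------------------------------------------------------------------------
# AMPA receptor (6-state)
# ---------------------------------------------------------------------------

STATE_NAMES = ("C0", "C1", "C2", "O_fast", "O_slow", "D")


@dataclass
class AMPAParams:
    # binding (per ms, at the 1 mM-equivalent transmitter pulse)
    k_on1: float = 30.0         # C0 -> C1
    k_off1: float = 3.0         # C1 -> C0
    k_on2: float = 21.0         # C1 -> C2
    k_off2: float = 6.0         # C2 -> C1
    beta_f: float = 20.0        # C2 -> O_fast
    alpha_f: float = 3.0        # O_fast -> C2
    beta_s: float = 2.0         # C2 -> O_slow
    alpha_s: float = 0.5        # O_slow -> C2
    delta_f: float = 1.2        # O_fast -> D
    delta_s: float = 0.2        # O_slow -> D
    rec: float = 0.02           # D -> C2 recovery
    transmitter_ms: float = 1.0
    g_zone: float = 2.6e-4      # peak conductance per release (μS) at full opening
    e_rev: float = 0.0          # mV (excitatory)

    def rate_matrix(self, t_on: bool) -> np.ndarray:
        b = 1.0 if t_on else 0.0
        k = np.zeros((6, 6))

        def add(i, j, rate):     # j -> i
            k[i, j] += rate
            k[j, j] -= rate

        add(1, 0, self.k_on1 * b)
        add(0, 1, self.k_off1)
        add(2, 1, self.k_on2 * b)
        add(1, 2, self.k_off2)
        add(3, 2, self.beta_f)
        add(2, 3, self.alpha_f)
        add(4, 2, self.beta_s)
        add(2, 4, self.alpha_s)
        add(5, 3, self.delta_f)
        add(5, 4, self.delta_s)
        add(2, 5, self.rec)
        return k


class AMPAState:
    """Occupancy vector of the 6-state scheme; first-order kinetic update."""

    def __init__(self, params: AMPAParams = None):
        self.p = params or AMPAParams()
        self.occ = np.zeros(6)
        self.occ[0] = 1.0
        self._m = {True: self.p.rate_matrix(True), False: self.p.rate_matrix(False)}

    def step(self, dt: float, transmitter_on: bool):
        self.occ = self.occ + dt * (self._m[bool(transmitter_on)] @ self.occ)
        if abs(self.occ.sum() - 1.0) > 1e-9:
            raise FloatingPointError("AMPA occupancy drift exceeds tolerance")
        return self.occ

    @property
    def open_fraction(self) -> float:
        return float(self.occ[3] + self.occ[4])

    def current(self, v: float) -> float:
        """I_syn (nA) for this patch at membrane potential v."""
        return self.p.g_zone * self.open_fraction * (v - self.p.e_rev)


def ampa_kernel(params: AMPAParams = None, dt: float = 0.005,
                duration: float = 25.0) -> np.ndarray:
    """Open-fraction time course of one receptor patch responding to a single
    1 ms transmitter pulse starting at t = 0 (sampled at ``dt``)."""
    p = params or AMPAParams()
    st = AMPAState(p)
    n = int(round(duration / dt))
    out = np.empty(n)
    for k in range(n):
        st.step(dt, k * dt < p.transmitter_ms)
        out[k] = st.open_fraction
    return out


# ---------------------------------------------------------------------------
# population conductance and EPSC assembly
# ---------------------------------------------------------------------------

def synaptic_conductance(ap_times: list, duration: float, dt: float = 0.005,
                         release: ReleaseParams = None, ampa: AMPAParams = None,
                         mode: str = "deterministic", seed: int = 0) -> np.ndarray:
    """Total synaptic conductance (μS) per time step for every cell.

    ``ap_times`` is a list (one entry per cell) of presynaptic (calyceal) AP
    time arrays.  Returns g of shape (n_steps, n_cells): superposition of the
    per-event AMPA kernels scaled by the number of released vesicles."""
    release = release or ReleaseParams()
    ampa = ampa or AMPAParams()
    n_steps = int(round(duration / dt))
    kern = ampa_kernel(ampa, dt=dt) * ampa.g_zone
    g = np.zeros((n_steps, len(ap_times)))
    rng = np.random.default_rng(seed)
    for c, times in enumerate(ap_times):
        state = ReleaseState(release, mode=mode, rng=np.random.default_rng(rng.integers(2**31)))
        for t_ap in np.sort(np.asarray(times, dtype=float)):
            n_rel, t_rel = state.on_presynaptic_spike(t_ap)
            if n_rel <= 0:
                continue
            k0 = int(round(t_rel / dt))
            if k0 >= n_steps:
                continue
            k1 = min(k0 + len(kern), n_steps)
            g[k0:k1, c] += n_rel * kern[: k1 - k0]
    return g


def epsc_trace(g: np.ndarray, v_hold: float = -70.0, e_rev: float = 0.0) -> np.ndarray:
    """EPSC (nA) under an ideal somatic voltage clamp at ``v_hold``."""
    return g * (v_hold - e_rev)
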