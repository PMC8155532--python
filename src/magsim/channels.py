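"""Hodgkin-Huxley-style channel kinetics for the GBC-MNTB pathway.

The channel complement follows the published auditory-brainstem models for
VCN bushy cells and MNTB principal neurons: fast inactivating Na+, low- and
high-threshold K+ (KLT / KHT), hyperpolarization-activated cation current
(Ih), a passive leak, and a voltage-gated Ca conductance at the calyx of
Held.  Steady-state activations and time constants are expressed at 22 °C
and Q10-scaled to the simulation temperature (default 34 °C): gate time
constants are divided by q10_gates^((T-22)/10), peak conductances multiplied
by q10_cond^((T-22)/10).

Every rate and density is configurable, so alternative published tables can
be dropped in verbatim.
"""

from __future__ import annotations

import numpy as np

RATES_REF_CELSIUS = 22.0
Q10_GATES = 3.0
Q10_COND = 2.0


def _exp(x):
    return np.exp(np.clip(x, -500.0, 500.0))


# --- gate steady states and time constants (ms, at 22 °C) -------------------

def _na_m_inf(v):  return 1.0 / (1.0 + _exp(-(v + 38.0) / 7.0))
def _na_m_tau(v):  return 10.0 / (5.0 * _exp((v + 60.0) / 18.0) + 36.0 * _exp(-(v + 60.0) / 25.0)) + 0.04
def _na_h_inf(v):  return 1.0 / (1.0 + _exp((v + 65.0) / 6.0))
def _na_h_tau(v):  return 100.0 / (7.0 * _exp((v + 60.0) / 11.0) + 10.0 * _exp(-(v + 60.0) / 25.0)) + 0.6

def _klt_w_inf(v): return (1.0 + _exp(-(v + 48.0) / 6.0)) ** -0.25
def _klt_w_tau(v): return 100.0 / (6.0 * _exp((v + 60.0) / 6.0) + 16.0 * _exp(-(v + 60.0) / 45.0)) + 1.5
def _klt_z_inf(v): return 0.5 + 0.5 / (1.0 + _exp((v + 71.0) / 10.0))
def _klt_z_tau(v): return 1000.0 / (_exp((v + 60.0) / 20.0) + _exp(-(v + 60.0) / 8.0)) + 50.0

def _kht_n_inf(v): return (1.0 + _exp(-(v + 15.0) / 5.0)) ** -0.5
def _kht_n_tau(v): return 100.0 / (11.0 * _exp((v + 60.0) / 24.0) + 21.0 * _exp(-(v + 60.0) / 23.0)) + 0.7
def _kht_p_inf(v): return 1.0 / (1.0 + _exp(-(v + 23.0) / 6.0))
def _kht_p_tau(v): return 100.0 / (4.0 * _exp((v + 60.0) / 32.0) + 5.0 * _exp(-(v + 60.0) / 22.0)) + 5.0

def _ih_r_inf(v):  return 1.0 / (1.0 + _exp((v + 76.0) / 7.0))
def _ih_r_tau(v):  return 1e5 / (237.0 * _exp((v + 60.0) / 12.0) + 17.0 * _exp(-(v + 60.0) / 14.0)) + 25.0

# MNTB principal-cell sodium: same functional form with the activation curve
# shifted 10 mV hyperpolarized, giving the low spike threshold needed for
# single-AP responses to brief calyceal inputs
_NA_MNTB_SHIFT = 10.0
def _nam_m_inf(v): return _na_m_inf(np.asarray(v) + _NA_MNTB_SHIFT)
def _nam_m_tau(v): return _na_m_tau(np.asarray(v) + _NA_MNTB_SHIFT)

# calyx P/Q-type calcium conductance (fast activating, non-inactivating)
def _ca_m_inf(v):  return 1.0 / (1.0 + _exp(-(v + 20.0) / 9.0))
def _ca_m_tau(v):  return 1.5 / (_exp((v + 20.0) / 15.0) + _exp(-(v + 20.0) / 15.0)) + 0.15


# registry: channel -> gate -> (inf, tau)
GATES = {
    "na": {"m": (_na_m_inf, _na_m_tau), "h": (_na_h_inf, _na_h_tau)},
    "na_mntb": {"m": (_nam_m_inf, _nam_m_tau), "h": (_na_h_inf, _na_h_tau)},
    "klt": {"w": (_klt_w_inf, _klt_w_tau), "z": (_klt_z_inf, _klt_z_tau)},
    "kht": {"n": (_kht_n_inf, _kht_n_tau), "p": (_kht_p_inf, _kht_p_tau)},
    "ih": {"r": (_ih_r_inf, _ih_r_tau)},
    "ca": {"m": (_ca_m_inf, _ca_m_tau)},
}

# open fraction of each channel as a function of its gate values
OPEN_FRACTION = {
    "na": lambda g: g["m"] ** 3 * g["h"],
    "na_mntb": lambda g: g["m"] ** 3 * g["h"],
    "klt": lambda g: g["w"] ** 4 * g["z"],
    "kht": lambda g: 0.85 * g["n"] ** 2 + 0.15 * g["p"],
    "ih": lambda g: g["r"],
    "ca": lambda g: g["m"] ** 2,
    "leak": lambda g: 1.0,
}

GATE_NAMES = {ch: tuple(d.keys()) for ch, d in GATES.items()}


def q10_tau_factor(celsius: float, q10: float = Q10_GATES) -> float:
    """Factor by which gate time constants shrink at ``celsius``."""
    return q10 ** ((celsius - RATES_REF_CELSIUS) / 10.0)


def gate_dynamics(v, channel: str, gate: str, celsius: float = 34.0,
                  q10: float = Q10_GATES):
    """Steady state (dimensionless) and time constant (ms, Q10-scaled to
    ``celsius``) of one gating variable at membrane potential ``v`` (mV)."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    try:
        inf_fn, tau_fn = GATES[channel][gate]
    except KeyError:
        raise KeyError(f"unknown channel/gate: {channel}/{gate}") from None
    return inf_fn(v), tau_fn(v) / q10_tau_factor(celsius, q10)


def steady_gates(v, channels, celsius: float = 34.0) -> dict:
    """Steady-state gate values for every gate of ``channels`` at ``v``."""
    out = {}
    for ch in channels:
        if ch == "leak":
            continue
        for g in GATE_NAMES[ch]:
            out[(ch, g)] = gate_dynamics(v, ch, g, celsius)[0]
    return out
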