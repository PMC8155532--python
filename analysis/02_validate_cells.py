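"""Single-cell and synapse validation against the published physiology.

Checks, on morphologically standard single cells: resting stability, axonal
conduction velocity (target 5-10 m/s), reliable following of 100/200 Hz
somatic pulse trains (GBC: 20 nA / 0.25 ms; principal cell: 0.5 nA), and
calyx transmission (EPSC amplitude > 1 nA under a -70 mV clamp, ~0.6-0.7 ms
calyx-to-soma delay, paired-pulse facilitation followed by train depression).
Writes results/cell_validation.csv.
"""

import os

import numpy as np
import pandas as pd

from magsim.cable import (CellTemplate, CurrentPulse, Stimuli, detect_spikes,
                          run_simulation)
from magsim.morphology import build_gbc, build_mntb
from magsim.synapse import epsc_trace, synaptic_conductance

rows = []
gbc = CellTemplate(build_gbc())
mntb = CellTemplate(build_mntb(rng=np.random.default_rng(1)))

# conduction velocity between the 1st and 16th node of Ranvier
stim = Stimuli(current=[CurrentPulse(gbc.indices("soma"), 20.0, 0.5, 0.25)])
tr = run_simulation(gbc, stim, duration=4.0)
n1 = detect_spikes(tr, gbc.node_from_is(1))
n16 = detect_spikes(tr, gbc.node_from_is(16))
dist_um = 200.0 * 8 + 180 + 150 + 120 + 95 + 75 + 60 + 50 + 15
cv = dist_um * 1e-3 / (n16[0] - n1[0])
v7 = tr.v[:, gbc.node_from_is(7), 0]
rows.append(("gbc_conduction_velocity_m_per_s", cv))
rows.append(("gbc_node7_ap_amplitude_mV", float(v7.max() - v7[0])))

for name, tpl, amp, det in (
    ("gbc", gbc, 20.0, gbc.node_from_is(7)),
    ("mntb", mntb, 0.5, int(mntb.indices("mntb_node")[-1])),
):
    for hz in (100, 200):
        stim = Stimuli(current=[CurrentPulse(tpl.indices("soma" if name == "gbc" else "mntb_soma"),
                                             amp, 1.0, 0.25, period=1000.0 / hz, n_pulses=5)])
        tr = run_simulation(tpl, stim, duration=1.0 + 5000.0 / hz)
        rows.append((f"{name}_spikes_per_5_pulses_{hz}Hz", len(detect_spikes(tr, det))))

# synaptic transmission (ideal -70 mV clamp)
g = synaptic_conductance([np.array([1.0])], 20.0)
i = epsc_trace(g[:, 0])
t = np.arange(len(i)) * 0.005
rows.append(("epsc_peak_nA", float(-i.min())))
rows.append(("ap_to_epsc_peak_delay_ms", float(t[np.argmin(i)] - 1.0)))
g2 = synaptic_conductance([np.array([1.0, 6.0])], 30.0)
i2 = epsc_trace(g2[:, 0])
t2 = np.arange(len(i2)) * 0.005
a1 = -(i2[(t2 >= 1.0) & (t2 < 6.0)]).min()
a2 = -(i2[(t2 >= 6.0) & (t2 < 11.0)]).min()
rows.append(("paired_pulse_ratio_5ms", float(a2 / a1)))
aps = np.arange(20) * 10.0 + 1.0
g3 = synaptic_conductance([aps], 230.0)
i3 = epsc_trace(g3[:, 0])
t3 = np.arange(len(i3)) * 0.005
peaks = np.array([-(i3[(t3 >= ta) & (t3 < ta + 9.9)]).min() for ta in aps])
rows.append(("train_100Hz_peak2_over_peak1", float(peaks[1] / peaks[0])))
rows.append(("train_100Hz_steadystate_over_peak1", float(peaks[-1] / peaks[0])))

df = pd.DataFrame(rows, columns=["quantity", "value"])
os.makedirs("results", exist_ok=True)
df.to_csv("results/cell_validation.csv", index=False)
print(df.to_string(index=False))
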