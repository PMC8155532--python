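"""Optothermal heating of the illuminated tissue.

Monte-Carlo light transport (worst case, as it predicts the highest
near-probe irradiance) provides the absorbed-power source for the explicit
finite-difference bioheat solver.  Continuous and pulsed (3 ms at 20 Hz)
protocols at 1 W/mm² source irradiance are simulated, plus the 4 W/mm² /
40 Hz worst case.  Writes results/heating.csv.
"""

import argparse
import os

import numpy as np
import pandas as pd

from magsim.optostim import LightSource, OpticalTissue, VoxelGrid, mc_irradiance
from magsim.thermal import (PulseProtocol, ThermalParams, fiber_source_grid,
                            solve_bioheat)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n-photons", type=int, default=200_000)
parser.add_argument("--t-end", type=float, default=12.0)
args = parser.parse_args()

src = LightSource(irradiance=1.0, position=(0.0, 0.0, 1500.0), direction=(0, 0, -1))
grid = VoxelGrid(origin=(-1000.0, -1000.0, -250.0), shape=(50, 50, 50), spacing=40.0)
field = mc_irradiance(src, OpticalTissue(), n_photons=args.n_photons,
                      seed=args.seed, grid=grid)
power = 1.0 * np.pi * (src.diameter / 2 * 1e-3) ** 2      # W at 1 W/mm²
p_coarse = ThermalParams(dx=0.06)              # continuous: smooth in time
p_fine = ThermalParams(dx=0.035)               # pulsed: resolve the 3 ms pulses
src_coarse = fiber_source_grid(field, p_coarse, extent_mm=3.6) * power
src_fine = fiber_source_grid(field, p_fine, extent_mm=2.45) * power

rows = []
for label, scale, proto, params, source, dt in (
    ("continuous_1W", 1.0, PulseProtocol(), p_coarse, src_coarse, None),
    ("pulsed_1W_3ms_20Hz", 1.0, PulseProtocol(3.0, 20.0), p_fine, src_fine, 1e-3),
    ("pulsed_4W_3ms_40Hz", 4.0, PulseProtocol(3.0, 40.0), p_fine, src_fine, 1e-3),
):
    r = solve_bioheat(scale * source, params, proto, t_end=args.t_end, dt=dt)
    rows.append((label, r.max_dT[-1], proto.duty_cycle))
    print(f"{label}: max dT = {r.max_dT[-1]:.2f} °C (duty {proto.duty_cycle:.3f})")

pd.DataFrame(rows, columns=["protocol", "max_dT_C", "duty_cycle"]
             ).to_csv("results/heating.csv", index=False)
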