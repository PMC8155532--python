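"""Firing fidelity under repetitive light stimulation.

For the calyx and the MNTB soma, 3 ms light pulses at 3× the single-pulse
threshold are repeated at 10-60 Hz over a 200 ms train, and the fraction of
pulses answered with a spike is reported (the calyx follows reliably up to
a few tens of Hz, the GBC soma is less stable).  Writes
results/train_fidelity.csv.
"""

import os

import numpy as np
import pandas as pd

from magsim.cable import CellTemplate
from magsim.experiments import run_train_experiment
from magsim.morphology import build_gbc, build_mntb

gbc = CellTemplate(build_gbc())
mntb = CellTemplate(build_mntb(rng=np.random.default_rng(1)))

rows = []
for target, tpl in (("calyx", gbc), ("gbc_soma", gbc), ("mntb_soma", mntb)):
    out = run_train_experiment(tpl, target, rates=(10, 20, 30, 40, 60),
                               train_ms=200.0, irradiance_multiplier=3.0)
    for rate, fid in zip(out["rates"], out["fidelity"]):
        rows.append((target, rate, fid))
    print(target, dict(zip(out["rates"], np.round(out["fidelity"], 2))))

pd.DataFrame(rows, columns=["target", "rate_Hz", "fidelity"]
             ).to_csv("results/train_fidelity.csv", index=False)
os.makedirs("results", exist_ok=True)
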