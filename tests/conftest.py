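import numpy as np
import pytest

from magsim.cable import CellTemplate
from magsim.morphology import build_gbc, build_mntb
from magsim.slice_builder import build_slice


@pytest.fixture(scope="session")
def gbc_template():
    tpl = CellTemplate(build_gbc())
    tpl.resting_state()
    return tpl


@pytest.fixture(scope="session")
def mntb_template():
    tpl = CellTemplate(build_mntb(rng=np.random.default_rng(1)))
    tpl.resting_state()
    return tpl


@pytest.fixture(scope="session")
def small_slice():
    return build_slice(n_cells=6, seed=3)
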