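import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from thromboprofile import hydro, synth


@pytest.fixture
def stenosis_geometry():
    """The study's channel: 200 x 50 µm, 80% stenosis."""
    return hydro.build_geometry(200.0, 50.0, 0.8)


@pytest.fixture
def default_flow():
    """18 µL/min, 1.0 mPa·s, whole-blood density."""
    return hydro.FlowCondition()


@pytest.fixture
def default_design():
    return synth.StudyDesign()


@pytest.fixture
def noiseless_design():
    return synth.StudyDesign(baseline_cv=(0.0,) * 7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
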