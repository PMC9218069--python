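import math

import numpy as np
import pytest

from chronicsense.core_model import Recording, Channel, BipolarPair, StimSetting, build_lead
from chronicsense.synthetic_cohort import GeneratorParams, generate_lfp, generate_stim_session


@pytest.fixture(scope="session")
def ring_lead():
    return build_lead("3389")


@pytest.fixture(scope="session")
def directional_lead():
    return build_lead("1-3-3-1")


@pytest.fixture
def theta_params():
    return GeneratorParams(seed=42, state_dwell={"theta": math.inf})


@pytest.fixture(scope="session")
def ep_setting():
    return StimSetting("E1", "E2", 5.0, "V", 5.0, 120.0, 30.0)


@pytest.fixture(scope="session")
def ep_session(ep_setting):
    params = GeneratorParams(seed=7, state_dwell={"theta": math.inf})
    rec, events = generate_stim_session(params, ep_setting, "ep_train")
    return rec, events


def make_recording(x, fs=250.0, label=("HC", "E0", "E3")):
    """Single-channel recording around a raw sample vector."""
    lead, a, b = label
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return Recording(fs=fs, channels=[Channel(lead, BipolarPair(a, b))], samples=x)


@pytest.fixture
def tone_recording():
    fs = 250.0
    t = np.arange(int(30 * fs)) / fs
    return make_recording(20.0 * np.sin(2 * np.pi * 4.5 * t), fs)
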