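import numpy as np
import pytest

from nanotransloc import Electrolyte, PoreSystem, get_fixture


@pytest.fixture(scope="session")
def ahl_system():
    """alpha-Hemolysin pore with ss-DNA at 0.04 M salt (image barrier)."""
    system, barrier = get_fixture("fig6").build()
    assert barrier == "image"
    return system


@pytest.fixture(scope="session")
def solid_state_system():
    """Solid-state pore, pressure-voltage trapping setup (mean-field barrier)."""
    system, barrier = get_fixture("fig2").build()
    assert barrier == "mf"
    return system


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


def make_system(**kw):
    """Small helper to build ad-hoc pore systems in tests."""
    defaults = dict(a=1.0, d=4.0, Lm=20.0, Lp=30.0, sigma_p=0.2,
                    sigma_m=0.1, delta_V=0.05, delta_P=0.0,
                    electrolyte=Electrolyte.monovalent(0.2))
    defaults.update(kw)
    return PoreSystem(**defaults)
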