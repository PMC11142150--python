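import numpy as np
import pytest

import actoflow as af


def make_params(L=20.0, n=2001, x_cz=10.0, sigma=1.0, amplitude=10.0,
                xi_left=1000.0, xi_right=1000.0, mu=1000.0, smooth=0.0):
    return af.ModelParams(
        domain=af.CellDomain(L, n),
        motors=af.MotorField(amplitude=amplitude, sigma=sigma, x_cz=x_cz),
        adhesion=af.AdhesionField(xi_left, xi_right, smooth_width=smooth),
        mu=mu,
    )


@pytest.fixture(scope="session")
def symmetric_params():
    """Symmetric cell, lambda = 2 (uniform adhesion, centred CZ)."""
    return make_params()


@pytest.fixture(scope="session")
def symmetric_profile(symmetric_params):
    return af.solve_flow(symmetric_params)


@pytest.fixture(scope="session")
def preset_profiles():
    """Noiseless forward solutions for all five motility presets."""
    out = {}
    for name in af.synthetic.PRESET_NAMES:
        preset = af.get_preset(name)
        out[name] = (preset, af.generate_profile(preset))
    return out
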