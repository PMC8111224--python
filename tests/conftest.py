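import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import costark as ck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def default_scenario() -> ck.TitrationScenario:
    """The reference synthetic titration: two CO bands, midpoints 102/237 mV."""
    return ck.TitrationScenario(rng_seed=2021)


@pytest.fixture
def noiseless_scenario(default_scenario) -> ck.TitrationScenario:
    return default_scenario.noiseless()


@pytest.fixture
def clean_scenario(noiseless_scenario) -> ck.TitrationScenario:
    """Noise off and no baseline drift: the exact linear band model."""
    from dataclasses import replace
    return replace(noiseless_scenario, baseline=(0.0, 300.0))


@pytest.fixture
def band_seeds() -> list:
    """Deliberately offset initial guesses for the two CO bands."""
    return [ck.PseudoVoigtBand(1963.0, 4.0, 0.2), ck.PseudoVoigtBand(1968.0, 4.0, 0.2)]


@pytest.fixture
def linear_probe() -> ck.ProbeGeometry:
    """Idealized Fe-C-O probe along +z with Fe at the origin."""
    return ck.default_probe("idealized_linear")


@pytest.fixture
def bent_probe() -> ck.ProbeGeometry:
    return ck.default_probe("bent")


def naive_coulomb_field(positions, charges, point, eps_r):
    """Independent double-loop evaluation of the point-charge field (MV/cm)."""
    E = np.zeros(3)
    for pos, q in zip(positions, charges):
        r = np.asarray(point, dtype=float) - np.asarray(pos, dtype=float)
        d = np.sqrt(float(r @ r))
        E += 1439.964 / eps_r * q * r / d**3
    return E
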