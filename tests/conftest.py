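import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from karstmethane import IncubationConfig, TrueState
from karstmethane.isotopes import atom_fraction
from karstmethane.simulate import BottleSpec, simulate_microcosm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

NAT_CH4 = atom_fraction(-40.0)  # unlabeled tank CH4


@pytest.fixture(scope="session")
def truth():
    return TrueState()


@pytest.fixture(scope="session")
def noiseless_cfg():
    return IncubationConfig(measurement_cv=0.0, delta_sd=0.0, seed=7)


def run_pair(target_ppm, truth, cfg):
    """Simulate a labeled bottle and its unlabeled counterpart."""
    lab = BottleSpec(f"13C-{target_ppm:g}ppm", 1, target_ppm,
                     cfg.label_atom_fraction)
    unl = BottleSpec(f"12C-{target_ppm:g}ppm", 1, target_ppm, NAT_CH4)
    sl, el = simulate_microcosm(lab, truth, cfg)
    su, eu = simulate_microcosm(unl, truth, cfg)
    return (sl, el), (su, eu)


@pytest.fixture(scope="session")
def pair_500(truth, noiseless_cfg):
    return run_pair(500.0, truth, noiseless_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
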