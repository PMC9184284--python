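import dataclasses

import pytest

from nsm.geometry import get_channel
from nsm.hydro import HydroContext
from nsm.optics import OpticalModel
from nsm.simulate import SimulationPlan, SpeciesSpec, simulate_experiment


@pytest.fixture(scope="session")
def channel_I():
    return get_channel("I")


@pytest.fixture(scope="session")
def ctx_I(channel_I):
    return dataclasses.replace(
        HydroContext(), equivalent_radius_nm=channel_I.equivalent_radius_nm
    )


@pytest.fixture(scope="session")
def optics():
    return OpticalModel()


@pytest.fixture(scope="session")
def optics_clean():
    """Noise-free optical model for exact rendering checks."""
    return OpticalModel(noise_rel=0.0)


@pytest.fixture(scope="session")
def thyro():
    return SpeciesSpec("thyroglobulin", 669.0, rs_nm=8.6)


@pytest.fixture(scope="session")
def bsa():
    return SpeciesSpec("BSA", 66.0, rs_nm=3.5)


@pytest.fixture(scope="session")
def thyro_scene(channel_I, optics, thyro):
    """One noisy 400-frame thyroglobulin scene (kymograph + ground truth)."""
    plan = SimulationPlan(channel=channel_I, n_frames=400, rng_seed=123)
    return simulate_experiment(thyro, plan, optics)
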