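import numpy as np
import pytest
from hypothesis import settings

from scnkit.simulate import NetworkTemplate, SimulationConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_cohort():
    """Default-condition cohort: 91 Met + 101 Val, one planted Met>Val
    network on the dorsal caudal putamen seed (slopes 2 vs 1)."""
    config = SimulationConfig(rng_seed=11)
    cohort, truth = generate_cohort(config)
    return config, cohort, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Small, fast cohort on a 20^3 box with a planted equal-slope network."""
    template = NetworkTemplate(
        seed_name="dorsal_caudal_putamen",
        target_blobs=(((-16, -16, 8), 10.0, 1.0),),
        slope_met=2.0,
        slope_val=2.0,
    )
    config = SimulationConfig(
        n_met=25, n_val=25, image_shape=(20, 20, 20),
        baseline={"kind": "box", "density": 0.6},
        templates=(template,), behavior_couplings=(),
        rng_seed=5,
    )
    cohort, truth = generate_cohort(config)
    return config, cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
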