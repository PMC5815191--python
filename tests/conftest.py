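import numpy as np
import pytest

from resistsim import InsecticideParams, Scenario


@pytest.fixture
def base_insecticide() -> InsecticideParams:
    """All control inputs at 0.5, start frequency 0.01, no cost."""
    return InsecticideParams(
        effectiveness=0.5,
        exposure_female=0.5,
        exposure_male=0.5,
        resistance_restoration=0.5,
        dominance_resistance=0.5,
        start_frequency=0.01,
        cost=0.0,
        dominance_cost=0.0,
    )


@pytest.fixture
def base_scenario(base_insecticide) -> Scenario:
    return Scenario(insecticide1=base_insecticide, insecticide2=base_insecticide)


def random_insecticide(rng: np.random.Generator) -> InsecticideParams:
    """A biologically plausible random parameter draw."""
    return InsecticideParams(
        effectiveness=rng.uniform(0.1, 1.0),
        exposure_female=rng.uniform(0.1, 1.0),
        exposure_male=rng.uniform(0.1, 1.0),
        resistance_restoration=rng.uniform(0.0, 1.0),
        dominance_resistance=rng.uniform(0.0, 1.0),
        start_frequency=10 ** rng.uniform(-3.0, -1.3),
        cost=rng.uniform(0.0, 0.2),
        dominance_cost=rng.uniform(0.0, 1.0),
    )
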