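import pandas as pd
import pytest

from mycograze.simulate import SimulationConfig, generate_dataset


@pytest.fixture
def toy_obs():
    return pd.DataFrame(
        {
            "unit": ["f1/ungrazed/q1/s1", "f1/ungrazed/q1/s2", "f1/ungrazed/q1/s2"],
            "species": ["A", "A", "B"],
            "individual_number": [2, 1, 1],
        }
    )


@pytest.fixture
def toy_traits():
    return pd.DataFrame(
        {
            "species": ["A", "B"],
            "order": ["Agaricales", "Polyporales"],
            "trophic": ["Wood saprotrophs", "Soil saprotrophs"],
            "attachment": ["Wood-inhabiting", "Soil-inhabiting"],
            "sporocarp": ["Agaricoid fungi", "Polyporoid fungi"],
            "geographic": ["Cosmopolitan", "Pantropical"],
            "edibility": ["Unknown", "Edible"],
        }
    )


@pytest.fixture(scope="session")
def sim_default():
    """One realized default-condition dataset shared across tests."""
    config = SimulationConfig(seed=7)
    obs, traits, env, truth = generate_dataset(config)
    return config, obs, traits, env, truth
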