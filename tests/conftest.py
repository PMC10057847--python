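import numpy as np
import pytest

import sensortune as st


@pytest.fixture(scope="session")
def effect_model():
    return st.EffectModel.random(vocabulary_size=60, seed=11)


@pytest.fixture(scope="session")
def small_landscape(effect_model):
    """~700-variant synthetic landscape with its truth table."""
    genos = st.simulate_library(
        800, mean_missense=4.4, vocabulary=effect_model.vocabulary, seed=11
    )
    land, truth = st.simulate_landscape(genos, effect_model, seed=11)
    return land, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
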