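import numpy as np
import pytest

from synaptoflux.synthgen import ConditionSpec, SceneSpec


@pytest.fixture
def small_scene() -> SceneSpec:
    """Compact FOV that still holds a dozen well-separated boutons."""
    return SceneSpec(width_px=160, height_px=160, n_boutons=10, seed=7)


@pytest.fixture
def glass() -> ConditionSpec:
    return ConditionSpec(name="glass")


@pytest.fixture
def graphene() -> ConditionSpec:
    return ConditionSpec(name="graphene", bouton_intensity_scale=1.27)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
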