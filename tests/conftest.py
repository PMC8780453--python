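import pytest

from sacm.plant import (
    FlowLoopPlant,
    PlantConfig,
    crystalloid_curve,
    whole_blood_curve,
)


@pytest.fixture(scope="session")
def wb_curve():
    return whole_blood_curve()


@pytest.fixture(scope="session")
def cr_curve():
    return crystalloid_curve()


@pytest.fixture
def plant_at_75():
    """Whole-blood plant destabilized to 75 mmHg, noise-free."""
    return FlowLoopPlant(PlantConfig(), initial_map=75.0)


@pytest.fixture
def plant_full():
    """Whole-blood plant at the full-vessel baseline of 95 mmHg."""
    return FlowLoopPlant(PlantConfig())
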