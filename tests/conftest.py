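import pytest

from microlift import lift_physics, transfer_sim


@pytest.fixture
def cuboid400():
    """400-μm cuboid at the platform's operating point (56 μl/s, 0.8 mm)."""
    return lift_physics.FluidScenario.cuboid(400.0)


@pytest.fixture
def layout384():
    return transfer_sim.PlateLayout.standard(384)


@pytest.fixture
def mouse_model():
    return transfer_sim.ErrorModel.preset("mouse")


@pytest.fixture
def human_model():
    return transfer_sim.ErrorModel.preset("human")
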