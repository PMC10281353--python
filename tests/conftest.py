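import numpy as np
import pytest

from neurothresh.field_sources import LinearField, UniformField, figure_eight_coil
from neurothresh.geometry import CellFrame, GridSpec
from neurothresh.surrogate import (
    Placement,
    SurrogateNeuron,
    default_neuron,
    monophasic_waveform,
)


@pytest.fixture(scope="session")
def waveform():
    return monophasic_waveform()


@pytest.fixture
def identity_frame():
    return CellFrame((0.0, 0.0, 0.0), (0.0, 0.0, 1.0), (1.0, 0.0, 0.0))


@pytest.fixture
def spec9():
    return GridSpec(9, 1.5)


@pytest.fixture
def spec3():
    return GridSpec(3, 2.0)


@pytest.fixture
def uniform_z():
    return UniformField((0.0, 0.0, 1.0), 100.0)


@pytest.fixture
def linear_field():
    return LinearField(
        origin=(0.0, 0.0, 0.0),
        E0=(100.0, 20.0, -30.0),
        jacobian=((5.0, 1.0, -2.0), (0.0, 3.0, 4.0), (2.0, -1.0, 6.0)),
    )


@pytest.fixture(scope="session")
def coil():
    return figure_eight_coil()


@pytest.fixture
def single_terminal_neuron():
    """One terminal along +ẑc with weight 100 V/m: threshold 100/cosθ."""
    return SurrogateNeuron(
        "L5_PC", 1, ((0.0, 0.0, 0.5),), ((0.0, 0.0, 1.0),), (100.0,), 1.5
    )


@pytest.fixture
def seeded_neuron():
    return default_neuron("L5_PC", clone_id=1, seed=42)


@pytest.fixture
def placement(identity_frame):
    return Placement(0, identity_frame)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
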