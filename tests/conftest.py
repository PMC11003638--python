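import numpy as np
import pytest

from lfpunmix import ElectrodeGrid, Medium, Region


@pytest.fixture
def medium():
    return Medium(conductivity=0.3)


@pytest.fixture
def small_grid():
    """4 x 4 planar grid at 0.5 mm pitch, 1 mm deep."""
    xs, zs = np.meshgrid(np.arange(4) * 0.5, np.arange(4) * 0.5 + 1.0)
    pos = np.column_stack([xs.ravel(), np.zeros(16), zs.ravel()])
    return ElectrodeGrid(
        channel_ids=[f"ch{i}" for i in range(16)],
        positions=pos,
        broken=np.zeros(16, dtype=bool),
    )


@pytest.fixture
def unit_box():
    return Region("box", [[[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]]])
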