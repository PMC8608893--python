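import numpy as np
import pytest

from microspacing import PointPattern


@pytest.fixture
def unit_square_corners() -> PointPattern:
    return PointPattern(
        np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]), (0.0, 0.0, 1.0, 1.0)
    )


@pytest.fixture
def csr_50() -> PointPattern:
    rng = np.random.default_rng(42)
    return PointPattern(rng.uniform(0, 100, size=(50, 2)), (0.0, 0.0, 100.0, 100.0))
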