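import numpy as np
import pytest

from parafit import ExpressionMatrix


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """The 2x2 worked example [[1, 2], [3, 5]] (MSR = 0.0625)."""
    return ExpressionMatrix(np.array([[1.0, 2.0], [3.0, 5.0]]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def random_matrices(rng):
    """Seeded batch of small random matrices (shapes 2..6 x 2..6)."""
    def make(n: int, lo: int = 2, hi: int = 6, scale: float = 100.0):
        out = []
        for _ in range(n):
            shape = (rng.integers(lo, hi + 1), rng.integers(lo, hi + 1))
            out.append(rng.uniform(-scale, scale, size=shape))
        return out
    return make
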