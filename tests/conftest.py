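import numpy as np
import pytest

from clonecascade.fixtures import toy_model as _toy_model
from clonecascade.presets import human_hematopoiesis


@pytest.fixture
def toy_model():
    """4-compartment hierarchy with gamma=0.7, rates 1.26**(k-1), N0=5."""
    return _toy_model()


@pytest.fixture
def hema8():
    """Human hematopoiesis truncated to the first 8 compartments."""
    return human_hematopoiesis(8)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def rel_err(candidate: np.ndarray, oracle: np.ndarray) -> np.ndarray:
    """Relative error with the denominator floored at 1e-6 of the oracle's own
    peak, so points where the trajectory has decayed to the integrator's
    absolute-noise floor do not dominate the comparison."""
    candidate = np.asarray(candidate, dtype=float)
    oracle = np.asarray(oracle, dtype=float)
    floor = 1e-6 * max(np.max(np.abs(oracle)), 1e-300)
    return np.abs(candidate - oracle) / np.maximum(np.abs(oracle), floor)
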