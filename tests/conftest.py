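import numpy as np
import pytest

from nirchem.spectra import SpectraSet, WavelengthGrid


@pytest.fixture
def small_grid():
    return WavelengthGrid(np.array([950.0, 952.0, 954.0, 956.0]))


@pytest.fixture
def reflectance_set(small_grid):
    rng = np.random.default_rng(42)
    values = rng.uniform(0.1, 0.9, size=(3, 4))
    return SpectraSet(small_grid, values, ["a", "b", "c"], "reflectance")


@pytest.fixture
def absorbance_set(small_grid):
    rng = np.random.default_rng(7)
    values = rng.uniform(0.2, 1.5, size=(5, 4))
    return SpectraSet(small_grid, values, list("abcde"), "absorbance")


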