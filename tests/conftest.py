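import numpy as np
import pytest

from nichefit.pnm_core import R_FLOOR, ParamSet
from nichefit.web_data import FoodWeb


def make_web(S: int, L: int) -> FoodWeb:
    """Arbitrary web with exactly S species and L links (row-major fill)."""
    flat = np.zeros(S * S, dtype=np.int8)
    flat[:L] = 1
    return FoodWeb([f"s{i}" for i in range(S)], flat.reshape(S, S))


def random_params(S: int, rng: np.random.Generator) -> ParamSet:
    return ParamSet(
        n=rng.uniform(0, 1, S),
        c=rng.uniform(0, 1, S),
        r=rng.uniform(0.05, 0.8, S),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def chain_web():
    """Producer -> grazer -> predator chain with one omnivory link."""
    #        a  b  z
    A = [
        [0, 0, 0],  # a: producer
        [1, 0, 0],  # b eats a (specialist)
        [1, 1, 0],  # z eats a and b
    ]
    return FoodWeb(["a", "b", "z"], A)


@pytest.fixture
def two_species_web():
    return FoodWeb(["prey", "hunter"], [[0, 0], [1, 0]])
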