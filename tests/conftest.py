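import numpy as np
import pytest

from probeforest import NNParameterSet, load_nn_params

#: 42 C in kelvin -- the hybridization temperature of the modelled protocol.
TEMP_K = 315.15


@pytest.fixture(scope="session")
def nn_params() -> NNParameterSet:
    return load_nn_params()


@pytest.fixture(scope="session")
def zero_params() -> NNParameterSet:
    """A parameter set in which every term vanishes (dG identically 0)."""
    zero = (0.0, 0.0)
    full = load_nn_params()
    return NNParameterSet(
        {k: zero for k in full.match_steps},
        {k: zero for k in full.mismatch_steps},
        {"GC": zero, "AT": zero},
        salt_coeff=0.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
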