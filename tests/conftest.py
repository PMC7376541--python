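import numpy as np
import pytest

from notchfde import CellTopology, ModelParameters


@pytest.fixture
def table1() -> ModelParameters:
    """The packaged default constants with Delta expressed (lam = 1000)."""
    return ModelParameters(
        lambda_delta=1000.0,
        lambda_notch=0.07,
        f=0.01,
        d=0.01,
        a=0.01,
        b=200.0,
        theta=1.0e6,
        alpha=0.9,
    )


@pytest.fixture
def table1_zero(table1) -> ModelParameters:
    """The same constants with Delta production switched off."""
    return table1.replace(lambda_delta=0.0)


@pytest.fixture
def pair() -> CellTopology:
    return CellTopology.pair()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
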