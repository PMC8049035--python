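import numpy as np
import pytest

from thetafear import ParamSet


@pytest.fixture(scope="session")
def params() -> ParamSet:
    """Calibrated default parameter set."""
    return ParamSet()


@pytest.fixture(scope="session")
def tiny_params() -> ParamSet:
    """Small populations and short epochs for fast protocol tests."""
    return ParamSet(
        n_fear=2,
        n_pc_per_compartment=3,
        n_cycles_cond=10,
        n_cycles_recall=5,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
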