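import numpy as np
import pytest

from icodiff import build_icosphere, run_normative_study


@pytest.fixture(scope="session")
def ico0():
    return build_icosphere(0)


@pytest.fixture(scope="session")
def ico2():
    return build_icosphere(2)


@pytest.fixture(scope="session")
def ico3():
    return build_icosphere(3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def study_results():
    """The desk-scale end-to-end study: order-2 synthetic cohort, conditional
    and unconditional diffusion models, reconstruction, scoring, ablation.

    Expensive (several minutes); shared across the tests that assert on its
    outcome.
    """
    return run_normative_study(seed=1)
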