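import numpy as np
import pytest

from mcdip.core_model import BValueScheme, GradientScheme
from mcdip.phantom import PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def small_truth():
    """Small seeded phantom shared by read-only tests."""
    return make_phantom(shape=(16, 16, 10), seed=42)


@pytest.fixture(scope="session")
def medium_truth():
    """Cohort-scale phantom for fitting tests."""
    return make_phantom(shape=(24, 24, 12), seed=7)


@pytest.fixture(scope="session")
def scheme_2nd():
    return BValueScheme(scheme=GradientScheme.SECOND_ORDER_MC)


@pytest.fixture(scope="session")
def scheme_non():
    return BValueScheme(scheme=GradientScheme.NON_MC)
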