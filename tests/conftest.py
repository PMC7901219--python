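import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from markovcea import (ACTH_SUMMARY, TCH_SUMMARY, TransitionMatrix,
                       build_arm_matrix, default_model)


@pytest.fixture(scope="session")
def printed_model():
    """Base-case AC-TH vs TCH model with table-precision probabilities."""
    return default_model(rounding_mode="printed_precision")


@pytest.fixture(scope="session")
def acth_printed():
    return build_arm_matrix(ACTH_SUMMARY, rounding_mode="printed_precision")


@pytest.fixture(scope="session")
def tch_printed():
    return build_arm_matrix(TCH_SUMMARY, rounding_mode="printed_precision")


@pytest.fixture(scope="session")
def acth_matrix(acth_printed):
    return TransitionMatrix.from_derived(acth_printed)


@pytest.fixture(scope="session")
def tch_matrix(tch_printed):
    return TransitionMatrix.from_derived(tch_printed)


@pytest.fixture
def all_stable_init():
    return np.array([1.0, 0.0, 0.0, 0.0])
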