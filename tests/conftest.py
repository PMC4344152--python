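import numpy as np
import pytest

from modnets import build_mask, init_genome, make_input_set, make_task


@pytest.fixture(scope="session")
def small_input_set():
    """A 2-module (256 x 16) binary input set, fixed seed."""
    return make_input_set(2, seed=1234)


@pytest.fixture(scope="session")
def baseline_task(small_input_set):
    """State-1 task on the small input set: 100/156 split, threshold 0.5."""
    _, task = make_task(1, 99, small_input_set)
    return task


@pytest.fixture(scope="session")
def small_pmn_genome():
    return init_genome(build_mask("PMN", 2), beta=1.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
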