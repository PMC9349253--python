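import numpy as np
import pytest

from sectplan import datasets, make_three_target_model


@pytest.fixture(scope="session")
def three_target_block():
    return make_three_target_model()


@pytest.fixture(scope="session")
def position_table():
    return datasets.three_target_positions()


@pytest.fixture(scope="session")
def distance_table():
    return datasets.cutting_forward_distances()
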