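import numpy as np
import pandas as pd
import pytest

from socmap import GridSpec, SampleTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return GridSpec(0.0, 0.0, 1.0, 1.0, 20, 20)


@pytest.fixture
def simple_table():
    frame = pd.DataFrame({
        "x": [0.0, 1.0, 2.0],
        "y": [0.0, 1.0, 0.5],
        "soc": [10.0, 12.0, 11.0],
        "tn": [3.0, 3.5, 4.0],
    })
    return SampleTable(frame)
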