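import numpy as np
import pandas as pd
import pytest

from mbcca.datamodel import FeatureTable, GroupDesign


@pytest.fixture
def small_table():
    """4 samples x 3 features with group metadata."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [10.0, 0.0, 1.0], [8.0, 1.0, 0.0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["fA", "fB", "fC"],
    )
    meta = pd.DataFrame(
        {"group": ["ctl", "ctl", "trt", "trt"]}, index=data.index
    )
    return FeatureTable(data, "count", sample_meta=meta)


@pytest.fixture
def two_group_design():
    return GroupDesign({"s1": "ctl", "s2": "ctl", "s3": "trt", "s4": "trt"})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
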