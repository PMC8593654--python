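import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from streampulse.data_model import CompoundMeta, ConcentrationMatrix


@pytest.fixture
def toy_meta():
    return [
        CompoundMeta("alpha", "fungicide", False, 6.0, 0.10, aqs=50.0, rac=100.0),
        CompoundMeta("beta", "herbicide", False, 10.0, 0.05, aqs=200.0),
        CompoundMeta("gamma", "insecticide", False, 2.0, 0.02, rac=30.0),
    ]


@pytest.fixture
def toy_matrix(toy_meta):
    """8 x 3 matrix on a 20-min grid with one gap row and mixed censoring."""
    idx = pd.date_range("2019-06-01", periods=8, freq="20min")
    values = pd.DataFrame(
        {
            "alpha": [3.0, 10.0, 40.0, 80.0, 5.0, 12.0, 7.0, 9.0],
            "beta": [12.0, 9.0, 30.0, 250.0, 11.0, 8.0, 15.0, 40.0],
            "gamma": [1.0, 2.5, 5.0, 35.0, 1.5, 3.0, 2.0, 4.0],
        },
        index=idx,
    )
    values.iloc[5] = np.nan
    return ConcentrationMatrix(values=values, compounds=toy_meta)
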