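import numpy as np
import pandas as pd
import pytest

from metarr.cli import schematic_dataset, toy_missing_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20221226)


@pytest.fixture
def schematic():
    """Five effects in three studies; study S2 (effects E3, E4) does not
    report SDs."""
    return schematic_dataset()


@pytest.fixture
def toy_missing():
    """Small synthetic dataset with ~20% of studies missing SDs."""
    return toy_missing_dataset()


@pytest.fixture
def yv_frame():
    """Fixed 10-effect / 5-study (yi, vi) table used for model tests."""
    return pd.DataFrame({
        "yi": [0.42, 0.11, -0.05, 0.33, 0.27, 0.60, 0.18, -0.12, 0.05, 0.38],
        "vi": [0.012, 0.025, 0.018, 0.031, 0.009, 0.044, 0.015, 0.027,
               0.011, 0.022],
        "study_id": ["a", "a", "a", "b", "b", "c", "c", "d", "d", "e"],
    })
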