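import numpy as np
import pytest

import urbancanopy as uc
from urbancanopy import synthetic as syn


@pytest.fixture(scope="session")
def thresholds():
    """Canopy-splitting threshold lines calibrated from a synthetic
    QSM-tree table drawn from the benchmark scene's allometric laws."""
    params = syn.AllometricParams(height_range=(12.0, 18.0), radius_sd=0.25)
    return syn.calibration_thresholds(seed=123, params=params)


@pytest.fixture(scope="session")
def seg_params(thresholds):
    split, bt = thresholds
    return uc.SegmentationParams(split_model=split, bt_model=bt)


@pytest.fixture(scope="session")
def benchmark_scene():
    """One well-separated 50-tree scene with its ground truth."""
    return syn.well_separated_scene(n_trees=50, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
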