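import numpy as np
import pytest

from nirsbci.config import RunConfig
from nirsbci.features import SpatialFeatureExtractor
from nirsbci.montage import ImageGrid, Montage, map_channels_to_grid
from nirsbci.pipeline import participant_features
from nirsbci.preprocess import TrialEpoch


@pytest.fixture(scope="session")
def montage():
    return Montage()


@pytest.fixture(scope="session")
def grid():
    return ImageGrid()


@pytest.fixture(scope="session")
def channel_coords(montage, grid):
    return map_channels_to_grid(montage, grid)


@pytest.fixture(scope="session")
def extractor(montage, grid):
    return SpatialFeatureExtractor(montage, grid)


def make_epoch(data, fs=31.25, task="MM"):
    """Epoch from raw (9, 3, n) data with the standard identity fields."""
    data = np.asarray(data, dtype=float)
    return TrialEpoch(
        participant="P1", session=0, block=0, interval=0, task=task,
        onset_s=30.0, fs=fs, data=data,
    )


@pytest.fixture
def epoch_factory():
    return make_epoch


@pytest.fixture(scope="session")
def features_two_sessions():
    """Shared end-to-end feature matrix: one simulated participant, two
    sessions, generator defaults (24 epochs per task)."""
    cfg = RunConfig(seed=11, n_sessions=2)
    return participant_features(cfg, "P1", cfg.effect_spec(), seed=11)
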