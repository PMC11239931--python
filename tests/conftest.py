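import numpy as np
import pytest

from lgpc.grids import TFGrid
from lgpc.model import ScalingParams
from lgpc.synthetic import SyntheticConfig, simulate_ersp_dataset


@pytest.fixture(scope="session")
def roi_grid():
    """Reduced grid zoomed on the post-fifth-tone gamma response."""
    return TFGrid.response_roi()


@pytest.fixture(scope="session")
def standard_grid():
    return TFGrid.standard()


@pytest.fixture(scope="session")
def small_dataset(roi_grid):
    """Small synthetic dataset at the generator's default study conditions."""
    cfg = SyntheticConfig(grid=roi_grid, n_trials_per_type=32, seed=7)
    return simulate_ersp_dataset(cfg)


@pytest.fixture(scope="session")
def clean_dataset(roi_grid):
    """Noise-free dataset: per-type means equal the planted structure exactly."""
    cfg = SyntheticConfig(grid=roi_grid, n_trials_per_type=8, seed=5,
                          noise_sd=0.0, trial_gain_sd=0.0,
                          true_params=ScalingParams(0.4, 0.8, 0.7))
    return simulate_ersp_dataset(cfg)


def contrast_tensor(dataset):
    """Raw (unmasked) deviant-contrast tensor of a dataset."""
    tm = dataset.type_means()
    maps = np.stack([tm["xy|xx"] - tm["xx|xx"], tm["xy|xy"] - tm["xx|xy"]])
    from lgpc.tensorfit import tensor_from_maps
    return tensor_from_maps(maps, dataset.grid)
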