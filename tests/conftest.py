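import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from filmqa.grids import DosePlane2D
from filmqa.phantom import SimulationConfig, generate_treatment_dataset
from filmqa.pipeline import QaConfig, run_qa

SEED = 20260924


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


def smooth_relative_plane(rng, shape=(15, 15), lo=0.05, hi=1.0, sigma=2.0):
    """Smooth positive random field on a 1 mm grid, normalized to [lo, hi]."""
    raw = gaussian_filter(rng.normal(size=shape), sigma=sigma, mode="nearest")
    raw = (raw - raw.min()) / (raw.max() - raw.min() + 1e-12)
    vals = lo + (hi - lo) * raw
    return DosePlane2D(vals, [1.0, 1.0], [0.0, 0.0], True, 1.0)


def perturbed_pair(rng, shape=(15, 15), noise=0.05):
    """A correlated (reference, evaluated) pair of relative planes."""
    ref = smooth_relative_plane(rng, shape)
    bump = gaussian_filter(rng.normal(size=shape), sigma=3.0, mode="nearest")
    vals = ref.values + noise * bump
    ev = DosePlane2D(np.clip(vals, 0.01, None), [1.0, 1.0], [0.0, 0.0], True, 1.0)
    return ref, ev


@pytest.fixture(scope="session")
def paper_tree(tmp_path_factory):
    """The 14-dataset layout with default measurement noise and zero
    delivery error, generated once per session."""
    root = tmp_path_factory.mktemp("paper_tree")
    config = SimulationConfig.null_experiment()
    dataset = generate_treatment_dataset(config, 1, root)
    return root, dataset


@pytest.fixture(scope="session")
def paper_report(paper_tree):
    root, _ = paper_tree
    return run_qa(QaConfig(dataset_root=root))
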