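import numpy as np
import pytest

from melvasc.pipeline import analyze_roi
from melvasc.simulate import generate_roi, random_roi_spec


@pytest.fixture(scope="session")
def small_roi():
    """One mid-size synthetic ROI, generated once and shared read-only."""
    spec = random_roi_spec(seed=7, shape=(700, 700), n_vessels=12,
                           n_cells=150, n_tls=1)
    stack, truth = generate_roi(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def small_roi_result(small_roi):
    """Full pipeline result on the shared ROI."""
    _, stack, _ = small_roi
    return analyze_roi(stack)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
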