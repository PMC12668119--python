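"""Shared fixtures: grids, gradient tables and small dictionaries.

Everything is generated programmatically; the only packaged inputs are the
precomputed 724-vertex orientation grid and the 150-direction scheme.
"""

import numpy as np
import pytest

from fibermatch import FitConfig, build_dictionary, default_grid, make_gradient_table
from fibermatch.sphere import build_grid


@pytest.fixture(scope="session")
def grid724():
    return default_grid()


@pytest.fixture(scope="session")
def gtab151():
    """Single-shell b=2000 scheme: one b0 + 150 directions."""
    return make_gradient_table(150, 2000.0)


@pytest.fixture(scope="session")
def small_grid():
    """Cheap 64-vertex grid for tests that rebuild grids."""
    return build_grid(64, n_iter=400)


@pytest.fixture(scope="session")
def small_dictionary(gtab151, grid724):
    """2,000-entry in vivo dictionary on the 151-volume scheme."""
    return build_dictionary(2000, gtab151, grid724, mode="invivo", seed=7)


@pytest.fixture(scope="session")
def fit_cfg():
    return FitConfig(K=50, alpha=1e-5, wm_threshold=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
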