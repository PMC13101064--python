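import numpy as np
import pandas as pd
import pytest

from mpmtex import CohortDesign, FeatureTable, GridSpec, PhantomParams

# Small geometry used throughout the suite: full cohort structure, tiny tiles.
SMALL_GRID = GridSpec(rows=2, cols=2, tile_size=64, overlap=0.10)


@pytest.fixture
def small_grid() -> GridSpec:
    return SMALL_GRID


@pytest.fixture
def small_design() -> CohortDesign:
    """Default cohort composition at a fast 2x2/64px/1z geometry."""
    return CohortDesign(grid=SMALL_GRID, n_z=1)


@pytest.fixture
def quiet_params() -> PhantomParams:
    """Noise-free, vignette-free phantom parameters (truth passthrough)."""
    return PhantomParams(vignette_strength=0.0, read_noise_sd=0.0,
                         shot_noise=False)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


def make_feature_table(X: np.ndarray, labels, names=None,
                       preparations=None) -> FeatureTable:
    """Wrap a raw matrix as a FeatureTable for selection/stats tests."""
    n, f = X.shape
    names = names or [f"F {k:02d}" for k in range(1, f + 1)]
    ids = [f"s{k:03d}" for k in range(n)]
    preparations = preparations or ["FFPE"] * n
    return FeatureTable(ids, list(labels), list(preparations),
                        pd.DataFrame(X, columns=names))
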