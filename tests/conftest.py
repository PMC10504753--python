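import numpy as np
import pandas as pd
import pytest

from symptomnet.cohort import (
    default_spec,
    generate_cohort,
)
from symptomnet.ggm import EstimatorConfig


@pytest.fixture(scope="session")
def fast_config() -> EstimatorConfig:
    """Reduced lambda grid for test-scale estimation."""
    return EstimatorConfig(n_lambda=20)


@pytest.fixture(scope="session")
def planted_items_2000() -> pd.DataFrame:
    """Symptom items only, n=2000, default planted network, fixed seed."""
    return generate_cohort(default_spec(2000, seed=11, include_ctq=False))


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Full cohort (CTQ + demographics + symptoms), n=4000, fixed seed."""
    return generate_cohort(default_spec(4000, seed=3))


def draw_ordinal_pair(r: float, thresholds, n: int, seed: int) -> np.ndarray:
    """Two ordinal items discretized from a bivariate normal with corr r."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    z[:, 1] = r * z[:, 0] + np.sqrt(1 - r * r) * z[:, 1]
    return np.searchsorted(np.asarray(thresholds), z, side="left")
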