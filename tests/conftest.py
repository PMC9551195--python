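import numpy as np
import pytest

from cumimpact import (GridSpec, HabitatLayer, SeascapeConfig,
                       generate_evidence, load_demo_evidence, demo_truth)
from cumimpact.meta import SensitivityScore


@pytest.fixture(scope="session")
def demo_records():
    """The packaged synthetic evidence table (published-count structure)."""
    return load_demo_evidence()


@pytest.fixture(scope="session")
def synthetic_records():
    return generate_evidence(demo_truth(), seed=11)


@pytest.fixture
def small_grid():
    return GridSpec(n_rows=8, n_cols=10, origin_x=500_000.0,
                    origin_y=6_000_000.0)


@pytest.fixture
def uniform_reef(small_grid):
    return HabitatLayer("reef", small_grid,
                        np.full(small_grid.shape, 0.5))


def make_score(habitat_id, pressures, rr_mean, rr_low=None, rr_high=None,
               k=5, evidence="direct"):
    """Convenience constructor for hand-specified sensitivity scores."""
    if rr_low is None:
        rr_low = rr_mean * 0.8
    if rr_high is None:
        rr_high = rr_mean * 1.25
    return SensitivityScore(
        habitat_id=habitat_id, pressure_set=frozenset(pressures), k=k,
        rr_mean=rr_mean, rr_low=rr_low, rr_high=rr_high, tau2=0.0,
        evidence=evidence)


@pytest.fixture
def seascape_config():
    return SeascapeConfig(n_rows=30, n_cols=30, seed=5)
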