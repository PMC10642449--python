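import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from myelinlfq.synthetic_data import SimulationConfig, default_aging_design
from myelinlfq.types import IntensityMatrix, SampleDesign

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_group_design() -> SampleDesign:
    return SampleDesign.from_groups(
        {"young": ["y1", "y2", "y3"], "old": ["o1", "o2", "o3"]}
    )


@pytest.fixture
def small_matrix(two_group_design) -> IntensityMatrix:
    rng = np.random.default_rng(7)
    vals = pd.DataFrame(
        rng.lognormal(14, 1, (20, 6)),
        index=[f"P{i:03d}" for i in range(20)],
        columns=two_group_design.samples,
    )
    return IntensityMatrix(vals, "raw")


@pytest.fixture
def quiet_config() -> SimulationConfig:
    """No dropout, no differential abundance: a clean complete null."""
    return SimulationConfig(
        n_proteins=100, de_fraction=0.0, mnar_midpoint=-np.inf, mar_rate=0.0, seed=11
    )


def make_design(n_per_group: int = 3) -> SampleDesign:
    return default_aging_design(SimulationConfig(n_per_group=n_per_group))
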