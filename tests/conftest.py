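import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import famclust as fc

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def tiny_expr():
    """3 genes x 4 samples of raw counts."""
    vals = pd.DataFrame(
        [[0.0, 1.0, 3.0, 7.0], [10.0, 20.0, 30.0, 40.0], [5.0, 5.0, 6.0, 8.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return fc.ExpressionMatrix(vals, platform="count_like", transform_state="raw")


@pytest.fixture
def small_cohort():
    """Separable 3-cluster synthetic cohort used by several modules."""
    spec = fc.CohortSpec(
        n_samples_per_cluster=(40, 40, 40),
        n_genes=60,
        n_informative_genes=30,
        seed=7,
    )
    expr, truth = fc.simulate_expression(spec)
    return spec, expr, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
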