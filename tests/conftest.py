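import math

import numpy as np
import pytest

import crxpower as cp


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def example_a():
    """Two-period crossover count scenario: 10 clusters, 210 participants per
    cluster-period with 10 at-risk days each, baseline 4 events per 1000
    at-risk days, rate ratio 0.75, between-cluster variance 0.5."""
    design = cp.make_design(10, 2, 210)
    params = cp.PoissonParams(
        period_effect=math.log(0.004),
        effect_size=math.log(0.75),
        btw_clust_var=0.5,
        at_risk=10,
    )
    return design, params


@pytest.fixture(scope="session")
def example_d_crxo():
    """Crossover count scenario: 20 clusters of 20, 5 at-risk days each,
    baseline 1 event/day, rate ratio 0.9, between-cluster variance 0.01."""
    design = cp.make_design(20, 2, 20)
    params = cp.PoissonParams(
        period_effect=math.log(1.0),
        effect_size=math.log(0.9),
        btw_clust_var=0.01,
        at_risk=5,
    )
    return design, params
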