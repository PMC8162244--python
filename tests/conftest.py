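import numpy as np
import pandas as pd
import pytest

import varpart as vp


@pytest.fixture(scope="session")
def orthogonal_gaussian():
    """Two independent unit-variance predictors, beta=(0,1,0.5), known truth."""
    sc = vp.SimScenario(
        n_groups=50,
        group_size=20,
        beta=(0.0, 1.0, 0.5),
        sigma2_group=0.5,
        sigma2_resid=0.5,
        seed=42,
    )
    data, truth = vp.simulate_dataset(sc)
    return sc, data, truth


@pytest.fixture(scope="session")
def orthogonal_fit(orthogonal_gaussian):
    _, data, _ = orthogonal_gaussian
    spec = vp.parse_formula("y ~ x1 + x2 + (1|group)")
    return vp.fit_mixed_model(spec, data), data


@pytest.fixture()
def interaction_data():
    """Continuous Rank x 3-level Time factor with a subject grouping."""
    return vp.guinea_pig_like(seed=1, interaction_strength=0.3)
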