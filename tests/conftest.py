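import numpy as np
import pytest

import ramanpheno as rp


@pytest.fixture(scope="session")
def small_axis():
    """Fingerprint-region axis used by most fixtures (fast)."""
    return rp.make_axis(600.0, 1800.0, 300)


@pytest.fixture(scope="session")
def template():
    return rp.default_template()


@pytest.fixture(scope="session")
def small_cohort(template, small_axis):
    """Clean 2-donor cohort: 150 cells/donor, no artifacts beyond noise."""
    config = rp.CohortConfig(
        n_donors=2, cells_per_donor=150, seed=42, axis=small_axis
    )
    return rp.simulate_cohort(template, config)


@pytest.fixture(scope="session")
def toy_xy():
    """Separable-ish 2-channel toy problem for optimizer oracles."""
    rng = np.random.default_rng(7)
    n = 20
    X = rng.normal(size=(n, 2))
    logits = 0.8 * X[:, 0] - 0.5 * X[:, 1] + 0.2
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
    # ensure both classes present
    y[0], y[1] = 0, 1
    return X, y
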