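import numpy as np
import pandas as pd
import pytest

import paleoniche as pn


@pytest.fixture(scope="session")
def default_run():
    """Default change-point scenario: cube, niche, raw occurrences."""
    cfg = pn.default_scenario(seed=7)
    cube, niche, occ = pn.generate_scenario(cfg)
    return cfg, cube, niche, occ


@pytest.fixture(scope="session")
def collapsed(default_run):
    _, cube, _, occ = default_run
    return pn.collapse_occurrences(pn.filter_occurrences(occ), cube)


@pytest.fixture(scope="session")
def model_table(default_run, collapsed):
    """One background repetition joined to environments."""
    _, cube, _, _ = default_run
    reps = pn.sample_background_repetitions(
        collapsed, cube, n_repetitions=1, ratio=50, master_seed=3
    )
    return pn.build_model_table(collapsed, reps, cube)


@pytest.fixture(scope="session")
def quadratic_logit_data():
    """Presence/background rows from a known quadratic-logit truth in one
    variable; used for recovery and score tests."""
    rng = np.random.default_rng(42)
    n = 5000
    x = rng.uniform(-2, 2, n)
    eta = -1.0 + 1.2 * x - 1.5 * x**2
    p = 1 / (1 + np.exp(-eta))
    y = (rng.random(n) < p).astype(float)
    return pd.DataFrame({"response": y, "BIO5": x, "eta_true": eta})
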