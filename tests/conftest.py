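import numpy as np
import pandas as pd
import pytest

from gmintegrity.modelspec import parse_model
from gmintegrity.ram import compile_ram, implied_moments
from gmintegrity.simulate import default_base2_config

TWO_FACTOR_MODEL = """
F =~ x1 + x2 + x3
G =~ y1 + y2 + y3
F ~~ G
"""


@pytest.fixture(scope="session")
def base_config():
    return default_base2_config()


@pytest.fixture(scope="session")
def two_factor_spec():
    return parse_model(TWO_FACTOR_MODEL)


def sample_from_spec(spec, theta, n, seed, missing_frac=0.0):
    """Draw rows from the multivariate normal implied by a compiled spec."""
    ram = compile_ram(spec)
    mu, Sigma = implied_moments(ram, theta)
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(mu, Sigma, size=n, method="cholesky")
    if missing_frac > 0:
        mask = rng.random(X.shape) < missing_frac
        # keep at least one observed cell per row
        mask[mask.all(axis=1), 0] = False
        X[mask] = np.nan
    return pd.DataFrame(X, columns=spec.observed)


def two_factor_theta(ram, factor_cov=0.5):
    """A regular parameter point for the two-factor fixture model."""
    values = {
        "l_F_x2": 0.8, "l_F_x3": 0.7, "l_G_y2": 0.9, "l_G_y3": 0.6,
        "c_F_G": factor_cov, "v_F": 1.0, "v_G": 1.0,
    }
    theta = np.zeros(ram.n_params)
    for k, label in enumerate(ram.param_names):
        if label in values:
            theta[k] = values[label]
        elif label.startswith("v_"):
            theta[k] = 0.64
        elif label.startswith("mu_"):
            theta[k] = 0.0
    return theta
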