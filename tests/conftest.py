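import logging

import numpy as np
import pytest

import varlaplace as vl


@pytest.fixture(autouse=True)
def _quiet_logs():
    logging.getLogger("varlaplace").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def linear_gaussian_instance(rng, p=None, D=None):
    """Random linear-Gaussian model with the noise log precision clamped."""
    from varlaplace.validation import clamp_lambda

    p = p or int(rng.integers(1, 5))
    D = D or int(rng.integers(p + 1, 31))
    X = rng.normal(size=(D, p))
    prior = vl.GaussianDensity(rng.normal(0.0, 1.0, p), np.diag(rng.uniform(0.5, 2.0, p)))
    lam_star = float(rng.uniform(-1.0, 1.0))
    beta_true = rng.multivariate_normal(prior.mean, prior.cov)
    y = X @ beta_true + rng.standard_normal(D) * np.exp(-0.5 * lam_star)
    model = vl.GenerativeModel(
        g=lambda b, X=X: X @ b,
        prior_beta=prior,
        prior_lambda=clamp_lambda([lam_star]),
        precision=vl.PrecisionComponents([np.eye(D)]),
    )
    return X, y, lam_star, model


@pytest.fixture
def scalar_model():
    """One observation, one parameter, identity map, unit noise and prior."""
    return vl.GenerativeModel(
        g=lambda b: np.array([b[0]]),
        prior_beta=vl.GaussianDensity([0.0], [[1.0]]),
        prior_lambda=vl.GaussianDensity([0.0], [[1e-8]]),
        precision=vl.PrecisionComponents([np.eye(1)]),
    )
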