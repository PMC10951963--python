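"""Seeded synthetic-data generators for every worked model.

Each generator is a pure function of a :class:`FixtureSpec`: the seed fully
determines the emitted dataset, so experiments are bit-reproducible.  The
declared true parameter values are fixture constants chosen to be realistic
for each model class (the regression, heteroskedastic-noise, exponential
decay and hemodynamic settings used throughout the tests); they define the
simulation study conditions and are not tuned per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import (
    GaussianDensity,
    GenerativeModel,
    PrecisionComponents,
    default_hyperprior,
)
from .dynamics import StateSpaceModel, as_observation_function
from .exceptions import InputError
from .models import (
    HemodynamicConstants,
    HemodynamicParams,
    bold_observation,
    decay_field,
    glm_design,
    glm_predict,
    hemo_field,
    hetero_components,
)

__all__ = [
    "FixtureSpec",
    "glm_spec",
    "hetero_spec",
    "decay_spec",
    "hemo_spec",
    "make_glm",
    "make_hetero",
    "make_decay",
    "make_hemo",
    "hemo_state_space",
    "boxcar",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Registry key, generating parameter values, seed, size and model-specific extras."""

    name: str
    true_beta: tuple[float, ...]
    true_lambda: tuple[float, ...]
    seed: int = 0
    size: int = 100
    extras: dict[str, Any] = field(default_factory=dict)


def glm_spec(seed: int = 0, size: int = 100, **extras) -> FixtureSpec:
    """Linear regression: intercept 4, slope 0.3, i.i.d. log precision -2."""
    return FixtureSpec("glm", (4.0, 0.3), (-2.0,), seed=seed, size=size, extras=extras)


def hetero_spec(seed: int = 0, size: int = 100, **extras) -> FixtureSpec:
    """Two-block heteroskedastic regression: first half noisier (log precisions -3, -1)."""
    return FixtureSpec(
        "glm-hetero", (4.0, 0.3), (-3.0, -1.0), seed=seed, size=size, extras=extras
    )


def decay_spec(seed: int = 0, size: int = 50, **extras) -> FixtureSpec:
    """Exponential decay: log rate -1, unit initial state, 10 s of samples, log precision 2."""
    extras = {"x0": 1.0, "duration": 10.0, **extras}
    return FixtureSpec("decay", (-1.0,), (2.0,), seed=seed, size=size, extras=extras)


def hemo_spec(seed: int = 0, duration: float = 300.0, **extras) -> FixtureSpec:
    """Balloon model driven by a boxcar train.

    Ground truth: transit time 2 s, signal decay 0.64 /s, efficacy 0.4
    (fitted as ln tau_h, ln kappa, efficacy); observation noise sd 0.003 in
    fractional BOLD units, i.e. roughly a third of the response peak.
    """
    extras = {
        "TR": 1.0,
        "substeps": 2,        # fitted model: discretisation error ~2% of noise sd
        "gen_substeps": 16,   # data generation: effectively exact
        "noise_sd": 0.003,
        "box_on": 10.0,
        "box_period": 30.0,
        "box_start": 10.0,
        **extras,
    }
    true_lambda = float(-2.0 * np.log(extras["noise_sd"]))
    size = int(round(duration / extras["TR"]))
    return FixtureSpec(
        "hemo",
        (float(np.log(2.0)), float(np.log(0.64)), 0.4),
        (true_lambda,),
        seed=seed,
        size=size,
        extras=extras,
    )


def _noise(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    """Gaussian noise at precision exp(lam); an infinite lam clamps noise to zero."""
    if np.isinf(lam) and lam > 0:
        return np.zeros(n)
    return rng.standard_normal(n) * np.exp(-0.5 * lam)


def make_glm(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray, GenerativeModel]:
    """Simulate the evenly spaced-covariate regression; return (X, y, model)."""
    if spec.size < 2:
        raise InputError("GLM fixture needs size >= 2")
    rng = np.random.default_rng(spec.seed)
    X = glm_design(spec.size)
    beta = np.asarray(spec.true_beta, dtype=float)
    y = glm_predict(X, beta) + _noise(rng, spec.true_lambda[0], spec.size)
    model = GenerativeModel(
        g=lambda b: glm_predict(X, b),
        prior_beta=GaussianDensity(np.zeros(2), 16.0 * np.eye(2)),
        prior_lambda=default_hyperprior(1),
        precision=PrecisionComponents([np.eye(spec.size)]),
        name="glm",
    )
    return X, y, model


def make_hetero(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray, GenerativeModel]:
    """Simulate the two-block heteroskedastic regression; return (X, y, model)."""
    rng = np.random.default_rng(spec.seed)
    X = glm_design(spec.size)
    beta = np.asarray(spec.true_beta, dtype=float)
    pc = hetero_components(spec.size, 2)
    y = glm_predict(X, beta)
    for lam, Q in zip(spec.true_lambda, pc.components):
        mask = np.diag(Q) > 0
        y = y + mask * _noise(rng, lam, spec.size)
    model = GenerativeModel(
        g=lambda b: glm_predict(X, b),
        prior_beta=GaussianDensity(np.zeros(2), 16.0 * np.eye(2)),
        prior_lambda=default_hyperprior(2),
        precision=pc,
        name="glm-hetero",
    )
    return X, y, model


def make_decay(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray, GenerativeModel]:
    """Simulate noisy exponential decay; return (times, y, model)."""
    rng = np.random.default_rng(spec.seed)
    times = np.linspace(0.0, float(spec.extras["duration"]), spec.size)
    x0 = float(spec.extras["x0"])
    beta0 = spec.true_beta[0]
    clean = x0 * np.exp(-np.exp(beta0) * times)
    y = clean + _noise(rng, spec.true_lambda[0], spec.size)
    ssm = StateSpaceModel(
        f=lambda x, b, u: np.array([decay_field(x[0], b[0])]),
        obs=lambda x: x,
        x0=np.array([x0]),
        times=times,
    )
    model = GenerativeModel(
        g=as_observation_function(ssm),
        prior_beta=GaussianDensity(np.zeros(1), np.eye(1)),
        prior_lambda=default_hyperprior(1),
        precision=PrecisionComponents([np.eye(spec.size)]),
        name="decay",
    )
    return times, y, model


def boxcar(
    times: np.ndarray, start: float, on: float, period: float
) -> np.ndarray:
    """Periodic boxcar input train: 1 during [start + k*period, start + k*period + on)."""
    t = np.asarray(times, dtype=float)
    phase = np.mod(t - start, period)
    return ((t >= start) & (phase < on)).astype(float)


def hemo_state_space(
    times: np.ndarray,
    inputs: np.ndarray,
    consts: HemodynamicConstants,
    substeps: int = 4,
) -> StateSpaceModel:
    """Balloon-model state space over (s, f_in, v, q) with BOLD observation.

    Parameters enter as beta = (ln tau_h, ln kappa, efficacy).
    """

    param_cache: dict[bytes, HemodynamicParams] = {}

    def f(x, beta, u):
        # one parameter transform per trajectory, not per field evaluation
        key = beta.tobytes()
        params = param_cache.get(key)
        if params is None:
            if len(param_cache) > 64:
                param_cache.clear()
            params = HemodynamicParams.from_unconstrained(beta)
            param_cache[key] = params
        return hemo_field(x, params, consts, float(u[0]) if u.size else 0.0)

    return StateSpaceModel(
        f=f,
        obs=lambda x: np.array([bold_observation(x[2], x[3], consts)]),
        x0=np.array([0.0, 1.0, 1.0, 1.0]),
        times=times,
        inputs=np.asarray(inputs, dtype=float).reshape(-1, 1),
        substeps=substeps,
    )


def make_hemo(
    spec: FixtureSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GenerativeModel]:
    """Simulate a BOLD run from the balloon model; return (times, inputs, y, model)."""
    rng = np.random.default_rng(spec.seed)
    ex = spec.extras
    times = np.arange(spec.size, dtype=float) * float(ex["TR"])
    inputs = boxcar(times, ex["box_start"], ex["box_on"], ex["box_period"])
    consts = ex.get("constants", HemodynamicConstants())
    ssm_gen = hemo_state_space(
        times, inputs, consts, substeps=int(ex.get("gen_substeps", ex["substeps"]))
    )
    clean = as_observation_function(ssm_gen)(np.asarray(spec.true_beta, dtype=float))
    ssm = hemo_state_space(times, inputs, consts, substeps=int(ex["substeps"]))
    g = as_observation_function(ssm)
    y = clean + _noise(rng, spec.true_lambda[0], clean.size)
    model = GenerativeModel(
        g=g,
        prior_beta=GaussianDensity(
            np.array([np.log(2.0), np.log(0.64), 0.0]),
            np.diag([1.0 / 16.0, 1.0 / 16.0, 1.0]),
        ),
        prior_lambda=default_hyperprior(1),
        precision=PrecisionComponents([np.eye(clean.size)]),
        name="hemo",
    )
    return times, inputs, y, model
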