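"""Generative-model data types and the precision-component noise model.

A model is specified by an observation function ``g`` mapping a parameter
vector ``beta`` (length ``p``) to a predicted data vector (length ``D``),
Gaussian priors on the parameters and on the log-precision hyperparameters
``lambda`` (length ``h``), and a set of ``K = h`` fixed precision-component
matrices ``Q_k``.  The modelled noise precision is the positivity-enforcing
mixture

    Pi_y(lambda) = sum_k exp(lambda_k) * Q_k,

so each hyperparameter is the log of the weight on one component.  At its
simplest, a single identity component makes ``lambda_1`` the log precision
of i.i.d. observation noise; block-diagonal 0/1 components model
heteroskedastic channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import DegenerateModelError, EvaluationError, InputError

__all__ = [
    "PrecisionComponents",
    "GaussianDensity",
    "GenerativeModel",
    "ErrorTerms",
    "precision_matrix",
    "component_derivative",
    "error_terms",
    "default_hyperprior",
]

_SYM_TOL = 1e-10


def _as_matrix(a, name: str) -> np.ndarray:
    m = np.asarray(a, dtype=float)
    if m.ndim == 1:
        m = np.diag(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InputError(f"{name} must be a square matrix, got shape {m.shape}")
    return m


@dataclass(frozen=True)
class PrecisionComponents:
    """Fixed symmetric PSD matrices whose exp(lambda)-weighted sum is the noise precision.

    Diagonal components may be given as 1-D arrays; everything is stored dense
    (data dimension is small at desk scale).  Component order is significant:
    ``lambda_k`` always weights ``components[k]``.
    """

    components: tuple[np.ndarray, ...]

    def __init__(self, components: Sequence[np.ndarray]):
        mats = tuple(_as_matrix(q, f"Q_{k + 1}") for k, q in enumerate(components))
        if len(mats) < 1:
            raise InputError("at least one precision component is required")
        dim = mats[0].shape[0]
        for k, q in enumerate(mats):
            if q.shape != (dim, dim):
                raise InputError(
                    f"Q_{k + 1} has shape {q.shape}, expected ({dim}, {dim})"
                )
            if not np.allclose(q, q.T, atol=_SYM_TOL):
                raise InputError(f"Q_{k + 1} is not symmetric")
            if np.linalg.eigvalsh(q).min() < -1e-8:
                raise InputError(f"Q_{k + 1} is not positive semidefinite")
        if np.linalg.eigvalsh(sum(mats)).min() <= 1e-12:
            raise InputError(
                "sum of precision components must be positive definite"
            )
        object.__setattr__(self, "components", mats)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def dim(self) -> int:
        return self.components[0].shape[0]


@dataclass(frozen=True)
class GaussianDensity:
    """A multivariate normal, used for priors and approximate posteriors.

    Stored as mean and covariance; the covariance must be symmetric positive
    definite (improper/zero-precision priors are out of scope).
    """

    mean: np.ndarray
    cov: np.ndarray

    def __init__(self, mean, cov):
        m = np.atleast_1d(np.asarray(mean, dtype=float))
        c = _as_matrix(cov, "covariance")
        if m.ndim != 1:
            raise InputError("mean must be a vector")
        if c.shape[0] != m.size:
            raise InputError(
                f"covariance order {c.shape[0]} does not match mean length {m.size}"
            )
        if not np.allclose(c, c.T, atol=_SYM_TOL):
            raise InputError("covariance is not symmetric")
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError as exc:
            raise InputError("covariance is not positive definite") from exc
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "cov", c)

    @property
    def dim(self) -> int:
        return self.mean.size

    @property
    def precision(self) -> np.ndarray:
        """Inverse covariance (computed on demand via a symmetric solve)."""
        identity = np.eye(self.dim)
        chol = np.linalg.cholesky(self.cov)
        half = np.linalg.solve(chol, identity)
        return half.T @ half

    def logdet_cov(self) -> float:
        chol = np.linalg.cholesky(self.cov)
        return 2.0 * float(np.sum(np.log(np.diag(chol))))


def default_hyperprior(h: int) -> GaussianDensity:
    """Weakly informative default prior on log precisions: N(0, 16 I).

    A proper hyperprior is required for the free energy to be finite; this
    default admits precisions over many orders of magnitude while keeping the
    posterior well defined.  Override whenever prior information exists.
    """
    return GaussianDensity(np.zeros(h), 16.0 * np.eye(h))


@dataclass(frozen=True)
class GenerativeModel:
    """Observation function + priors + noise precision components.

    ``g`` maps a parameter vector of length ``p`` to a predicted data vector
    of length ``D``.  The number of hyperparameters equals the number of
    precision components.
    """

    g: Callable[[np.ndarray], np.ndarray]
    prior_beta: GaussianDensity
    prior_lambda: GaussianDensity
    precision: PrecisionComponents
    name: str = field(default="model")

    def __post_init__(self):
        object.__setattr__(self, "_predict_cache", {})
        if self.prior_lambda.dim != self.precision.n_components:
            raise InputError(
                f"{self.prior_lambda.dim} hyperparameters for "
                f"{self.precision.n_components} precision components; "
                "one log-precision per component is required"
            )
        pred = self.predict(self.prior_beta.mean)
        if pred.size != self.precision.dim:
            raise InputError(
                f"g returned length {pred.size}, precision components are "
                f"{self.precision.dim}x{self.precision.dim}"
            )

    @property
    def n_params(self) -> int:
        return self.prior_beta.dim

    @property
    def n_hyper(self) -> int:
        return self.prior_lambda.dim

    @property
    def n_data(self) -> int:
        return self.precision.dim

    def predict(self, beta: np.ndarray) -> np.ndarray:
        """Evaluate g with finiteness checking.

        Results are memoised on the exact parameter vector: g is pure, and
        one ascent iteration evaluates the prediction at the same point from
        several routines, which matters when g integrates an ODE.
        """
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        cache: dict = self._predict_cache  # type: ignore[attr-defined]
        key = beta.tobytes()
        hit = cache.get(key)
        if hit is not None:
            return hit
        out = np.atleast_1d(np.asarray(self.g(beta), dtype=float)).ravel()
        if not np.all(np.isfinite(out)):
            raise EvaluationError(
                "observation function returned non-finite values", beta=beta
            )
        if len(cache) > 128:
            cache.clear()
        cache[key] = out
        return out


@dataclass(frozen=True)
class ErrorTerms:
    """Residuals of data, parameters and hyperparameters from their expectations."""

    eps_y: np.ndarray
    eps_beta: np.ndarray
    eps_lambda: np.ndarray


def precision_matrix(pc: PrecisionComponents, lam: np.ndarray) -> np.ndarray:
    """Noise precision Pi_y(lambda) = sum_k exp(lambda_k) Q_k.

    Raises a degenerate-model error if the weighted sum is numerically
    singular (e.g. extremely negative log precisions on all components).
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if lam.size != pc.n_components:
        raise InputError(
            f"lambda has length {lam.size}, expected {pc.n_components}"
        )
    if not np.all(np.isfinite(lam)):
        raise InputError("lambda must be finite")
    weights = np.exp(lam)
    out = np.zeros((pc.dim, pc.dim))
    for w, q in zip(weights, pc.components):
        out += w * q
    out = 0.5 * (out + out.T)
    try:
        np.linalg.cholesky(out)
    except np.linalg.LinAlgError as exc:
        raise DegenerateModelError(
            f"noise precision is numerically singular at lambda={lam}"
        ) from exc
    return out


def component_derivative(
    pc: PrecisionComponents, lam: np.ndarray, i: int
) -> np.ndarray:
    """P_i = d Pi_y / d lambda_i = exp(lambda_i) Q_i (1-based index ``i``)."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if not 1 <= i <= pc.n_components:
        raise InputError(
            f"component index {i} out of range 1..{pc.n_components}"
        )
    return np.exp(lam[i - 1]) * pc.components[i - 1]


def error_terms(
    model: GenerativeModel,
    y: np.ndarray,
    mu_beta: np.ndarray,
    mu_lambda: np.ndarray,
) -> ErrorTerms:
    """Residual vectors: data minus prediction, and posterior minus prior means."""
    y = np.atleast_1d(np.asarray(y, dtype=float)).ravel()
    mu_beta = np.atleast_1d(np.asarray(mu_beta, dtype=float))
    mu_lambda = np.atleast_1d(np.asarray(mu_lambda, dtype=float))
    if y.size != model.n_data:
        raise InputError(f"data length {y.size}, model expects {model.n_data}")
    if mu_beta.size != model.n_params:
        raise InputError(
            f"mu_beta length {mu_beta.size}, model has {model.n_params} parameters"
        )
    if mu_lambda.size != model.n_hyper:
        raise InputError(
            f"mu_lambda length {mu_lambda.size}, model has {model.n_hyper} hyperparameters"
        )
    return ErrorTerms(
        eps_y=y - model.predict(mu_beta),
        eps_beta=mu_beta - model.prior_beta.mean,
        eps_lambda=mu_lambda - model.prior_lambda.mean,
    )
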