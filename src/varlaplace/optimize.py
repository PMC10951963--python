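"""Free-energy ascent by alternating mean-field updates with adaptive regularization.

The scheme alternates between updating the Gaussian posterior over the noise
log precisions Q(lambda) and over the model parameters Q(beta).  Each mean
update integrates the gradient-flow ODE ``mu_dot = grad`` over a finite time
``t`` using local linearization,

    d_mu = (expm(t H) - I) H^-1 grad,

where H is the (negative-definite) curvature.  Small ``t`` gives a cautious
gradient step; by around t = 2 the update is indistinguishable from a full
Gauss-Newton step.  The integration time is controlled by a log step-size
``v`` scaled by the geometric-mean curvature magnitude, increased when an
update improves the free energy and decreased (with the previous state
restored) when it does not.  Posterior covariances come from the same
curvatures: Sigma_beta = (J' Pi_y J + Pi_beta)^-1 and a diagonal Sigma_lambda.

Second derivatives of the observation function are omitted throughout, i.e.
the model is treated as locally approximately linear (Gauss-Newton).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import cho_factor, cho_solve, expm, LinAlgError

from .core import (
    GaussianDensity,
    GenerativeModel,
    component_derivative,
    error_terms,
    precision_matrix,
)
from .exceptions import (
    ConditioningError,
    DomainError,
    EvaluationError,
    InputError,
    IntegrationError,
)
from .free_energy import FreeEnergyBreakdown, laplace_free_energy

__all__ = [
    "OptimizerConfig",
    "IterationRecord",
    "VLResult",
    "numerical_jacobian",
    "beta_gradient",
    "beta_curvature",
    "lambda_gradient",
    "lambda_curvature",
    "local_linear_step",
    "step_time",
    "fit_vl",
]

logger = logging.getLogger("varlaplace")

_PRECISION_FLOOR = 1e-8


@dataclass(frozen=True)
class OptimizerConfig:
    """Tunable knobs of the ascent.

    ``v0`` is the initial log step (-4: cautious, near-gradient behaviour),
    capped at ``v_max`` (4: effectively a full Gauss-Newton step).  ``v`` is
    raised by ``v_up`` after an iteration that improves the free energy and
    dropped by ``v_down`` (with state restored) after one that does not.
    Convergence is declared when the improvement predicted by the local
    quadratic model stays below ``convergence_tol`` nats for
    ``convergence_window`` consecutive iterations.
    """

    v0: float = -4.0
    v_max: float = 4.0
    v_up: float = 0.5
    v_down: float = 2.0
    max_iterations: int = 128
    inner_lambda_steps: int = 8
    convergence_tol: float = 0.1
    convergence_window: int = 4
    fd_step: float = 1e-4
    seed: int | None = None

    def __post_init__(self):
        if self.v0 > self.v_max:
            raise InputError("v0 must not exceed v_max")
        if self.max_iterations < 1:
            raise InputError("max_iterations must be >= 1")
        if self.convergence_tol <= 0 or self.fd_step <= 0:
            raise InputError("tolerances must be positive")


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    free_energy: float
    v: float
    accepted: bool
    predicted_improvement: float


@dataclass(frozen=True)
class VLResult:
    """Posterior factors, maximised free energy and the per-iteration trace."""

    q_beta: GaussianDensity
    q_lambda: GaussianDensity
    free_energy: float
    breakdown: FreeEnergyBreakdown
    trace: tuple[IterationRecord, ...]
    converged: bool
    iterations: int

    def to_dict(self) -> dict:
        return {
            "posterior_beta": {
                "mean": self.q_beta.mean.tolist(),
                "cov": self.q_beta.cov.tolist(),
            },
            "posterior_lambda": {
                "mean": self.q_lambda.mean.tolist(),
                "cov": self.q_lambda.cov.tolist(),
            },
            "free_energy": self.free_energy,
            "breakdown": self.breakdown.to_dict(),
            "converged": self.converged,
            "iterations": self.iterations,
            "trace": [
                {
                    "iteration": r.iteration,
                    "F": r.free_energy,
                    "v": r.v,
                    "accepted": r.accepted,
                    "predicted_improvement": r.predicted_improvement,
                }
                for r in self.trace
            ],
        }


def numerical_jacobian(
    g: Callable[[np.ndarray], np.ndarray], mu: np.ndarray, fd_step: float = 1e-4
) -> np.ndarray:
    """Central-difference Jacobian of ``g`` at ``mu`` (D x p).

    The perturbation of parameter j is ``fd_step * max(1, |mu_j|)`` so the
    step is relative for large parameters and absolute near zero.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    cols = []
    for j in range(mu.size):
        delta = fd_step * max(1.0, abs(mu[j]))
        up = mu.copy()
        dn = mu.copy()
        up[j] += delta
        dn[j] -= delta
        fu = np.asarray(g(up), dtype=float).ravel()
        fd = np.asarray(g(dn), dtype=float).ravel()
        if not (np.all(np.isfinite(fu)) and np.all(np.isfinite(fd))):
            raise EvaluationError(
                f"observation function non-finite when perturbing parameter {j}",
                beta=mu,
                index=j,
            )
        cols.append((fu - fd) / (2.0 * delta))
    return np.column_stack(cols)


def _prior_precisions(model: GenerativeModel):
    return model.prior_beta.precision, model.prior_lambda.precision


def beta_gradient(
    model: GenerativeModel,
    y: np.ndarray,
    q_beta: GaussianDensity,
    q_lambda: GaussianDensity,
    J: np.ndarray,
) -> np.ndarray:
    """Gradient of the variational energy I_beta at the current means.

    Likelihood pull J' Pi_y e_y, prior pull -Pi_beta e_beta, plus the
    hyperparameter-uncertainty correction weighting each component
    derivative by half the posterior variance of its log precision (the
    factor that makes this the exact gradient of the variational energy,
    as the finite-difference cross-checks verify).
    """
    eps = error_terms(model, y, q_beta.mean, q_lambda.mean)
    pi_y = precision_matrix(model.precision, q_lambda.mean)
    pi_b = model.prior_beta.precision
    grad = J.T @ (pi_y @ eps.eps_y) - pi_b @ eps.eps_beta
    s_ll = np.diag(q_lambda.cov)
    for j in range(model.n_hyper):
        if s_ll[j] == 0.0:
            continue
        P_j = component_derivative(model.precision, q_lambda.mean, j + 1)
        grad += 0.5 * s_ll[j] * (J.T @ (P_j @ eps.eps_y))
    return grad


def beta_curvature(
    model: GenerativeModel, q_lambda: GaussianDensity, J: np.ndarray
) -> np.ndarray:
    """Negative-definite curvature -(J' Pi_y J + Pi_beta); its negative inverse is Sigma_beta."""
    pi_y = precision_matrix(model.precision, q_lambda.mean)
    pi_b = model.prior_beta.precision
    H = -(J.T @ pi_y @ J + pi_b)
    return 0.5 * (H + H.T)


def lambda_gradient(
    model: GenerativeModel,
    y: np.ndarray,
    q_beta: GaussianDensity,
    q_lambda: GaussianDensity,
    J: np.ndarray,
) -> np.ndarray:
    """Gradient of the variational energy I_lambda, elementwise over components.

    Element i balances the expected degrees of freedom carried by component i
    (trace term) against the weighted squared residuals, the hyperprior pull,
    and the parameter-uncertainty correction tr(Sigma_beta J' P_i J)/2.
    """
    eps = error_terms(model, y, q_beta.mean, q_lambda.mean)
    pi_y = precision_matrix(model.precision, q_lambda.mean)
    cf_y = cho_factor(pi_y, lower=True)
    pi_l = model.prior_lambda.precision
    prior_pull = pi_l @ eps.eps_lambda
    grad = np.empty(model.n_hyper)
    for i in range(model.n_hyper):
        P_i = component_derivative(model.precision, q_lambda.mean, i + 1)
        tr_data = float(np.trace(cho_solve(cf_y, P_i)))
        quad = float(eps.eps_y @ P_i @ eps.eps_y)
        tr_beta = float(np.trace(q_beta.cov @ (J.T @ P_i @ J)))
        grad[i] = 0.5 * tr_data - 0.5 * quad - prior_pull[i] - 0.5 * tr_beta
    return grad


def lambda_curvature(
    model: GenerativeModel,
    y: np.ndarray,
    q_beta: GaussianDensity,
    q_lambda: GaussianDensity,
    J: np.ndarray,
) -> np.ndarray:
    """Diagonal negative-definite curvature of I_lambda.

    The posterior precision of each log precision is floored at a small
    positive value before inversion; the mean-field treatment keeps only the
    diagonal.
    """
    eps = error_terms(model, y, q_beta.mean, q_lambda.mean)
    pi_y = precision_matrix(model.precision, q_lambda.mean)
    cf_y = cho_factor(pi_y, lower=True)
    pi_l = model.prior_lambda.precision
    prec = np.empty(model.n_hyper)
    for i in range(model.n_hyper):
        P_i = component_derivative(model.precision, q_lambda.mean, i + 1)
        PS = cho_solve(cf_y, P_i.T).T  # P_i Sigma_y
        tr_term = float(np.trace(PS) - np.sum(PS * PS.T))
        quad = float(eps.eps_y @ P_i @ eps.eps_y)
        tr_beta = float(np.trace(q_beta.cov @ (J.T @ P_i @ J)))
        prec[i] = pi_l[i, i] - 0.5 * tr_term + 0.5 * quad + 0.5 * tr_beta
    if np.any(~np.isfinite(prec)):
        raise ConditioningError(
            f"non-finite hyperparameter precision: {prec}"
        )
    prec = np.maximum(prec, _PRECISION_FLOOR)
    return -np.diag(prec)


def local_linear_step(
    grad: np.ndarray, curvature: np.ndarray, t: float
) -> np.ndarray:
    """Integrate the gradient flow for time t: (expm(t H) - I) H^-1 grad.

    Evaluated through the matrix exponential of the augmented system
    [[H, grad], [0, 0]], which avoids explicitly inverting H and remains
    well defined when H is nearly singular.
    """
    if t <= 0:
        raise InputError("integration time t must be positive")
    grad = np.atleast_1d(np.asarray(grad, dtype=float))
    H = np.atleast_2d(np.asarray(curvature, dtype=float))
    n = grad.size
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = t * H
    aug[:n, n] = t * grad
    phi = expm(aug)
    step = phi[:n, n]
    if not np.all(np.isfinite(step)):
        raise ConditioningError("matrix exponential overflowed in update step")
    return step


def step_time(v: float, curvature: np.ndarray) -> float:
    """Integration time t = exp(v) / alpha with alpha the geometric-mean curvature magnitude.

    alpha = exp(ln|det H| / n) so an isotropic curvature -c I gives
    t = exp(v)/c regardless of dimension: steeper landscapes get shorter
    integration times, i.e. more regularization.
    """
    H = np.atleast_2d(np.asarray(curvature, dtype=float))
    sign, logdet = np.linalg.slogdet(H)
    if sign == 0 or not np.isfinite(logdet):
        raise ConditioningError("curvature is singular; cannot scale step time")
    alpha = float(np.exp(logdet / H.shape[0]))
    return float(np.exp(v)) / alpha


def _solve_spd(mat: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Symmetric positive-definite solve with a single jittered retry."""
    try:
        return cho_solve(cho_factor(mat, lower=True), rhs)
    except (LinAlgError, ValueError):
        jitter = 1e-10 * np.trace(mat) / mat.shape[0]
        try:
            return cho_solve(
                cho_factor(mat + jitter * np.eye(mat.shape[0]), lower=True), rhs
            )
        except (LinAlgError, ValueError) as exc:
            raise ConditioningError(
                "posterior precision could not be factorised"
            ) from exc


def _posterior_beta_cov(model, q_lambda, J) -> np.ndarray:
    pi_y = precision_matrix(model.precision, q_lambda.mean)
    prec = J.T @ pi_y @ J + model.prior_beta.precision
    cov = _solve_spd(prec, np.eye(model.n_params))
    return 0.5 * (cov + cov.T)


def fit_vl(
    model: GenerativeModel,
    y: np.ndarray,
    config: OptimizerConfig | None = None,
) -> VLResult:
    """Maximise the free energy; return posterior factors, F and the trace.

    Each outer iteration, starting from the best state found so far:
    re-evaluate the Jacobian; take up to ``inner_lambda_steps`` local-linear
    hyperparameter updates; refresh both posterior covariances; take one
    local-linear parameter update; then evaluate F.  An improvement is
    accepted and loosens the regularization (v up); a worsening restores the
    previous state and tightens it (v down).  The procedure is deterministic:
    identical inputs yield bit-identical results.
    """
    if config is None:
        config = OptimizerConfig()
    y = np.atleast_1d(np.asarray(y, dtype=float)).ravel()
    if y.size != model.n_data:
        raise InputError(f"data length {y.size}, model expects {model.n_data}")

    mu_b = model.prior_beta.mean.copy()
    mu_l = model.prior_lambda.mean.copy()
    v = config.v0

    def _evaluate(mu_b, mu_l):
        """Consistent state at given means: covariances from local curvature, then F."""
        J = numerical_jacobian(model.predict, mu_b, config.fd_step)
        cov_b = _posterior_beta_cov(model, GaussianDensity(mu_l, _tiny_eye(mu_l)), J)
        q_b = GaussianDensity(mu_b, cov_b)
        q_l_point = GaussianDensity(mu_l, _tiny_eye(mu_l))
        Hl = lambda_curvature(model, y, q_b, q_l_point, J)
        cov_l = np.diag(1.0 / np.maximum(-np.diag(Hl), _PRECISION_FLOOR))
        q_l = GaussianDensity(mu_l, cov_l)
        F = laplace_free_energy(model, y, q_b, q_l)
        return J, q_b, q_l, F

    try:
        J, q_b, q_l, F = _evaluate(mu_b, mu_l)
    except EvaluationError:
        raise
    if not np.isfinite(F.total):
        raise ConditioningError("free energy non-finite at the prior means")

    best = {"q_b": q_b, "q_l": q_l, "F": F, "J": J}
    trace: list[IterationRecord] = []
    streak = 0
    converged = False
    n_iter = 0

    for it in range(1, config.max_iterations + 1):
        n_iter = it
        mu_b = best["q_b"].mean.copy()
        mu_l = best["q_l"].mean.copy()
        J = best["J"]

        rejected_midway = False
        try:
            # --- hyperparameter updates (shared v) ---
            q_b_tmp = best["q_b"]
            for _ in range(config.inner_lambda_steps):
                q_l_tmp = GaussianDensity(mu_l, _tiny_eye(mu_l))
                gl = lambda_gradient(model, y, q_b_tmp, q_l_tmp, J)
                Hl = lambda_curvature(model, y, q_b_tmp, q_l_tmp, J)
                t_l = step_time(v, Hl)
                dl = local_linear_step(gl, Hl, t_l)
                mu_l = mu_l + dl
                q_b_tmp = GaussianDensity(
                    mu_b, _posterior_beta_cov(model, GaussianDensity(mu_l, _tiny_eye(mu_l)), J)
                )
                if float(np.abs(dl).max()) < 1e-12:
                    break

            # --- parameter update ---
            q_l_mid = GaussianDensity(
                mu_l,
                np.diag(
                    1.0
                    / np.maximum(
                        -np.diag(lambda_curvature(model, y, q_b_tmp, GaussianDensity(mu_l, _tiny_eye(mu_l)), J)),
                        _PRECISION_FLOOR,
                    )
                ),
            )
            gb = beta_gradient(model, y, q_b_tmp, q_l_mid, J)
            Hb = beta_curvature(model, q_l_mid, J)
            t_b = step_time(v, Hb)
            db = local_linear_step(gb, Hb, t_b)
            # predicted improvement of the full quadratic (Gauss-Newton) step:
            # scale-free in v, so stalling under heavy regularization is not
            # mistaken for convergence
            predicted = float(gb @ _solve_spd(-Hb, gb))
            mu_b = mu_b + db

            # --- evaluate the candidate ---
            J_new, q_b_new, q_l_new, F_new = _evaluate(mu_b, mu_l)
        except (EvaluationError, ConditioningError, IntegrationError, DomainError):
            # candidate state is not evaluable: treat as a worsening step
            rejected_midway = True
            F_new = None
            predicted = float("inf")

        if (not rejected_midway) and not np.isfinite(F_new.total):
            raise ConditioningError(
                f"free energy became non-finite at iteration {it}; trace={trace}"
            )

        if (not rejected_midway) and F_new.total > best["F"].total:
            best = {"q_b": q_b_new, "q_l": q_l_new, "F": F_new, "J": J_new}
            accepted = True
            v = min(v + config.v_up, config.v_max)
        else:
            accepted = False
            v = v - config.v_down

        F_report = F_new.total if (not rejected_midway) else float("nan")
        trace.append(
            IterationRecord(
                iteration=it,
                free_energy=best["F"].total if not accepted else F_report,
                v=v,
                accepted=accepted,
                predicted_improvement=predicted,
            )
        )
        logger.info(
            "iter=%d F=%.6f v=%.2f accepted=%s", it, best["F"].total, v, accepted
        )

        if predicted < config.convergence_tol:
            streak += 1
        else:
            streak = 0
        if streak >= config.convergence_window:
            converged = True
            break

    if not converged:
        logger.warning(
            "fit_vl reached max_iterations=%d without convergence",
            config.max_iterations,
        )

    return VLResult(
        q_beta=best["q_b"],
        q_lambda=best["q_l"],
        free_energy=best["F"].total,
        breakdown=best["F"],
        trace=tuple(trace),
        converged=converged,
        iterations=n_iter,
    )


def _tiny_eye(mu: np.ndarray) -> np.ndarray:
    """Placeholder SPD covariance for intermediate point-mass densities."""
    return 1e-12 * np.eye(np.atleast_1d(mu).size)
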