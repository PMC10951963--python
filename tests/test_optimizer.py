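import numpy as np
import pytest

import varlaplace as vl
from varlaplace.exceptions import InputError
from varlaplace.optimize import OptimizerConfig
from varlaplace.validation import (
    PRECISE,
    clamp_lambda,
    conjugate_posterior,
)
from conftest import linear_gaussian_instance


class TestNumericalJacobian:
    def test_linear_map_recovered_exactly(self, rng):
        X = rng.normal(size=(7, 3))
        J = vl.numerical_jacobian(lambda b: X @ b, rng.normal(size=3))
        np.testing.assert_allclose(J, X, atol=1e-8)

    def test_scalar_exponential(self):
        J = vl.numerical_jacobian(lambda b: np.exp(b), np.array([0.0]))
        assert J[0, 0] == pytest.approx(1.0, abs=1e-8)

    def test_cubic_against_analytic_derivative(self, rng):
        f = lambda b: np.array([b[0] ** 3 - 2 * b[0]])
        df = lambda x: 3 * x**2 - 2
        for x in rng.uniform(-2, 2, 20):
            J = vl.numerical_jacobian(f, np.array([x]), fd_step=1e-5)
            assert J[0, 0] == pytest.approx(df(x), abs=1e-6)


def _log_joint(model, y, beta, lam):
    """Exact log joint ln P(y, beta, lambda) — oracle building block."""
    pi_y = vl.precision_matrix(model.precision, lam)
    return (
        vl.log_mvnormal(y, model.predict(beta), np.linalg.inv(pi_y))
        + vl.log_mvnormal(beta, model.prior_beta.mean, model.prior_beta.cov)
        + vl.log_mvnormal(lam, model.prior_lambda.mean, model.prior_lambda.cov)
    )


def _small_instance(rng, h=1):
    D, p = 9, 2
    X = rng.normal(size=(D, p))
    if h == 1:
        pc = vl.PrecisionComponents([np.eye(D)])
    else:
        pc = vl.hetero_components(D, h)
    model = vl.GenerativeModel(
        g=lambda b: X @ b,
        prior_beta=vl.GaussianDensity(np.zeros(p), np.diag([2.0, 0.7])),
        prior_lambda=vl.GaussianDensity(np.zeros(h), 4.0 * np.eye(h)),
        precision=pc,
    )
    y = rng.normal(size=D)
    return X, y, model


class TestBetaGradient:
    def test_unit_case(self, scalar_model):
        """One observation y=1, identity map, unit noise and prior, start at 0."""
        q_b = vl.GaussianDensity([0.0], [[1.0]])
        q_l = vl.GaussianDensity([0.0], [[1e-12]])  # suppress hyper-uncertainty term
        J = np.array([[1.0]])
        grad = vl.beta_gradient(scalar_model, np.array([1.0]), q_b, q_l, J)
        assert grad[0] == pytest.approx(1.0, abs=1e-9)

    def test_vanishes_at_conjugate_posterior_mean(self, rng):
        X, y, lam_star, model = linear_gaussian_instance(rng, p=2, D=12)
        post = conjugate_posterior(
            X, y, np.exp(lam_star) * np.eye(12), model.prior_beta
        )
        q_l = vl.GaussianDensity([lam_star], [[1e-12]])
        grad = vl.beta_gradient(model, y, post, q_l, X)
        assert np.abs(grad).max() < 1e-8

    def test_matches_finite_difference_of_variational_energy(self, rng):
        """Gradient equals the central difference of
        I_beta(b) = ln P(y,b,mu_l) + tr(Sigma_l * d2/dl2 ln P)/2 (linear g)."""
        X, y, model = _small_instance(rng)
        mu_b = rng.normal(0, 0.5, 2)
        mu_l = np.array([0.2])
        s_ll = np.array([0.3])
        q_b = vl.GaussianDensity(mu_b, 0.1 * np.eye(2))
        q_l = vl.GaussianDensity(mu_l, np.diag(s_ll))

        def d2_lambda(beta):
            # second lambda-derivative of the log joint, written out directly
            # (definitional part of the Eq-39-style energy, not under test):
            # tr(-Sy P Sy P + Sy P)/2 - eps' P eps / 2 - prior precision
            eps = y - X @ beta
            pi_y = np.exp(mu_l[0]) * np.eye(y.size)
            P = pi_y  # single identity component
            Sy = np.linalg.inv(pi_y)
            tr = 0.5 * np.trace(-Sy @ P @ Sy @ P + Sy @ P)
            return (
                tr
                - 0.5 * eps @ P @ eps
                - model.prior_lambda.precision[0, 0]
            )

        def I_beta(beta):
            return _log_joint(model, y, beta, mu_l) + 0.5 * s_ll[0] * d2_lambda(beta)

        grad = vl.beta_gradient(model, y, q_b, q_l, X)
        for j in range(2):
            d = 1e-5
            e = np.zeros(2)
            e[j] = d
            fd = (I_beta(mu_b + e) - I_beta(mu_b - e)) / (2 * d)
            assert grad[j] == pytest.approx(fd, abs=1e-5)


class TestBetaCurvature:
    def test_two_unit_observations(self):
        X = np.array([[1.0], [1.0]])
        model = vl.GenerativeModel(
            g=lambda b: X @ b,
            prior_beta=vl.GaussianDensity([0.0], [[1.0]]),
            prior_lambda=clamp_lambda([0.0]),
            precision=vl.PrecisionComponents([np.eye(2)]),
        )
        q_l = vl.GaussianDensity([0.0], [[1e-12]])
        H = vl.beta_curvature(model, q_l, X)
        assert H[0, 0] == pytest.approx(-3.0)

    def test_vanishing_data_precision_returns_prior(self):
        X = np.array([[1.0], [1.0]])
        model = vl.GenerativeModel(
            g=lambda b: X @ b,
            prior_beta=vl.GaussianDensity([0.0], [[0.5]]),
            prior_lambda=clamp_lambda([-40.0]),
            precision=vl.PrecisionComponents([np.eye(2)]),
        )
        q_l = vl.GaussianDensity([-40.0], [[1e-12]])
        H = vl.beta_curvature(model, q_l, X)
        np.testing.assert_allclose(-np.linalg.inv(H), model.prior_beta.cov, rtol=1e-8)

    def test_matches_conjugate_posterior_covariance(self, rng):
        X, y, lam_star, model = linear_gaussian_instance(rng, p=3, D=20)
        post = conjugate_posterior(
            X, y, np.exp(lam_star) * np.eye(20), model.prior_beta
        )
        q_l = vl.GaussianDensity([lam_star], [[1e-12]])
        H = vl.beta_curvature(model, q_l, X)
        np.testing.assert_allclose(-np.linalg.inv(H), post.cov, atol=1e-10)


class TestLambdaGradientAndCurvature:
    def _point_masses(self, n, lam=0.0):
        q_b = vl.GaussianDensity([0.0], [[1e-14]])
        q_l = vl.GaussianDensity([lam], [[1e-12]])
        return q_b, q_l

    def _unit_model(self, n, prior_prec=1e-12):
        # g == 0 so residuals equal the data; effectively no hyperprior force
        return vl.GenerativeModel(
            g=lambda b: np.zeros(n),
            prior_beta=vl.GaussianDensity([0.0], [[1e-14]]),
            prior_lambda=vl.GaussianDensity(
                [0.0], [[1.0 / prior_prec]]
            ),
            precision=vl.PrecisionComponents([np.eye(n)]),
        )

    def test_zero_at_ml_precision(self):
        """With eps'eps = n at lambda = 0, the n/2 terms cancel exactly."""
        n = 6
        model = self._unit_model(n)
        y = np.ones(n)  # eps'eps = n
        q_b, q_l = self._point_masses(n)
        J = np.zeros((n, 1))
        grad = vl.lambda_gradient(model, y, q_b, q_l, J)
        assert grad[0] == pytest.approx(0.0, abs=1e-9)

    def test_pushes_precision_up_for_perfect_fit(self):
        n = 6
        model = self._unit_model(n)
        q_b, q_l = self._point_masses(n)
        J = np.zeros((n, 1))
        grad = vl.lambda_gradient(model, np.zeros(n), q_b, q_l, J)
        assert grad[0] == pytest.approx(n / 2)

    def test_matches_finite_difference_of_variational_energy(self, rng):
        """Element i equals the central difference of
        I_lambda(l) = ln P(y,mu_b,l) + tr(Sigma_b * d2/db2 ln P)/2 with fixed Sigma_b."""
        X, y, model = _small_instance(rng, h=2)
        mu_b = rng.normal(0, 0.5, 2)
        cov_b = np.array([[0.05, 0.01], [0.01, 0.08]])
        q_b = vl.GaussianDensity(mu_b, cov_b)
        mu_l = np.array([0.1, -0.3])
        q_l = vl.GaussianDensity(mu_l, 0.1 * np.eye(2))

        def I_lambda(lam):
            pi_y = vl.precision_matrix(model.precision, lam)
            hess_b = -(X.T @ pi_y @ X + model.prior_beta.precision)
            return _log_joint(model, y, mu_b, lam) + 0.5 * np.trace(cov_b @ hess_b)

        grad = vl.lambda_gradient(model, y, q_b, q_l, X)
        for i in range(2):
            d = 1e-5
            e = np.zeros(2)
            e[i] = d
            fd = (I_lambda(mu_l + e) - I_lambda(mu_l - e)) / (2 * d)
            assert grad[i] == pytest.approx(fd, abs=1e-5)

    def test_curvature_collapse_single_identity_component(self, rng):
        """At lambda = 0 with Q = I, tr(P Sy - P Sy P Sy) = 0 so the posterior
        precision is Pi_lambda + eps'eps/2 + tr(Sigma_b J'J)/2."""
        X, y, model = _small_instance(rng)
        mu_b = np.zeros(2)
        cov_b = 0.1 * np.eye(2)
        q_b = vl.GaussianDensity(mu_b, cov_b)
        q_l = vl.GaussianDensity([0.0], [[1.0]])
        H = vl.lambda_curvature(model, y, q_b, q_l, X)
        eps = y - X @ mu_b
        expected = (
            model.prior_lambda.precision[0, 0]
            + 0.5 * eps @ eps
            + 0.5 * np.trace(cov_b @ X.T @ X)
        )
        assert -H[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_prior_domination(self, rng):
        X, y, model_base = _small_instance(rng)
        model = vl.GenerativeModel(
            g=model_base.g,
            prior_beta=model_base.prior_beta,
            prior_lambda=vl.GaussianDensity([0.0], [[1e-6]]),
            precision=model_base.precision,
        )
        q_b = vl.GaussianDensity(np.zeros(2), 1e-12 * np.eye(2))
        q_l = vl.GaussianDensity([0.0], [[1e-6]])
        H = vl.lambda_curvature(model, y, q_b, q_l, X)
        assert -1.0 / H[0, 0] == pytest.approx(1e-6, rel=1e-3)

    def test_curvature_matches_numerical_hessian(self, rng):
        X, y, model = _small_instance(rng)
        mu_b = rng.normal(0, 0.3, 2)
        cov_b = 0.05 * np.eye(2)
        q_b = vl.GaussianDensity(mu_b, cov_b)
        mu_l = np.array([0.25])
        q_l = vl.GaussianDensity(mu_l, [[0.1]])

        def I_lambda(lam):
            pi_y = vl.precision_matrix(model.precision, lam)
            hess_b = -(X.T @ pi_y @ X + model.prior_beta.precision)
            return _log_joint(model, y, mu_b, lam) + 0.5 * np.trace(cov_b @ hess_b)

        d = 1e-4
        fd = (
            I_lambda(mu_l + d) - 2 * I_lambda(mu_l) + I_lambda(mu_l - d)
        ) / d**2
        H = vl.lambda_curvature(model, y, q_b, q_l, X)
        assert H[0, 0] == pytest.approx(fd, rel=1e-3)


class TestLocalLinearStep:
    def test_scalar_closed_form(self):
        step = vl.local_linear_step(np.array([1.0]), np.array([[-1.0]]), 1.0)
        assert step[0] == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_large_time_is_gauss_newton(self):
        step = vl.local_linear_step(np.array([2.0]), np.array([[-1.0]]), 50.0)
        assert step[0] == pytest.approx(2.0, abs=1e-12)

    def test_gauss_newton_limit_rates(self):
        """Within exp(-2) of the full step by t=2; indistinguishable by t=10."""
        grad = np.array([1.0])
        H = np.array([[-1.0]])
        full = 1.0
        assert abs(vl.local_linear_step(grad, H, 2.0)[0] - full) < 0.15 * full
        assert abs(vl.local_linear_step(grad, H, 10.0)[0] - full) < 1e-4

    def test_small_time_is_gradient_step(self, rng):
        for _ in range(5):
            n = int(rng.integers(1, 5))
            A = rng.normal(size=(n, n))
            H = -(A @ A.T + np.eye(n))
            grad = rng.normal(size=n)
            t = 1e-6
            step = vl.local_linear_step(grad, H, t)
            np.testing.assert_allclose(step / t, grad, atol=1e-4)

    def test_rejects_nonpositive_time(self):
        with pytest.raises(InputError):
            vl.local_linear_step(np.array([1.0]), np.array([[-1.0]]), 0.0)


class TestStepTime:
    def test_isotropic_cases(self):
        assert vl.step_time(-4.0, -np.eye(3)) == pytest.approx(np.exp(-4))
        assert vl.step_time(0.0, -4.0 * np.eye(5)) == pytest.approx(0.25)

    def test_dimension_invariance_for_isotropic_curvature(self):
        c = 2.7
        times = [vl.step_time(1.0, -c * np.eye(n)) for n in range(1, 7)]
        np.testing.assert_allclose(times, np.exp(1.0) / c, rtol=1e-12)


class TestFitVL:
    def test_matches_conjugate_posterior(self, rng):
        X, y, lam_star, model = linear_gaussian_instance(rng, p=2, D=15)
        res = vl.fit_vl(model, y, PRECISE)
        post = conjugate_posterior(
            X, y, np.exp(lam_star) * np.eye(15), model.prior_beta
        )
        np.testing.assert_allclose(res.q_beta.mean, post.mean, atol=1e-6)
        np.testing.assert_allclose(res.q_beta.cov, post.cov, atol=1e-6)

    def test_free_energy_consistent_with_returned_densities(self, rng):
        _, y, _, model = linear_gaussian_instance(rng, p=2, D=10)
        res = vl.fit_vl(model, y)
        fe = vl.laplace_free_energy(model, y, res.q_beta, res.q_lambda)
        assert fe.total == pytest.approx(res.free_energy, abs=1e-10)

    def test_deterministic(self, rng):
        _, y, _, model = linear_gaussian_instance(rng, p=2, D=10)
        r1 = vl.fit_vl(model, y)
        r2 = vl.fit_vl(model, y)
        np.testing.assert_array_equal(r1.q_beta.mean, r2.q_beta.mean)
        np.testing.assert_array_equal(r1.q_lambda.mean, r2.q_lambda.mean)
        assert r1.free_energy == r2.free_energy

    def test_rejected_overshoot_restores_state_and_tightens(self):
        """A valley-shaped residual surface makes the first full Gauss-Newton
        step overshoot: the step must be rejected, v reduced, and the accepted
        free-energy trace stays non-decreasing."""

        def g(b):
            return np.array([10.0 * (b[1] - b[0] ** 2), 1.0 - b[0]])

        model = vl.GenerativeModel(
            g=g,
            prior_beta=vl.GaussianDensity(np.zeros(2), 100.0 * np.eye(2)),
            prior_lambda=clamp_lambda([0.0]),
            precision=vl.PrecisionComponents([np.eye(2)]),
        )
        y = np.zeros(2)
        cfg = OptimizerConfig(v0=4.0, max_iterations=64)
        res = vl.fit_vl(model, y, cfg)
        assert not res.trace[0].accepted
        assert res.trace[0].v == pytest.approx(4.0 - cfg.v_down)
        accepted = [r.free_energy for r in res.trace if r.accepted]
        assert all(b >= a for a, b in zip(accepted, accepted[1:]))
        assert len(accepted) > 0

    def test_stationarity_at_convergence(self, rng):
        X, y, lam_star, model = linear_gaussian_instance(rng, p=2, D=15)
        res = vl.fit_vl(model, y, PRECISE)
        J = vl.numerical_jacobian(model.predict, res.q_beta.mean)
        grad = vl.beta_gradient(model, y, res.q_beta, res.q_lambda, J)
        assert np.abs(grad).max() < 1e-4

    def test_invalid_config_rejected(self):
        with pytest.raises(InputError):
            OptimizerConfig(v0=5.0, v_max=4.0)
        with pytest.raises(InputError):
            OptimizerConfig(max_iterations=0)
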