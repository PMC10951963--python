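import numpy as np
import pytest
from scipy.integrate import solve_ivp

import varlaplace as vl
from varlaplace.dynamics import StateSpaceModel
from varlaplace.exceptions import DomainError, InputError
from varlaplace.fixtures import hemo_state_space
from varlaplace.models import HemodynamicConstants, HemodynamicParams


class TestGLM:
    def test_predictions(self):
        X = vl.glm_design(100)
        np.testing.assert_allclose(X[:, 1], np.linspace(-50, 50, 100))
        np.testing.assert_allclose(vl.glm_predict(X, [0.0, 0.0]), np.zeros(100))
        np.testing.assert_allclose(vl.glm_predict(X, [1.0, 0.0]), np.ones(100))

    def test_random_matrix_product(self, rng):
        X = rng.normal(size=(8, 3))
        b = rng.normal(size=3)
        np.testing.assert_allclose(vl.glm_predict(X, b), X @ b)

    def test_shape_mismatch(self):
        with pytest.raises(InputError):
            vl.glm_predict(np.ones((4, 2)), [1.0])


class TestHeteroComponents:
    @pytest.mark.parametrize(
        "D, n, sizes",
        [(4, 2, [2, 2]), (6, 3, [2, 2, 2]), (5, 2, [2, 3])],
    )
    def test_partition(self, D, n, sizes):
        pc = vl.hetero_components(D, n)
        got = [int(np.trace(Q)) for Q in pc.components]
        assert got == sizes
        np.testing.assert_allclose(sum(pc.components), np.eye(D))

    def test_masks_idempotent_and_orthogonal(self):
        pc = vl.hetero_components(7, 3)
        for i, Q in enumerate(pc.components):
            np.testing.assert_allclose(Q @ Q, Q)
            for j, R in enumerate(pc.components):
                if i != j:
                    np.testing.assert_allclose(Q @ R, np.zeros_like(Q))

    def test_too_many_blocks(self):
        with pytest.raises(InputError):
            vl.hetero_components(3, 4)


class TestDecayField:
    def test_values(self):
        assert vl.decay_field(1.0, 0.0) == pytest.approx(-1.0)
        assert vl.decay_field(3.0, np.log(2.0)) == pytest.approx(-6.0)

    def test_integrated_trajectory_closed_form(self):
        times = np.linspace(0, 6, 13)
        beta = 0.4
        ssm = StateSpaceModel(
            f=lambda x, b, u: np.array([vl.decay_field(x[0], b[0])]),
            obs=lambda x: x,
            x0=np.array([2.0]),
            times=times,
        )
        states = vl.integrate_ll(ssm, np.array([beta]))
        np.testing.assert_allclose(
            states[:, 0], 2.0 * np.exp(-np.exp(beta) * times), atol=1e-9
        )


class TestBalloonModel:
    consts = HemodynamicConstants()
    params = HemodynamicParams(tau_h=2.0, kappa=0.64, z_efficacy=0.4)

    def test_rest_is_exact_fixed_point(self):
        rest = np.array([0.0, 1.0, 1.0, 1.0])
        deriv = vl.hemo_field(rest, self.params, self.consts, 0.0)
        assert np.abs(deriv).max() < 1e-12

    def test_inflow_restoring_force(self):
        delta = 1e-3
        state = np.array([0.0, 1.0 + delta, 1.0, 1.0])
        deriv = vl.hemo_field(state, self.params, self.consts, 0.0)
        assert deriv[0] == pytest.approx(-self.consts.gamma * delta, rel=1e-6)

    def test_bold_zero_at_rest_and_algebraic_perturbation(self):
        assert vl.bold_observation(1.0, 1.0, self.consts) == 0.0
        d = 0.05
        expected = self.consts.V0 * (
            self.consts.k2 * (d / (1 + d)) - self.consts.k3 * d
        )
        assert vl.bold_observation(1.0 + d, 1.0, self.consts) == pytest.approx(
            expected
        )

    def test_derived_constants_definitions(self):
        c = HemodynamicConstants(theta0=30.0, E0=0.4, TE=0.03, r0=20.0, eps_h=0.6)
        assert c.k1 == pytest.approx(4.3 * 30.0 * 0.4 * 0.03)
        assert c.k2 == pytest.approx(0.6 * 20.0 * 0.4 * 0.03)
        assert c.k3 == pytest.approx(0.4)

    def test_domain_guards(self):
        with pytest.raises(DomainError):
            vl.hemo_field(np.array([0.0, 1.0, -0.1, 1.0]), self.params, self.consts, 0.0)
        with pytest.raises(DomainError):
            vl.bold_observation(-1.0, 1.0, self.consts)
        with pytest.raises(InputError):
            HemodynamicParams(tau_h=-1.0, kappa=0.5, z_efficacy=0.0)

    def test_response_matches_dense_reference(self):
        """BOLD response to a 1 s unit input vs a fine-tolerance RK integration."""
        times = np.arange(0.0, 30.0, 1.0)
        inputs = (times < 1.0).astype(float)
        ssm = hemo_state_space(times, inputs, self.consts, substeps=16)
        beta = np.array([np.log(2.0), np.log(0.64), 1.0])

        def rhs(t, x):
            k = min(int(np.floor(t)), times.size - 1)  # zero-order hold
            return ssm.f(x, beta, np.array([inputs[k]]))

        ref = solve_ivp(
            rhs, (0, times[-1]), [0, 1, 1, 1], t_eval=times,
            rtol=1e-10, atol=1e-12, max_step=0.25,
        )
        bold_ref = np.array(
            [vl.bold_observation(x[2], x[3], self.consts) for x in ref.y.T]
        )
        bold = vl.as_observation_function(ssm)(beta)
        np.testing.assert_allclose(bold, bold_ref, atol=1e-4)
        assert bold.max() > 0  # positive-peaked response

    def test_relaxation_to_rest_after_stimulus(self):
        """After the input returns to zero the states settle back to
        (0, 1, 1, 1) and BOLD to zero."""
        times = np.arange(0.0, 61.0, 1.0)
        inputs = (times < 2.0).astype(float)
        ssm = hemo_state_space(times, inputs, self.consts, substeps=8)
        beta = np.array([np.log(2.0), np.log(0.64), 1.0])
        states = vl.integrate_ll(ssm, beta)
        np.testing.assert_allclose(states[-1], [0.0, 1.0, 1.0, 1.0], atol=1e-3)
        assert abs(
            vl.bold_observation(states[-1, 2], states[-1, 3], self.consts)
        ) < 1e-3


class TestBilinear:
    def _conn(self):
        A = np.array([[-1.0, 0.2], [0.0, -0.8]])
        B = [np.array([[0.0, 0.0], [0.3, 0.0]])]
        C = np.array([[1.0], [0.0]])
        return vl.BilinearConnectivity(A, B, C)

    def test_no_input_is_intrinsic_coupling(self):
        conn = self._conn()
        z = np.array([0.5, -1.0])
        np.testing.assert_allclose(
            vl.bilinear_field(z, np.zeros(1), conn), conn.A @ z
        )

    def test_zero_state_is_driving_input(self):
        conn = self._conn()
        u = np.array([2.0])
        np.testing.assert_allclose(
            vl.bilinear_field(np.zeros(2), u, conn), conn.C @ u
        )

    def test_stable_impulse_response_decays(self):
        conn = vl.BilinearConnectivity(
            np.array([[-0.5, 0.1], [0.1, -0.7]]),
            [np.zeros((2, 2))],
            np.array([[1.0], [0.0]]),
        )
        times = np.linspace(0, 30, 31)
        inputs = np.zeros((31, 1))
        inputs[0, 0] = 1.0  # brief drive at onset
        ssm = StateSpaceModel(
            f=lambda x, b, u: vl.bilinear_field(x, u, conn),
            obs=lambda x: x,
            x0=np.zeros(2),
            times=times,
            inputs=inputs,
        )
        states = vl.integrate_ll(ssm, np.zeros(1))
        assert np.abs(states[1]).max() > 1e-3  # the impulse moved the states
        assert np.abs(states[-1]).max() < 1e-4  # and they decayed away

    def test_shape_validation(self):
        with pytest.raises(InputError):
            vl.BilinearConnectivity(np.ones((2, 3)), [], np.ones((2, 1)))
        conn = self._conn()
        with pytest.raises(InputError):
            vl.bilinear_field(np.zeros(3), np.zeros(1), conn)
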