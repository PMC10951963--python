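"""Turn ODE-defined models into observation functions by local-linearization integration.

A dynamic model splits into an evolution field ``x_dot = f(x, beta, u)`` over
latent states and an observation map applied at each sampling time.  Each
integration interval advances the state with

    x <- x + (expm(dt J_f) - I) J_f^-1 f(x),

where J_f is the state Jacobian of f at the current state (central
differences).  This update is exact for linear fields regardless of step
size, which is what makes coarse steps tolerable.  It is computed through
the matrix exponential of an augmented (n+1)-dimensional system so a
singular J_f needs no special casing; should that still fail numerically, a
classical 4th-order Runge-Kutta step is taken instead.

Inputs are held piecewise constant over each sampling interval (zero-order
hold).  Flattened predictions are time-major: all channels at t1, then t2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import expm

from .exceptions import InputError, IntegrationError

__all__ = ["StateSpaceModel", "integrate_ll", "as_observation_function"]


@dataclass(frozen=True)
class StateSpaceModel:
    """Evolution field, observation map, initial state, sampling grid and inputs.

    ``f(x, beta, u)`` returns dx/dt; ``obs(x)`` maps a state vector to the
    observed channels.  ``inputs`` (one row per sampling time, or None) are
    applied with zero-order hold.  ``substeps`` internal steps are taken per
    sampling interval.
    """

    f: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    obs: Callable[[np.ndarray], np.ndarray]
    x0: np.ndarray
    times: np.ndarray
    inputs: np.ndarray | None = None
    substeps: int = 1
    fd_step: float = 1e-4

    def __post_init__(self):
        x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if times.size < 1 or np.any(np.diff(times) <= 0):
            raise InputError("sampling times must be strictly increasing")
        inputs = self.inputs
        if inputs is not None:
            inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
            if inputs.shape[0] == 1 and times.size > 1:
                inputs = inputs.T
            if inputs.shape[0] != times.size:
                raise InputError(
                    f"inputs have {inputs.shape[0]} rows for {times.size} sampling times"
                )
        if self.substeps < 1:
            raise InputError("substeps must be >= 1")
        object.__setattr__(self, "x0", x0)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "inputs", inputs)

    @property
    def n_states(self) -> int:
        return self.x0.size

    def input_at(self, index: int) -> np.ndarray:
        if self.inputs is None:
            return np.zeros(0)
        return self.inputs[index]


def _state_jacobian(f_frozen, x: np.ndarray, fd_step: float) -> np.ndarray:
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        delta = fd_step * max(1.0, abs(x[j]))
        up = x.copy()
        dn = x.copy()
        up[j] += delta
        dn[j] -= delta
        J[:, j] = (f_frozen(up) - f_frozen(dn)) / (2.0 * delta)
    return J


def _ll_step(f_frozen, x: np.ndarray, dt: float, fd_step: float) -> np.ndarray:
    fx = f_frozen(x)
    n = x.size
    Jf = _state_jacobian(f_frozen, x, fd_step)
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = dt * Jf
    aug[:n, n] = dt * fx
    step = expm(aug)[:n, n]
    if not np.all(np.isfinite(step)):
        # Runge-Kutta fallback for a numerically intractable Jacobian
        k1 = fx
        k2 = np.asarray(f_frozen(x + 0.5 * dt * k1), dtype=float)
        k3 = np.asarray(f_frozen(x + 0.5 * dt * k2), dtype=float)
        k4 = np.asarray(f_frozen(x + dt * k3), dtype=float)
        step = dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    return x + step


def integrate_ll(
    ssm: StateSpaceModel, beta: np.ndarray, substeps: int | None = None
) -> np.ndarray:
    """Integrate the state trajectory at the sampling grid (time x state).

    The first row is the initial state at ``times[0]``.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    nsub = ssm.substeps if substeps is None else int(substeps)
    if nsub < 1:
        raise InputError("substeps must be >= 1")
    times = ssm.times
    x = ssm.x0.copy()
    out = np.empty((times.size, x.size))
    out[0] = x
    f_model = ssm.f
    for k in range(times.size - 1):
        u = ssm.input_at(k)

        def f_frozen(xx, _u=u):
            return np.asarray(f_model(xx, beta, _u), dtype=float)

        dt = (times[k + 1] - times[k]) / nsub
        for _ in range(nsub):
            x = _ll_step(f_frozen, x, dt, ssm.fd_step)
            if not np.all(np.isfinite(x)):
                raise IntegrationError(
                    f"state became non-finite near t={times[k + 1]:.4g}",
                    time=float(times[k + 1]),
                    state=x,
                )
        out[k + 1] = x
    return out


def as_observation_function(
    ssm: StateSpaceModel,
) -> Callable[[np.ndarray], np.ndarray]:
    """Wrap a state-space model as a pure function beta -> flat prediction vector.

    Integrates the states, applies the observation map at every sampling
    time, and flattens time-major (all channels at t1, then t2, ...), the
    convention assumed when indexing channels in precision components.
    """

    def g(beta: np.ndarray) -> np.ndarray:
        states = integrate_ll(ssm, beta)
        rows = [np.atleast_1d(np.asarray(ssm.obs(x), dtype=float)) for x in states]
        return np.concatenate(rows)

    return g
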