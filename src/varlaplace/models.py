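"""Worked generative models: GLMs, exponential decay, the hemodynamic balloon
model, and the generic bilinear neural state-space model.

The balloon model maps a neuronal drive to the BOLD signal through four
hidden states: a vasoactive signal s, normalised blood inflow f_in, venous
volume v and deoxyhaemoglobin content q.  Inflow responds to the drive and
decays back (rate kappa) with an autoregulatory pull gamma*(f_in - 1);
volume and deoxyhaemoglobin wash in and out on the venous transit time
tau_h, with outflow f_out(v) = v^(1/alpha) (Grubb's exponent) and oxygen
extraction saturating via the resting fraction E0.  The observation equation
combines v and q into a fractional signal change through field- and
sequence-dependent constants k1, k2, k3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PrecisionComponents
from .exceptions import DomainError, InputError

__all__ = [
    "HemodynamicConstants",
    "HemodynamicParams",
    "BilinearConnectivity",
    "glm_predict",
    "glm_design",
    "hetero_components",
    "decay_field",
    "hemo_field",
    "bold_observation",
    "bilinear_field",
]


@dataclass(frozen=True)
class HemodynamicConstants:
    """Fixed physiological/scanner constants of the balloon model.

    Defaults follow the standard balloon-model literature for 1.5-3 T BOLD:
    Grubb's exponent 0.32, autoregulation 0.32 /s, resting oxygen extraction
    0.32, resting venous volume fraction 0.04, theta0 = 40.3 /s, r0 = 25 /s,
    echo time 40 ms, intra/extravascular ratio 0.5.  All overridable.
    """

    alpha_grubb: float = 0.32
    gamma: float = 0.32
    E0: float = 0.32
    V0: float = 0.04
    theta0: float = 40.3
    r0: float = 25.0
    TE: float = 0.04
    eps_h: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.E0 < 1.0 and 0.0 < self.V0 < 1.0):
            raise InputError("E0 and V0 must lie strictly between 0 and 1")
        if self.alpha_grubb <= 0 or self.TE <= 0:
            raise InputError("alpha_grubb and TE must be positive")

    @property
    def k1(self) -> float:
        return 4.3 * self.theta0 * self.E0 * self.TE

    @property
    def k2(self) -> float:
        return self.eps_h * self.r0 * self.E0 * self.TE

    @property
    def k3(self) -> float:
        return 1.0 - self.eps_h


@dataclass(frozen=True)
class HemodynamicParams:
    """The three estimated parameters: transit time, signal decay, stimulus efficacy.

    ``tau_h`` (s) and ``kappa`` (1/s) are scale parameters; fits place
    Gaussian priors on their logs so positivity is automatic.
    """

    tau_h: float
    kappa: float
    z_efficacy: float

    def __post_init__(self):
        if self.tau_h <= 0 or self.kappa <= 0:
            raise InputError("tau_h and kappa must be positive")

    @classmethod
    def from_unconstrained(cls, beta: np.ndarray) -> "HemodynamicParams":
        """beta = (ln tau_h, ln kappa, z_efficacy)."""
        beta = np.asarray(beta, dtype=float)
        return cls(
            tau_h=float(np.exp(beta[0])),
            kappa=float(np.exp(beta[1])),
            z_efficacy=float(beta[2]),
        )


@dataclass(frozen=True)
class BilinearConnectivity:
    """Intrinsic coupling A, modulatory matrices B_j and driving inputs C (all Hz).

    Structural zeros encode switched-off connections; fitting preserves them
    exactly by giving those entries zero prior mean and (near-)zero prior
    variance.
    """

    A: np.ndarray
    B: tuple[np.ndarray, ...]
    C: np.ndarray

    def __init__(self, A, B, C):
        A = np.atleast_2d(np.asarray(A, dtype=float))
        p = A.shape[0]
        if A.shape != (p, p):
            raise InputError("A must be square")
        B = tuple(np.atleast_2d(np.asarray(b, dtype=float)) for b in B)
        for j, b in enumerate(B):
            if b.shape != (p, p):
                raise InputError(f"B_{j + 1} has shape {b.shape}, expected ({p}, {p})")
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[0] != p:
            raise InputError(f"C has {C.shape[0]} rows for {p} regions")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "C", C)

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]


def glm_design(size: int, low: float = -50.0, high: float = 50.0) -> np.ndarray:
    """Intercept plus one evenly spaced covariate column over [low, high]."""
    if size < 2:
        raise InputError("design needs at least 2 rows")
    return np.column_stack([np.ones(size), np.linspace(low, high, size)])


def glm_predict(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Linear predictor X @ beta."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if X.shape[1] != beta.size:
        raise InputError(
            f"design has {X.shape[1]} columns, beta has length {beta.size}"
        )
    return X @ beta


def hetero_components(D: int, n_blocks: int) -> PrecisionComponents:
    """0/1 diagonal masks over contiguous equal blocks of the data vector.

    The last block absorbs any remainder; the masks partition the diagonal,
    so their sum is the identity.
    """
    if n_blocks < 1:
        raise InputError("n_blocks must be >= 1")
    if n_blocks > D:
        raise InputError(f"cannot split {D} observations into {n_blocks} blocks")
    block = D // n_blocks
    mats = []
    for b in range(n_blocks):
        start = b * block
        stop = D if b == n_blocks - 1 else (b + 1) * block
        diag = np.zeros(D)
        diag[start:stop] = 1.0
        mats.append(np.diag(diag))
    return PrecisionComponents(mats)


def decay_field(x: float, beta: float) -> float:
    """Exponential decay field -exp(beta) * x; beta is the log decay rate."""
    return -np.exp(beta) * x


def hemo_field(
    state: np.ndarray,
    params: HemodynamicParams,
    consts: HemodynamicConstants,
    z_t: float,
) -> np.ndarray:
    """Time derivatives of the balloon-model states (s, f_in, v, q)."""
    s, f_in, vol, q = (float(x) for x in state)
    if f_in <= 0 or vol <= 0 or q <= 0:
        raise DomainError(
            f"balloon states must stay positive; got f_in={f_in}, v={vol}, q={q}"
        )
    f_out = vol ** (1.0 / consts.alpha_grubb)
    ds = params.z_efficacy * z_t - params.kappa * s - consts.gamma * (f_in - 1.0)
    dfin = s
    dv = (f_in - f_out) / params.tau_h
    extraction = (1.0 - (1.0 - consts.E0) ** (1.0 / f_in)) / consts.E0
    dq = (f_in * extraction - f_out * q / vol) / params.tau_h
    return np.array([ds, dfin, dv, dq])


def bold_observation(
    v: float, q: float, consts: HemodynamicConstants
) -> float:
    """BOLD signal V0 * (k1(1-q) + k2(1-q/v) + k3(1-v)); zero at rest (v=q=1)."""
    if v <= 0:
        raise DomainError(f"venous volume must be positive, got {v}")
    return consts.V0 * (
        consts.k1 * (1.0 - q)
        + consts.k2 * (1.0 - q / v)
        + consts.k3 * (1.0 - v)
    )


def bilinear_field(
    z: np.ndarray, u: np.ndarray, conn: BilinearConnectivity
) -> np.ndarray:
    """Neural dynamics (A + sum_j u_j B_j) z + C u.

    Input j modulates connectivity through B_j when one is supplied (inputs
    beyond the modulatory list are purely driving) and drives regions
    through its column of C.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if z.size != conn.n_regions:
        raise InputError(f"state has length {z.size} for {conn.n_regions} regions")
    if u.size != conn.C.shape[1] or len(conn.B) > u.size:
        raise InputError(
            f"{u.size} inputs for {len(conn.B)} modulatory matrices and "
            f"{conn.C.shape[1]} driving columns"
        )
    J = conn.A.copy()
    for uj, Bj in zip(u, conn.B):
        J += uj * Bj
    return J @ z + conn.C @ u
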