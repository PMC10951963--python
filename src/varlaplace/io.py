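"""File formats: model specification YAML, data CSV, result JSON.

A model file names a registry entry (``glm``, ``glm-hetero``, ``decay``,
``hemo``, ``bilinear``) plus priors and precision components; data files are
plain CSV with a single ``y`` column (row order = data-vector order) or, for
timeseries, a ``t`` column plus one column per channel/input.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

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
    bilinear_field,
    BilinearConnectivity,
    glm_design,
    glm_predict,
    hetero_components,
    decay_field,
)
from .fixtures import hemo_state_space
from .optimize import OptimizerConfig, VLResult

__all__ = [
    "read_data_csv",
    "write_data_csv",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "load_model",
    "load_model_dict",
    "load_optimizer_config",
    "result_to_json",
]


def read_data_csv(path) -> np.ndarray:
    """Observation vector from a CSV with one column ``y``."""
    df = pd.read_csv(path)
    if "y" not in df.columns:
        raise InputError(f"{path}: expected a column named 'y'")
    return df["y"].to_numpy(dtype=float)


def write_data_csv(path, y) -> None:
    pd.DataFrame({"y": np.asarray(y, dtype=float)}).to_csv(path, index=False)


def read_timeseries_csv(path) -> tuple[np.ndarray, pd.DataFrame]:
    """(times, channels) from a CSV with column ``t`` plus one column per channel."""
    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise InputError(f"{path}: expected a column named 't'")
    t = df["t"].to_numpy(dtype=float)
    return t, df.drop(columns=["t"])


def write_timeseries_csv(path, t, channels: dict) -> None:
    pd.DataFrame({"t": np.asarray(t, dtype=float), **channels}).to_csv(
        path, index=False
    )


def _parse_density(node, what: str) -> GaussianDensity:
    if node is None:
        raise InputError(f"missing {what} specification")
    mean = np.atleast_1d(np.asarray(node["mean"], dtype=float))
    if "cov" in node:
        cov = np.asarray(node["cov"], dtype=float)
    elif "var" in node:
        cov = np.diag(np.atleast_1d(np.asarray(node["var"], dtype=float)))
    elif "sd" in node:
        cov = np.diag(np.atleast_1d(np.asarray(node["sd"], dtype=float)) ** 2)
    else:
        raise InputError(f"{what}: provide 'cov', 'var' or 'sd'")
    return GaussianDensity(mean, cov)


def _parse_components(nodes, D: int) -> PrecisionComponents:
    if nodes is None:
        return PrecisionComponents([np.eye(D)])
    mats = []
    for node in nodes:
        if node == "identity":
            mats.append(np.eye(D))
        elif isinstance(node, dict) and "block" in node:
            start, stop = (int(v) for v in node["block"])
            diag = np.zeros(D)
            diag[start:stop] = 1.0
            mats.append(np.diag(diag))
        elif isinstance(node, dict) and "diag" in node:
            mats.append(np.diag(np.asarray(node["diag"], dtype=float)))
        elif isinstance(node, dict) and "matrix" in node:
            mats.append(np.asarray(node["matrix"], dtype=float))
        else:
            raise InputError(f"unrecognised precision component: {node!r}")
    return PrecisionComponents(mats)


def _times_from(node) -> np.ndarray:
    if isinstance(node, dict):
        return np.linspace(
            float(node["start"]), float(node["stop"]), int(node["num"])
        )
    return np.asarray(node, dtype=float)


def _build_glm(cfg: dict):
    design = cfg.get("design")
    if isinstance(design, dict):
        X = glm_design(
            int(design["size"]),
            float(design.get("low", -50.0)),
            float(design.get("high", 50.0)),
        )
    else:
        X = np.asarray(design, dtype=float)
    return (lambda b: glm_predict(X, b)), X.shape[0]


def _build_decay(cfg: dict):
    times = _times_from(cfg["times"])
    x0 = float(cfg.get("x0", 1.0))
    ssm = StateSpaceModel(
        f=lambda x, b, u: np.array([decay_field(x[0], b[0])]),
        obs=lambda x: x,
        x0=np.array([x0]),
        times=times,
        substeps=int(cfg.get("substeps", 1)),
    )
    return as_observation_function(ssm), times.size


def _build_hemo(cfg: dict):
    times = _times_from(cfg["times"])
    inputs = np.asarray(cfg["inputs"], dtype=float)
    consts = HemodynamicConstants(**cfg.get("constants", {}))
    ssm = hemo_state_space(times, inputs, consts, substeps=int(cfg.get("substeps", 2)))
    return as_observation_function(ssm), times.size


def _build_bilinear(cfg: dict):
    """Bilinear neural model observed directly at the sampling grid.

    ``A``, ``B`` (list) and ``C`` are given as prior-mean matrices with
    matching prior-variance matrices; entries with zero prior variance are
    fixed at their mean (structural zeros stay exactly zero), the rest form
    the parameter vector.  Returns the observation function, data size, and
    the implied parameter prior.
    """
    A_m = np.asarray(cfg["A"]["mean"], dtype=float)
    A_v = np.asarray(cfg["A"]["var"], dtype=float)
    B_m = [np.asarray(b["mean"], dtype=float) for b in cfg.get("B", [])]
    B_v = [np.asarray(b["var"], dtype=float) for b in cfg.get("B", [])]
    C_m = np.asarray(cfg["C"]["mean"], dtype=float)
    C_v = np.asarray(cfg["C"]["var"], dtype=float)
    times = _times_from(cfg["times"])
    inputs = np.atleast_2d(np.asarray(cfg["inputs"], dtype=float))
    if inputs.shape[0] != times.size:
        inputs = inputs.T
    x0 = np.asarray(cfg.get("x0", np.zeros(A_m.shape[0])), dtype=float)

    blocks = [("A", A_m, A_v)] + [
        (f"B{j + 1}", m, v) for j, (m, v) in enumerate(zip(B_m, B_v))
    ] + [("C", C_m, C_v)]
    free, means, variances = [], [], []
    for name, m, v in blocks:
        idx = np.argwhere(v > 0)
        for i, j in idx:
            free.append((name, int(i), int(j)))
            means.append(m[i, j])
            variances.append(v[i, j])
    if not free:
        raise InputError("bilinear model has no free parameters")

    def assemble(beta):
        A = A_m.copy()
        Bs = [b.copy() for b in B_m]
        C = C_m.copy()
        for (name, i, j), val in zip(free, beta):
            if name == "A":
                A[i, j] = val
            elif name == "C":
                C[i, j] = val
            else:
                Bs[int(name[1:]) - 1][i, j] = val
        return BilinearConnectivity(A, Bs, C)

    def f(x, beta, u):
        return bilinear_field(x, u, assemble(beta))

    ssm = StateSpaceModel(
        f=f,
        obs=lambda x: x,
        x0=x0,
        times=times,
        inputs=inputs,
        substeps=int(cfg.get("substeps", 1)),
    )
    prior_beta = GaussianDensity(np.asarray(means), np.diag(variances))
    g = as_observation_function(ssm)
    return g, times.size * A_m.shape[0], prior_beta


_REGISTRY = {"glm", "glm-hetero", "decay", "hemo", "bilinear"}


def load_model_dict(cfg: dict) -> GenerativeModel:
    """Build a GenerativeModel from a parsed model-specification dictionary."""
    kind = cfg.get("model")
    if kind not in _REGISTRY:
        raise InputError(f"unknown model kind {kind!r}; expected one of {sorted(_REGISTRY)}")
    prior_beta = None
    if kind in ("glm", "glm-hetero"):
        g, D = _build_glm(cfg)
    elif kind == "decay":
        g, D = _build_decay(cfg)
    elif kind == "hemo":
        g, D = _build_hemo(cfg)
    else:
        g, D, prior_beta = _build_bilinear(cfg)

    if prior_beta is None or "prior_beta" in cfg:
        prior_beta = _parse_density(cfg.get("prior_beta"), "prior_beta")
    if kind == "glm-hetero" and "components" not in cfg:
        pc = hetero_components(D, int(cfg.get("n_blocks", 2)))
    else:
        pc = _parse_components(cfg.get("components"), D)
    if "prior_lambda" in cfg:
        prior_lambda = _parse_density(cfg["prior_lambda"], "prior_lambda")
    else:
        prior_lambda = default_hyperprior(pc.n_components)
    return GenerativeModel(
        g=g,
        prior_beta=prior_beta,
        prior_lambda=prior_lambda,
        precision=pc,
        name=str(cfg.get("name", kind)),
    )


def load_model(path) -> GenerativeModel:
    """Read a YAML (or JSON) model specification file."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: expected a mapping at top level")
    return load_model_dict(cfg)


def load_optimizer_config(path) -> OptimizerConfig:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    return OptimizerConfig(**cfg)


def result_to_json(result: VLResult, path=None) -> str:
    text = json.dumps(result.to_dict(), indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
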