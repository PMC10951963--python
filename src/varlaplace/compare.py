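"""Bayesian model comparison from free energies.

Each model's maximised free energy approximates its log evidence, so the log
Bayes factor between two models is the difference of free energies and the
posterior probability over a candidate set is a softmax of free energies
(plus log model priors, uniform by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError

__all__ = [
    "ComparisonTable",
    "log_bayes_factor",
    "bayes_factor",
    "model_posteriors",
    "compare",
]

_LNB_OVERFLOW = 700.0


@dataclass(frozen=True)
class ComparisonTable:
    """Free energies, log Bayes factors against a reference model, and posterior probabilities."""

    model_names: tuple[str, ...]
    free_energies: np.ndarray
    reference_index: int
    log_bayes_factors: np.ndarray
    posterior_probs: np.ndarray

    def to_dict(self) -> dict:
        return {
            "model_names": list(self.model_names),
            "free_energies": self.free_energies.tolist(),
            "reference_index": int(self.reference_index),
            "reference_model": self.model_names[self.reference_index],
            "log_bayes_factors": self.log_bayes_factors.tolist(),
            "posterior_probs": self.posterior_probs.tolist(),
        }

    def __str__(self) -> str:
        lines = [
            f"{'model':<16}{'F (nats)':>12}{'ln BF':>10}{'P(m|y)':>10}",
        ]
        for name, F, lnb, p in zip(
            self.model_names,
            self.free_energies,
            self.log_bayes_factors,
            self.posterior_probs,
        ):
            lines.append(f"{name:<16}{F:>12.2f}{lnb:>10.2f}{p:>10.4f}")
        return "\n".join(lines)


def log_bayes_factor(F1: float, F2: float) -> float:
    """Log Bayes factor in favour of model 1: F1 - F2."""
    if not (np.isfinite(F1) and np.isfinite(F2)):
        raise InputError("free energies must be finite")
    return float(F1) - float(F2)


def bayes_factor(lnB: float) -> float:
    """Evidence ratio exp(lnB); returns +inf above the overflow threshold."""
    if not np.isfinite(lnB):
        raise InputError("log Bayes factor must be finite")
    if lnB > _LNB_OVERFLOW:
        return float("inf")
    return float(np.exp(lnB))


def model_posteriors(
    free_energies: np.ndarray, prior_probs: np.ndarray | None = None
) -> np.ndarray:
    """Posterior model probabilities: softmax of F + ln prior.

    Computed with max subtraction for overflow safety.  With two equal-prior
    models this reduces to 1 / (1 + exp(-lnB)).
    """
    F = np.atleast_1d(np.asarray(free_energies, dtype=float))
    if F.size < 2:
        raise InputError("model comparison needs at least 2 models")
    if prior_probs is None:
        logprior = np.zeros(F.size)
    else:
        prior = np.atleast_1d(np.asarray(prior_probs, dtype=float))
        if prior.size != F.size:
            raise InputError("prior_probs length must match free_energies")
        if np.any(prior <= 0) or abs(prior.sum() - 1.0) > 1e-8:
            raise InputError("prior_probs must be positive and sum to 1")
        logprior = np.log(prior)
    score = F + logprior
    score -= score.max()
    w = np.exp(score)
    return w / w.sum()


def compare(
    model_names,
    free_energies,
    prior_probs=None,
    reference: int | str = "worst",
) -> ComparisonTable:
    """Build a comparison table; the reference defaults to the lowest-F model."""
    names = tuple(str(n) for n in model_names)
    F = np.atleast_1d(np.asarray(free_energies, dtype=float))
    if len(names) != F.size:
        raise InputError("one name per free energy required")
    if F.size < 2:
        raise InputError("model comparison needs at least 2 models")
    if reference == "worst":
        ref = int(np.argmin(F))
    else:
        ref = int(reference)
        if not 0 <= ref < F.size:
            raise InputError(f"reference index {ref} out of range")
    lnb = F - F[ref]
    probs = model_posteriors(F, prior_probs)
    return ComparisonTable(
        model_names=names,
        free_energies=F,
        reference_index=ref,
        log_bayes_factors=lnb,
        posterior_probs=probs,
    )
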