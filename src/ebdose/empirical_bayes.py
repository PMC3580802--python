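"""Empirical-Bayes (BLUP) prediction of a patient's intercept.

With the population model treated as known, the normal-normal posterior of a
patient's intercept given n observed log-residuals with mean ``rbar`` is

    alpha_hat = (sigma_eps2 * mu_alpha + n * sigma_alpha2 * rbar)
                / (sigma_eps2 + n * sigma_alpha2)
    v         = sigma_alpha2 * sigma_eps2 / (sigma_eps2 + n * sigma_alpha2)

which shrinks the patient's mean residual toward the population mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_model import PopulationModel, log_residuals

__all__ = ["PatientHistory", "PosteriorIntercept", "posterior_intercept", "gamma_index"]


@dataclass
class PatientHistory:
    """A patient's covariates plus accumulated (dose, response) pairs."""

    covariates: np.ndarray = field(default_factory=lambda: np.empty(0))
    observations: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.covariates = np.asarray(self.covariates, dtype=float).reshape(-1)
        self.observations = [(float(d), float(y)) for d, y in self.observations]
        for d, y in self.observations:
            if d <= 0 or y <= 0:
                raise ValueError("doses and responses must be strictly positive")

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def doses(self) -> np.ndarray:
        return np.array([d for d, _ in self.observations], dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return np.array([y for _, y in self.observations], dtype=float)

    def record(self, dose: float, response: float) -> None:
        if dose <= 0 or response <= 0:
            raise ValueError("doses and responses must be strictly positive")
        self.observations.append((float(dose), float(response)))


@dataclass(frozen=True)
class PosteriorIntercept:
    """Posterior mean and variance of a patient's intercept."""

    alpha_hat: float
    v: float
    n_obs: int

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("posterior variance must be nonnegative")
        if self.n_obs < 0:
            raise ValueError("n_obs must be nonnegative")


def posterior_intercept(
    model: PopulationModel, history: PatientHistory
) -> PosteriorIntercept:
    """Empirical-Bayes posterior of the patient's intercept given history.

    An empty history returns the prior ``(mu_alpha, sigma_alpha2)``.  The
    posterior depends on the history only through the number of observations
    and the mean log-residual.
    """
    n = history.n_obs
    if n == 0:
        return PosteriorIntercept(model.mu_alpha, model.sigma_alpha2, 0)
    r = log_residuals(model, history.covariates, history.doses, history.responses)
    rbar = float(np.mean(r))
    sa2, se2 = model.sigma_alpha2, model.sigma_eps2
    denom = se2 + n * sa2
    alpha_hat = (se2 * model.mu_alpha + n * sa2 * rbar) / denom
    v = sa2 * se2 / denom
    return PosteriorIntercept(alpha_hat, v, n)


def gamma_index(alpha: float, model: PopulationModel) -> float:
    """Standardized intercept ``(alpha - mu_alpha) / sigma_alpha``.

    Zero marks the average patient; positive values flag slower-than-average
    drug elimination (higher concentration at the same dose), negative values
    faster elimination.
    """
    if model.sigma_alpha2 == 0:
        raise ValueError("gamma undefined: sigma_alpha2 is zero")
    return (alpha - model.mu_alpha) / model.sigma_alpha
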