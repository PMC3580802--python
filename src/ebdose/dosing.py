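"""Dose individualization: initial dose, empirical-Bayes updates, window
probabilities, omega-optimality and the traditional TDM comparator.

All dose formulas target the geometric midpoint of the therapeutic window on
the log-concentration scale, which maximizes the probability of landing inside
the window for any symmetric predictive distribution of the log response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from .core_model import PopulationModel
from .empirical_bayes import PatientHistory, PosteriorIntercept, posterior_intercept

__all__ = [
    "TherapeuticWindow",
    "DoseRecommendation",
    "initial_dose",
    "update_dose",
    "window_probability",
    "max_attainable_probability",
    "is_omega_optimum",
    "tdm_update",
    "minimum_samples",
]


@dataclass(frozen=True)
class TherapeuticWindow:
    """Concentration interval (l1, l2) in which the drug is effective and safe."""

    l1: float
    l2: float

    def __post_init__(self) -> None:
        if not (0 < self.l1 < self.l2):
            raise ValueError("require 0 < l1 < l2")

    @property
    def therapeutic_index(self) -> float:
        return self.l2 / self.l1

    @property
    def geometric_midpoint(self) -> float:
        return math.sqrt(self.l1 * self.l2)

    @property
    def arithmetic_midpoint(self) -> float:
        return 0.5 * (self.l1 + self.l2)

    def scaled(self, c: float) -> "TherapeuticWindow":
        return TherapeuticWindow(self.l1 * c, self.l2 * c)


@dataclass(frozen=True)
class DoseRecommendation:
    dose: float
    step: int
    predicted_window_probability: float
    posterior: PosteriorIntercept

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be strictly positive")
        if not 0.0 <= self.predicted_window_probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


def _dose_for_alpha(
    model: PopulationModel, alpha: float, X: Sequence[float], window: TherapeuticWindow
) -> float:
    """Dose placing the predicted median response at the geometric midpoint:
    ``[sqrt(l1 l2) * exp(-alpha - beta'x)]^(1/d)``."""
    xb = model.linear_predictor(X)
    g = window.geometric_midpoint
    return (g * math.exp(-alpha - xb)) ** (1.0 / model.d)


def initial_dose(
    model: PopulationModel, X: Sequence[float], window: TherapeuticWindow
) -> DoseRecommendation:
    """First-step dose, appropriate for the average patient with covariates X."""
    return update_dose(model, PatientHistory(covariates=np.asarray(X, float)), window)


def update_dose(
    model: PopulationModel, history: PatientHistory, window: TherapeuticWindow
) -> DoseRecommendation:
    """Empirical-Bayes dose update from accumulated (dose, response) history.

    Replaces the population mean intercept with the patient's posterior mean;
    with an empty history this reduces to :func:`initial_dose`.
    """
    post = posterior_intercept(model, history)
    dose = _dose_for_alpha(model, post.alpha_hat, history.covariates, window)
    prob = window_probability(
        model, post.alpha_hat, post.v, history.covariates, dose, window
    )
    return DoseRecommendation(
        dose=dose,
        step=post.n_obs + 1,
        predicted_window_probability=prob,
        posterior=post,
    )


def window_probability(
    model: PopulationModel,
    alpha_mean: float,
    alpha_var: float,
    X: Sequence[float],
    dose: float,
    window: TherapeuticWindow,
) -> float:
    """P(l1 < Y < l2) for a given dose.

    The log response is normal with mean ``alpha_mean + beta'x + d log(dose)``
    and variance ``alpha_var + sigma_eps2``; ``alpha_var=0`` gives the
    known-intercept probability, ``alpha_var=v`` the posterior-predictive one.
    One minus this probability is the Bayes risk of the dose.
    """
    if dose <= 0:
        raise ValueError("dose must be strictly positive")
    if alpha_var < 0:
        raise ValueError("alpha_var must be nonnegative")
    m = alpha_mean + model.linear_predictor(X) + model.d * math.log(dose)
    s = math.sqrt(alpha_var + model.sigma_eps2)
    return float(
        norm.cdf((math.log(window.l2) - m) / s)
        - norm.cdf((math.log(window.l1) - m) / s)
    )


def max_attainable_probability(
    model: PopulationModel, window: TherapeuticWindow
) -> float:
    """Largest window probability attainable for any patient with known
    intercept: ``2 Phi(log(l2/l1) / (2 sigma_eps)) - 1``.

    Strictly below 1 whenever sigma_eps > 0, and independent of the patient's
    intercept: intra-patient noise caps what any dosing rule can achieve.
    """
    half_logwidth = 0.5 * math.log(window.therapeutic_index)
    return float(2.0 * norm.cdf(half_logwidth / model.sigma_eps) - 1.0)


def is_omega_optimum(
    dose: float,
    true_alpha: float,
    model: PopulationModel,
    X: Sequence[float],
    window: TherapeuticWindow,
    omega: float,
) -> bool:
    """Whether ``dose`` attains at least a fraction ``omega`` of the maximum
    attainable window probability for a patient with intercept ``true_alpha``."""
    if not 0.0 < omega < 1.0:
        raise ValueError("omega must lie strictly between 0 and 1")
    p = window_probability(model, true_alpha, 0.0, X, dose, window)
    return p >= omega * max_attainable_probability(model, window)


def tdm_update(
    previous_dose: float,
    measured_level: float,
    target_C0: float,
    d: float = 1.0,
) -> float:
    """Traditional TDM proportional adjustment toward a target trough level:
    ``previous * (C0 / measured)``.

    For d != 1 the generalized form ``previous * (C0/measured)^(1/d)`` is
    used, since proportional adjustment presumes linear kinetics.
    """
    if previous_dose <= 0 or measured_level <= 0 or target_C0 <= 0:
        raise ValueError("all inputs must be strictly positive")
    if d <= 0:
        raise ValueError("dose exponent d must be strictly positive")
    return previous_dose * (target_C0 / measured_level) ** (1.0 / d)


def minimum_samples(
    model: PopulationModel,
    window: TherapeuticWindow,
    omega: float = 0.9,
    population_fraction: float = 0.9,
    X_generator: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    max_n: int = 10,
    n_sim: int = 10_000,
    seed: int | None = None,
) -> int:
    """Minimum number of blood samples for an omega-optimum dose, by simulation.

    Returns the smallest n <= max_n such that the empirical-Bayes dose
    computed after n samples is omega-optimum (judged against each patient's
    true intercept) for at least ``population_fraction`` of a simulated
    population; returns ``max_n + 1`` as a sentinel when unattained.
    """
    if not (0.0 < omega < 1.0 and 0.0 < population_fraction < 1.0):
        raise ValueError("omega and population_fraction must lie in (0, 1)")
    if n_sim < 1:
        raise ValueError("n_sim must be positive")
    rng = np.random.default_rng(seed)
    alphas = rng.normal(model.mu_alpha, model.sigma_alpha, size=n_sim)
    k = model.beta.size
    if X_generator is not None:
        X = np.asarray(X_generator(rng, n_sim), dtype=float).reshape(n_sim, -1)
        if X.shape[1] != k:
            raise ValueError("X_generator returned wrong covariate dimension")
    else:
        X = np.zeros((n_sim, k))
    eps = rng.normal(0.0, model.sigma_eps, size=(n_sim, max_n))
    xb = X @ model.beta if k else np.zeros(n_sim)

    maxp = max_attainable_probability(model, window)
    target = omega * maxp
    se2, sa2 = model.sigma_eps2, model.sigma_alpha2
    log_l1, log_l2 = math.log(window.l1), math.log(window.l2)
    log_g = 0.5 * (log_l1 + log_l2)
    sig = model.sigma_eps

    for n in range(max_n + 1):
        if n == 0:
            alpha_hat = np.full(n_sim, model.mu_alpha)
        else:
            # residuals of EB-administered doses are alpha + eps regardless of
            # the dose actually given, so the posterior needs no dose record
            rbar = alphas + eps[:, :n].mean(axis=1)
            alpha_hat = (se2 * model.mu_alpha + n * sa2 * rbar) / (se2 + n * sa2)
        # known-alpha log-response mean at the EB dose
        m = alphas - alpha_hat + log_g
        prob = norm.cdf((log_l2 - m) / sig) - norm.cdf((log_l1 - m) / sig)
        if np.mean(prob >= target) >= population_fraction:
            return n
    return max_n + 1
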