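"""Synthetic populations and head-to-head dosing-strategy trials.

The generator realizes the assumed data structure — normal patient intercepts,
fixed covariate effects, a dose exponent, and log-normal intra-patient error —
and the trial engine runs competing dosing strategies over the same simulated
patients with common random numbers, so strategies differ only in the doses
they administer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .core_model import LongTable, PopulationModel
from .dosing import TherapeuticWindow, max_attainable_probability

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "TrialResult",
    "generate_population",
    "generate_response",
    "run_trial",
    "generate_long_table",
    "default_scenario",
]

STRATEGIES = ("empirical_bayes", "tdm", "fixed_population_dose")


@dataclass(frozen=True)
class CovariateSpec:
    """Distribution of one patient-level covariate."""

    name: str
    dist: str  # "binary" | "normal" | "constant"
    p: float = 0.5
    mean: float = 0.0
    sd: float = 1.0
    value: float = 0.0

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "binary":
            return rng.binomial(1, self.p, size=n).astype(float)
        if self.dist == "normal":
            return rng.normal(self.mean, self.sd, size=n)
        if self.dist == "constant":
            return np.full(n, self.value)
        raise ValueError(f"unknown covariate distribution {self.dist!r}")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CovariateSpec":
        return cls(**payload)


@dataclass
class SimulationConfig:
    population: PopulationModel
    window: TherapeuticWindow
    covariate_spec: tuple[CovariateSpec, ...] = ()
    omega: float = 0.9
    n_patients: int = 1000
    n_steps: int = 6
    strategies: tuple[str, ...] = ("empirical_bayes", "tdm")
    seed: int = 0

    def __post_init__(self) -> None:
        self.covariate_spec = tuple(self.covariate_spec)
        self.strategies = tuple(self.strategies)
        if self.n_patients < 1 or self.n_steps < 1:
            raise ValueError("n_patients and n_steps must be at least 1")
        if not self.strategies:
            raise ValueError("at least one strategy is required")
        for s in self.strategies:
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}; choose from {STRATEGIES}")
        if len(self.covariate_spec) != self.population.beta.size:
            raise ValueError("covariate_spec must match the model's beta length")
        if not 0.0 < self.omega < 1.0:
            raise ValueError("omega must lie in (0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SimulationConfig":
        pop = PopulationModel.from_dict(payload["population"])
        win = TherapeuticWindow(
            float(payload["window"]["l1"]), float(payload["window"]["l2"])
        )
        covs = tuple(
            CovariateSpec.from_dict(c) for c in payload.get("covariates", [])
        )
        return cls(
            population=pop,
            window=win,
            covariate_spec=covs,
            omega=float(payload.get("omega", 0.9)),
            n_patients=int(payload.get("n_patients", 1000)),
            n_steps=int(payload.get("n_steps", 6)),
            strategies=tuple(payload.get("strategies", ("empirical_bayes", "tdm"))),
            seed=int(payload["seed"]),
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TrialResult:
    """Per-(strategy, step) attainment statistics plus raw trajectories."""

    summary: pd.DataFrame
    trajectories: pd.DataFrame
    config: SimulationConfig


def default_scenario(
    n_patients: int = 2000,
    n_steps: int = 6,
    strategies: Sequence[str] = ("empirical_bayes", "tdm", "fixed_population_dose"),
    seed: int = 0,
) -> SimulationConfig:
    """Package-default head-to-head scenario with visible strategy separation."""
    model = PopulationModel(
        mu_alpha=1.0,
        sigma_alpha2=0.09,
        sigma_eps2=0.04,
        beta=np.array([0.3]),
        d=1.0,
        covariate_names=("smoker",),
    )
    return SimulationConfig(
        population=model,
        window=TherapeuticWindow(2.0, 6.0),
        covariate_spec=(CovariateSpec(name="smoker", dist="binary", p=0.5),),
        omega=0.9,
        n_patients=n_patients,
        n_steps=n_steps,
        strategies=tuple(strategies),
        seed=seed,
    )


def generate_population(config: SimulationConfig) -> list[tuple[float, np.ndarray]]:
    """Draw (true intercept, covariate vector) pairs for the population."""
    alphas, X = _draw_population(config, np.random.default_rng(config.seed))
    return [(float(a), X[i].copy()) for i, a in enumerate(alphas)]


def _draw_population(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    m = config.population
    alphas = rng.normal(m.mu_alpha, m.sigma_alpha, size=config.n_patients)
    cols = [spec.draw(rng, config.n_patients) for spec in config.covariate_spec]
    X = np.column_stack(cols) if cols else np.zeros((config.n_patients, 0))
    return alphas, X


def generate_response(
    model: PopulationModel,
    true_alpha: float,
    X: Sequence[float],
    dose: float,
    rng: np.random.Generator,
) -> float:
    """One steady-state trough response at the given dose."""
    if dose <= 0:
        raise ValueError("dose must be strictly positive")
    eps = rng.normal(0.0, model.sigma_eps)
    return float(
        math.exp(true_alpha + model.linear_predictor(X) + model.d * math.log(dose) + eps)
    )


def run_trial(config: SimulationConfig) -> TrialResult:
    """Simulate all configured strategies over one common population.

    Intercepts, covariates and the per-(patient, step) error stream are drawn
    once, so every strategy faces identical patients and noise; strategies
    differ only through the doses they choose.  Records, per administered
    dose, the window probability evaluated at the patient's true intercept.
    """
    rng = np.random.default_rng(config.seed)
    m = config.population
    win = config.window
    P, T = config.n_patients, config.n_steps
    alphas, X = _draw_population(config, rng)
    eps = rng.normal(0.0, m.sigma_eps, size=(P, T))
    xb = X @ m.beta if m.beta.size else np.zeros(P)

    log_l1, log_l2 = math.log(win.l1), math.log(win.l2)
    log_g = 0.5 * (log_l1 + log_l2)
    sig = m.sigma_eps
    sa2, se2 = m.sigma_alpha2, m.sigma_eps2
    maxp = max_attainable_probability(m, win)
    gamma_true = (alphas - m.mu_alpha) / m.sigma_alpha if sa2 > 0 else np.zeros(P)

    initial = np.exp((log_g - m.mu_alpha - xb) / m.d)

    summary_rows = []
    traj_frames = []
    for strat in config.strategies:
        dose = initial.copy()
        resid_sum = np.zeros(P)
        for t in range(T):
            log_dose = np.log(dose)
            # known-alpha window probability of the administered dose
            mt = alphas + xb + m.d * log_dose
            prob = norm.cdf((log_l2 - mt) / sig) - norm.cdf((log_l1 - mt) / sig)
            omega_flag = prob >= config.omega * maxp
            log_resp = alphas + xb + m.d * log_dose + eps[:, t]
            resid_sum += log_resp - xb - m.d * log_dose  # = alpha + eps
            n = t + 1
            alpha_hat = (se2 * m.mu_alpha + sa2 * resid_sum) / (se2 + n * sa2)
            v = sa2 * se2 / (se2 + n * sa2)
            if sa2 > 0:
                gamma_err = np.abs((alpha_hat - m.mu_alpha) / m.sigma_alpha - gamma_true)
            else:
                gamma_err = np.zeros(P)

            summary_rows.append(
                {
                    "strategy": strat,
                    "step": t + 1,
                    "mean_window_probability": float(prob.mean()),
                    "frac_omega_optimum": float(omega_flag.mean()),
                    "mean_abs_gamma_error": float(gamma_err.mean()),
                    "mean_posterior_variance": float(v),
                }
            )
            frame = pd.DataFrame(
                {
                    "strategy": strat,
                    "patient": np.arange(P),
                    "step": t + 1,
                    "dose": dose.copy(),
                    "response": np.exp(log_resp),
                    "true_alpha": alphas,
                    "alpha_hat": alpha_hat,
                    "window_probability": prob,
                    "omega_optimum": omega_flag,
                }
            )
            for j, name in enumerate(m.covariate_names):
                frame[name] = X[:, j]
            traj_frames.append(frame)

            # next dose
            if strat == "empirical_bayes":
                dose = np.exp((log_g - alpha_hat - xb) / m.d)
            elif strat == "tdm":
                dose = dose * (math.exp(log_g) / np.exp(log_resp)) ** (1.0 / m.d)
            elif strat == "fixed_population_dose":
                dose = initial.copy()

    summary = pd.DataFrame(summary_rows)
    trajectories = pd.concat(traj_frames, ignore_index=True)
    return TrialResult(summary=summary, trajectories=trajectories, config=config)


def generate_long_table(
    config: SimulationConfig,
    doses_per_patient: int,
    dose_range: tuple[float, float] = (0.5, 8.0),
) -> tuple[LongTable, np.ndarray]:
    """Fitting fixture with known ground truth.

    Doses are log-uniform over ``dose_range`` (keeps the dose exponent
    identifiable).  Returns the table together with the patients' true
    intercepts; the generating parameters are ``config.population``.
    """
    if doses_per_patient < 1:
        raise ValueError("doses_per_patient must be at least 1")
    lo, hi = dose_range
    if not 0 < lo < hi:
        raise ValueError("dose_range must satisfy 0 < low < high")
    rng = np.random.default_rng(config.seed)
    m = config.population
    P = config.n_patients
    alphas, X = _draw_population(config, rng)
    doses = np.exp(
        rng.uniform(math.log(lo), math.log(hi), size=(P, doses_per_patient))
    )
    eps = rng.normal(0.0, m.sigma_eps, size=(P, doses_per_patient))
    xb = X @ m.beta if m.beta.size else np.zeros(P)
    log_resp = alphas[:, None] + xb[:, None] + m.d * np.log(doses) + eps

    ids = np.repeat([f"p{i:05d}" for i in range(P)], doses_per_patient)
    table = LongTable(
        patient_id=ids,
        dose=doses.reshape(-1),
        response=np.exp(log_resp).reshape(-1),
        covariates=np.repeat(X, doses_per_patient, axis=0),
        covariate_names=m.covariate_names,
    )
    return table, alphas
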