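"""Covariate effect sizes on the response scale and the three-condition
variance-decomposition screen for candidate genetic covariates.

For a log-scale coefficient ``b``, every percentile of the response
distribution is multiplied by ``exp(b)`` when the covariate switches from 0
to 1, so ``E = (exp(b) - 1) * 100%`` is a percentile-free effect size and
``exp(-b)`` the corresponding dose-correction factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm

from .core_model import (
    FitResult,
    LongTable,
    PopulationModel,
    _design,
    _fit_arrays,
    fit_random_intercept,
)

__all__ = [
    "EffectSizeReport",
    "VariantScreenResult",
    "effect_size",
    "stratum_effect_size",
    "screen_variant",
    "effect_table",
]


@dataclass(frozen=True)
class EffectSizeReport:
    """Percent effect of a covariate on every response percentile."""

    coefficient: float
    effect_percent: float
    correction_factor: float
    ci_percent: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.effect_percent <= -100.0:
            raise ValueError("effect_percent must exceed -100")
        if self.correction_factor <= 0:
            raise ValueError("correction_factor must be positive")


def effect_size(
    beta_star: float,
    se: float | None = None,
    conf_level: float = 0.95,
) -> EffectSizeReport:
    """Effect size ``E = (exp(b) - 1) * 100`` and dose-correction factor.

    A positive E means higher concentrations per unit dose (metabolism
    inhibition when the covariate is a co-medication); negative E means
    induction.  The correction factor ``100 / (100 + E) = exp(-b)`` is the
    multiplier to apply to a patient's dose when the covariate switches from
    0 to 1.  With ``se`` given, a delta-method confidence interval for E is
    attached.
    """
    if not math.isfinite(beta_star):
        raise ValueError("beta_star must be finite")
    e = (math.exp(beta_star) - 1.0) * 100.0
    factor = 100.0 / (100.0 + e)
    ci = None
    if se is not None and math.isfinite(se):
        z = norm.ppf(0.5 + conf_level / 2.0)
        ci = (
            (math.exp(beta_star - z * se) - 1.0) * 100.0,
            (math.exp(beta_star + z * se) - 1.0) * 100.0,
        )
    return EffectSizeReport(
        coefficient=beta_star, effect_percent=e, correction_factor=factor, ci_percent=ci
    )


def stratum_effect_size(
    beta_main: float, beta_interaction: float, stratum: int
) -> EffectSizeReport:
    """Effect size within a stratum of a binary moderator.

    The covariate's log-scale coefficient in stratum ``s`` is
    ``beta_main + s * beta_interaction`` (a main effect plus an interaction
    term), so the same covariate can inhibit in one stratum and induce in the
    other.
    """
    if stratum not in (0, 1):
        raise ValueError("stratum must be 0 or 1")
    return effect_size(beta_main + stratum * beta_interaction)


def effect_table(fit: FitResult) -> list[dict]:
    """Per-covariate effect-size rows from a fitted model (for reporting)."""
    rows = []
    for name, b in zip(fit.model.covariate_names, fit.model.beta):
        se = fit.standard_errors.get(name)
        rep = effect_size(float(b), se=se)
        rows.append(
            {
                "covariate": name,
                "coefficient": rep.coefficient,
                "effect_percent": rep.effect_percent,
                "correction_factor": rep.correction_factor,
                "ci_low_percent": rep.ci_percent[0] if rep.ci_percent else None,
                "ci_high_percent": rep.ci_percent[1] if rep.ci_percent else None,
            }
        )
    return rows


@dataclass
class VariantScreenResult:
    """Outcome of the three-condition screen for one candidate covariate.

    Conditions: (1) the variant's coefficient differs from zero; (2) adding
    the variant significantly reduces the between-patient variance; (3) it
    does NOT significantly reduce the within-patient variance.  A variant is
    worth pursuing only when all three hold simultaneously.
    """

    variant: str
    coefficient: float
    coef_p: float
    delta_sigma_alpha2: float
    delta_sigma_eps2: float
    p_alpha_reduction: float
    p_eps_reduction: float
    condition1: bool
    condition2: bool
    condition3: bool
    passed: bool
    alpha_level: float
    n_boot: int
    warnings: list[str]

    def __post_init__(self) -> None:
        for p in (self.coef_p, self.p_alpha_reduction, self.p_eps_reduction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("p-values must lie in [0, 1]")
        if self.passed != (self.condition1 and self.condition2 and self.condition3):
            raise ValueError("overall verdict must equal the conjunction")


def _raw_fit(table: LongTable, fix_d_at_one: bool, reml: bool):
    """(coef, sa2, se2, loglik, y, X, codes) on prepared arrays."""
    codes = table.group_codes()
    y, X = _design(table, fix_d_at_one)
    coef, sa2, se2, ll, _ = _fit_arrays(y, X, codes, reml=reml)
    return coef, sa2, se2, ll, y, X, codes


def screen_variant(
    data: LongTable,
    base_covariates: Sequence[str],
    variant_covariate: str,
    alpha_level: float = 0.05,
    n_boot: int = 500,
    seed: int | None = None,
    fix_d_at_one: bool = False,
) -> VariantScreenResult:
    """Three-condition variance-decomposition screen of one candidate column.

    Fits the model with and without ``variant_covariate``.  Condition 1 is a
    1-df likelihood-ratio test on the variant coefficient (ML fits).
    Conditions 2-3 compare the observed drops in the two variance components
    (REML fits, the package's variance-component default) against their
    parametric-bootstrap null distributions, simulated from the fitted base
    model over the observed design (one-sided).  Deterministic given
    ``seed``.
    """
    if variant_covariate not in data.covariate_names:
        raise ValueError(f"variant column {variant_covariate!r} not found")
    if variant_covariate in base_covariates:
        raise ValueError("variant column must not be among the base covariates")
    warnings: list[str] = []
    if n_boot < 200:
        warnings.append(
            f"n_boot={n_boot} is below 200; bootstrap p-values will be coarse"
        )

    base = data.with_covariates(list(base_covariates))
    aug = data.with_covariates(list(base_covariates) + [variant_covariate])

    _, _, _, ll_b_ml, _, _, _ = _raw_fit(base, fix_d_at_one, reml=False)
    coef_a_ml, _, _, ll_a_ml, _, _, _ = _raw_fit(aug, fix_d_at_one, reml=False)
    coef_b, sa2_b, se2_b, _, y_b, X_b, codes = _raw_fit(base, fix_d_at_one, reml=True)
    _, sa2_a, se2_a, _, _, X_a, _ = _raw_fit(aug, fix_d_at_one, reml=True)

    lrt = max(2.0 * (ll_a_ml - ll_b_ml), 0.0)
    coef_p = float(chi2.sf(lrt, df=1))
    # the variant column sits right after the base covariates in the design
    variant_coef = float(coef_a_ml[1 + len(base_covariates)])

    d_sa2 = sa2_b - sa2_a
    d_se2 = se2_b - se2_a

    # parametric bootstrap of the variance drops under the base model
    rng = np.random.default_rng(seed)
    order = np.argsort(codes, kind="stable")
    codes_sorted = codes[order]
    Xb_s = X_b[order]
    Xa_s = X_a[order]
    G = int(codes_sorted.max()) + 1
    mean_b = Xb_s @ coef_b
    sig_a, sig_e = math.sqrt(max(sa2_b, 0.0)), math.sqrt(se2_b)

    boot_d_sa2 = np.empty(n_boot)
    boot_d_se2 = np.empty(n_boot)
    for b in range(n_boot):
        alpha_dev = rng.normal(0.0, sig_a, size=G)[codes_sorted]
        y_star = mean_b + alpha_dev + rng.normal(0.0, sig_e, size=mean_b.size)
        _, bs_sa2, bs_se2, _, _ = _fit_arrays(y_star, Xb_s, codes_sorted, reml=True)
        _, as_sa2, as_se2, _, _ = _fit_arrays(y_star, Xa_s, codes_sorted, reml=True)
        boot_d_sa2[b] = bs_sa2 - as_sa2
        boot_d_se2[b] = bs_se2 - as_se2

    p_alpha = float((1 + np.sum(boot_d_sa2 >= d_sa2)) / (n_boot + 1))
    p_eps = float((1 + np.sum(boot_d_se2 >= d_se2)) / (n_boot + 1))

    c1 = coef_p <= alpha_level
    c2 = p_alpha <= alpha_level
    c3 = p_eps > alpha_level
    return VariantScreenResult(
        variant=variant_covariate,
        coefficient=variant_coef,
        coef_p=coef_p,
        delta_sigma_alpha2=float(d_sa2),
        delta_sigma_eps2=float(d_se2),
        p_alpha_reduction=p_alpha,
        p_eps_reduction=p_eps,
        condition1=bool(c1),
        condition2=bool(c2),
        condition3=bool(c3),
        passed=bool(c1 and c2 and c3),
        alpha_level=alpha_level,
        n_boot=n_boot,
        warnings=warnings,
    )
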