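"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: closed-form ANOVA for
balanced designs, numerical quadrature for the normal-normal posterior, and
brute-force grid/golden-section search for dose optimality.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate
from scipy.optimize import minimize_scalar
from scipy.stats import norm


def balanced_anova(r: np.ndarray) -> tuple[float, float, float]:
    """One-way random-effects ANOVA estimators on a (groups x replicates)
    matrix of log concentration-to-dose ratios.

    Returns (grand mean, between-variance estimate floored at 0, MSW).
    """
    G, m = r.shape
    grand = r.mean()
    gmeans = r.mean(axis=1)
    msw = ((r - gmeans[:, None]) ** 2).sum() / (G * (m - 1))
    msb = m * ((gmeans - grand) ** 2).sum() / (G - 1)
    return float(grand), max(0.0, (msb - msw) / m), float(msw)


def quadrature_posterior(
    mu: float, sa2: float, se2: float, resids: np.ndarray
) -> tuple[float, float]:
    """Posterior mean/variance of the intercept by numerical integration of
    prior x likelihood over a wide bracket."""
    resids = np.asarray(resids, dtype=float)
    n = resids.size
    # crude center/width for the integration bracket only
    center = (mu / sa2 + resids.sum() / se2) / (1.0 / sa2 + n / se2)
    width = 1.0 / math.sqrt(1.0 / sa2 + n / se2)
    lo, hi = center - 15 * width, center + 15 * width

    def log_post(a):
        ll = -0.5 * np.sum((resids - a) ** 2) / se2
        lp = -0.5 * (a - mu) ** 2 / sa2
        return ll + lp

    shift = log_post(center)

    def f(a, k):
        return a**k * math.exp(log_post(a) - shift)

    opts = dict(epsabs=1e-14, epsrel=1e-12, limit=200)
    z = integrate.quad(f, lo, hi, args=(0,), **opts)[0]
    m1 = integrate.quad(f, lo, hi, args=(1,), **opts)[0] / z
    m2 = integrate.quad(f, lo, hi, args=(2,), **opts)[0] / z
    return float(m1), float(m2 - m1**2)


def window_prob_direct(
    m: float, s: float, l1: float, l2: float
) -> float:
    """P(l1 < exp(N(m, s^2)) < l2) straight from the normal CDF."""
    return float(norm.cdf((math.log(l2) - m) / s) - norm.cdf((math.log(l1) - m) / s))


def best_dose_on_grid(
    alpha_mean: float,
    alpha_var: float,
    xb: float,
    d: float,
    se2: float,
    l1: float,
    l2: float,
    n_grid: int = 10_000,
    half_width: float = 4.0,
) -> tuple[float, float]:
    """Grid maximizer of the predictive window probability over log dose.

    The grid is centered on the log of the analytic candidate so the true
    optimum is interior.  Returns (best dose, best probability).
    """
    s = math.sqrt(alpha_var + se2)
    center = (0.5 * (math.log(l1) + math.log(l2)) - alpha_mean - xb) / d
    logd = np.linspace(center - half_width, center + half_width, n_grid)
    mean = alpha_mean + xb + d * logd
    p = norm.cdf((math.log(l2) - mean) / s) - norm.cdf((math.log(l1) - mean) / s)
    i = int(np.argmax(p))
    return float(np.exp(logd[i])), float(p[i])


def sup_window_probability(
    xb: float, d: float, se2: float, l1: float, l2: float, alpha: float
) -> float:
    """Golden-section supremum over dose of the known-intercept window
    probability."""
    s = math.sqrt(se2)

    def neg(logd):
        mean = alpha + xb + d * logd
        return -window_prob_direct(mean, s, l1, l2)

    center = (0.5 * (math.log(l1) + math.log(l2)) - alpha - xb) / d
    res = minimize_scalar(
        neg, bounds=(center - 5, center + 5), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(-res.fun)
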