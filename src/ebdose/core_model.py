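"""Random-intercept log-linear response model: data containers and (RE)ML fitting.

The model for one patient is

    log Y = alpha + beta' x + d * log D + eps,

where ``alpha`` is a patient-specific intercept, normally distributed across
the population with mean ``mu_alpha`` and variance ``sigma_alpha2``, and
``eps`` is intra-patient noise with variance ``sigma_eps2``.  Fitting profiles
the fixed effects analytically and optimizes the variance ratio
``lambda = sigma_alpha2 / sigma_eps2`` on a log scale, with the between-patient
variance floored at zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "PopulationModel",
    "LongTable",
    "FitResult",
    "fit_random_intercept",
    "log_residuals",
    "log_likelihood",
    "save_model",
    "load_model",
]

_RESERVED_COLUMNS = ("patient_id", "dose", "response")


@dataclass(frozen=True)
class PopulationModel:
    """Population parameters of the random-intercept log-linear model."""

    mu_alpha: float
    sigma_alpha2: float
    sigma_eps2: float
    beta: np.ndarray = field(default_factory=lambda: np.empty(0))
    d: float = 1.0
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        if not np.isfinite(self.mu_alpha):
            raise ValueError("mu_alpha must be finite")
        if self.sigma_alpha2 < 0:
            raise ValueError("sigma_alpha2 must be nonnegative")
        if self.sigma_eps2 <= 0:
            raise ValueError("sigma_eps2 must be strictly positive")
        if self.d <= 0:
            raise ValueError("dose exponent d must be strictly positive")
        if len(self.beta) != len(self.covariate_names):
            raise ValueError(
                f"beta has {len(self.beta)} entries but "
                f"{len(self.covariate_names)} covariate names were given"
            )

    @property
    def sigma_alpha(self) -> float:
        return math.sqrt(self.sigma_alpha2)

    @property
    def sigma_eps(self) -> float:
        return math.sqrt(self.sigma_eps2)

    def linear_predictor(self, X: Sequence[float]) -> float:
        """beta' x for a single covariate vector (excluding intercept/dose)."""
        x = np.asarray(X, dtype=float).reshape(-1)
        if x.size != self.beta.size:
            raise ValueError(
                f"covariate vector has length {x.size}, expected {self.beta.size}"
            )
        return float(self.beta @ x) if x.size else 0.0

    def to_dict(self) -> dict:
        return {
            "mu_alpha": float(self.mu_alpha),
            "sigma_alpha2": float(self.sigma_alpha2),
            "sigma_eps2": float(self.sigma_eps2),
            "beta": [float(b) for b in self.beta],
            "d": float(self.d),
            "covariate_names": list(self.covariate_names),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PopulationModel":
        return cls(
            mu_alpha=float(payload["mu_alpha"]),
            sigma_alpha2=float(payload["sigma_alpha2"]),
            sigma_eps2=float(payload["sigma_eps2"]),
            beta=np.asarray(payload.get("beta", []), dtype=float),
            d=float(payload.get("d", 1.0)),
            covariate_names=tuple(payload.get("covariate_names", ())),
        )


class LongTable:
    """Long-format repeated-measures table: one row per blood draw.

    Covariates must be constant within a patient unless explicitly exempted
    via ``time_varying_ok`` (used for screening within-patient artifact
    columns; ordinary modelling covariates are patient-level).
    """

    def __init__(
        self,
        patient_id: Sequence,
        dose: Sequence[float],
        response: Sequence[float],
        covariates: np.ndarray | None = None,
        covariate_names: Sequence[str] = (),
        time_varying_ok: Sequence[str] = (),
    ) -> None:
        self.patient_id = np.asarray(patient_id, dtype=object)
        self.dose = np.asarray(dose, dtype=float)
        self.response = np.asarray(response, dtype=float)
        n = self.patient_id.shape[0]
        if covariates is None:
            covariates = np.empty((n, 0))
        self.covariates = np.asarray(covariates, dtype=float).reshape(n, -1)
        self.covariate_names = tuple(covariate_names)
        self.time_varying_ok = frozenset(time_varying_ok)
        self._validate()

    def _validate(self) -> None:
        n = self.patient_id.shape[0]
        if n == 0:
            raise ValueError("empty table")
        if self.dose.shape != (n,) or self.response.shape != (n,):
            raise ValueError("patient_id, dose and response must have equal length")
        if self.covariates.shape[1] != len(self.covariate_names):
            raise ValueError("covariate matrix width must match covariate_names")
        if not np.all(self.dose > 0):
            raise ValueError("all doses must be strictly positive")
        if not np.all(self.response > 0):
            raise ValueError("all responses must be strictly positive")
        if not np.all(np.isfinite(self.covariates)):
            raise ValueError("covariates must be finite")
        # reject time-varying covariates (unless exempted by name)
        codes = self.group_codes()
        for j, name in enumerate(self.covariate_names):
            if name in self.time_varying_ok:
                continue
            col = self.covariates[:, j]
            firsts = np.full(self.n_patients, np.nan)
            for i, c in enumerate(codes):
                if np.isnan(firsts[c]):
                    firsts[c] = col[i]
                elif col[i] != firsts[c]:
                    raise ValueError(
                        f"covariate {name!r} varies within a patient; "
                        "time-varying covariates are not supported"
                    )

    # -- structure ---------------------------------------------------------

    def group_codes(self) -> np.ndarray:
        """Integer patient codes in order of first appearance."""
        _, idx, inv = np.unique(self.patient_id, return_index=True, return_inverse=True)
        order = np.argsort(idx)
        remap = np.empty_like(order)
        remap[order] = np.arange(order.size)
        return remap[inv]

    @property
    def n_obs(self) -> int:
        return int(self.patient_id.shape[0])

    @property
    def n_patients(self) -> int:
        return int(np.unique(self.patient_id).shape[0])

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, time_varying_ok: Sequence[str] = ()
    ) -> "LongTable":
        for col in _RESERVED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        cov_names = [c for c in df.columns if c not in _RESERVED_COLUMNS]
        return cls(
            patient_id=df["patient_id"].to_numpy(),
            dose=df["dose"].to_numpy(dtype=float),
            response=df["response"].to_numpy(dtype=float),
            covariates=df[cov_names].to_numpy(dtype=float) if cov_names else None,
            covariate_names=cov_names,
            time_varying_ok=time_varying_ok,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "dose": self.dose,
                "response": self.response,
            }
        )
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        return df

    @classmethod
    def read_csv(cls, path, time_varying_ok: Sequence[str] = ()) -> "LongTable":
        return cls.from_dataframe(pd.read_csv(path), time_varying_ok=time_varying_ok)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def with_covariates(self, names: Sequence[str]) -> "LongTable":
        """Restrict to a subset of covariate columns (order given by ``names``)."""
        idx = [self.covariate_names.index(n) for n in names]
        return LongTable(
            self.patient_id,
            self.dose,
            self.response,
            self.covariates[:, idx],
            tuple(names),
            time_varying_ok=self.time_varying_ok,
        )


@dataclass
class FitResult:
    model: PopulationModel
    standard_errors: dict[str, float]
    log_likelihood: float
    method: str
    converged: bool
    n_patients: int
    n_obs: int
    fix_d_at_one: bool = False
    message: str = ""


# ----------------------------------------------------------------------------
# internal fitting machinery


class _Sums:
    """Sufficient statistics for the profiled (restricted) likelihood.

    Rows must be sorted so that each patient's rows are contiguous.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, codes: np.ndarray) -> None:
        order = np.argsort(codes, kind="stable")
        y = y[order]
        X = X[order]
        codes = codes[order]
        starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
        self.ng = np.diff(np.r_[starts, codes.size]).astype(float)
        self.Sy = np.add.reduceat(y, starts)
        self.Sx = np.add.reduceat(X, starts, axis=0)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.N = y.size
        self.p = X.shape[1]
        self.G = self.ng.size


def _profile(lam: float, s: _Sums, reml: bool):
    """Profiled -2 log-likelihood at variance ratio ``lam``; returns
    (neg2ll, beta, sigma_eps2, XtWX)."""
    c = lam / (1.0 + lam * s.ng)
    XtWX = s.XtX - (s.Sx.T * c) @ s.Sx
    XtWy = s.Xty - s.Sx.T @ (c * s.Sy)
    ytWy = s.yty - float(c @ (s.Sy**2))
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(ytWy - float(beta @ XtWy), 1e-300)
    ld_blocks = float(np.sum(np.log1p(lam * s.ng)))
    if reml:
        dof = s.N - s.p
        s2 = rss / dof
        ld_x = np.linalg.slogdet(XtWX)[1]
        neg2 = dof * math.log(2.0 * math.pi * s2) + ld_blocks + ld_x + dof
    else:
        s2 = rss / s.N
        neg2 = s.N * math.log(2.0 * math.pi * s2) + ld_blocks + s.N
    return neg2, beta, s2, XtWX


def _neg2_at(sa2: float, se2: float, s: _Sums, reml: bool) -> float:
    """-2 log (restricted) likelihood at explicit variance components,
    fixed effects profiled out."""
    lam = sa2 / se2
    c = lam / (1.0 + lam * s.ng)
    XtWX = s.XtX - (s.Sx.T * c) @ s.Sx
    XtWy = s.Xty - s.Sx.T @ (c * s.Sy)
    ytWy = s.yty - float(c @ (s.Sy**2))
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(ytWy - float(beta @ XtWy), 1e-300)
    ld_blocks = float(np.sum(np.log1p(lam * s.ng)))
    neg2 = s.N * math.log(2.0 * math.pi * se2) + ld_blocks + rss / se2
    if reml:
        neg2 += np.linalg.slogdet(XtWX)[1] - s.p * math.log(se2)
        neg2 -= s.p * math.log(2.0 * math.pi)
    return neg2


_T_LO, _T_HI = -16.0, 16.0


def _optimize_lambda(s: _Sums, reml: bool) -> float:
    """Minimize the profiled criterion over lambda >= 0; returns lambda-hat."""
    grid = np.linspace(_T_LO, _T_HI, 33)
    vals = [_profile(math.exp(t), s, reml)[0] for t in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda t: _profile(math.exp(t), s, reml)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-11},
    )
    lam = math.exp(res.x)
    f_int = _profile(lam, s, reml)[0]
    f_zero = _profile(0.0, s, reml)[0]
    if f_zero <= f_int:
        return 0.0
    return lam


def _fit_arrays(
    y: np.ndarray,
    X: np.ndarray,
    codes: np.ndarray,
    reml: bool,
) -> tuple[np.ndarray, float, float, float, np.ndarray]:
    """Core fit on prepared arrays.

    Returns (coef, sigma_alpha2, sigma_eps2, loglik, cov_fixed).
    """
    s = _Sums(y, X, codes)
    lam = _optimize_lambda(s, reml)
    neg2, beta, se2, XtWX = _profile(lam, s, reml)
    sa2 = lam * se2
    cov_fixed = se2 * np.linalg.inv(XtWX)
    return beta, sa2, se2, -0.5 * neg2, cov_fixed


def _variance_ses(sa2: float, se2: float, s: _Sums, reml: bool) -> tuple[float, float]:
    """Standard errors of the variance components from the observed
    information of the profiled criterion; NaN for a boundary sigma_alpha2."""

    def f(v):
        return _neg2_at(max(v[0], 0.0), v[1], s, reml)

    if sa2 <= 0.0:
        h = 1e-4 * max(se2, 1e-4)
        d2 = (f((0.0, se2 + h)) - 2.0 * f((0.0, se2)) + f((0.0, se2 - h))) / h**2
        var = 2.0 / d2 if d2 > 0 else math.nan
        return math.nan, math.sqrt(var) if var > 0 else math.nan
    v0 = np.array([sa2, se2])
    h = 1e-4 * np.maximum(v0, 1e-4)
    H = np.empty((2, 2))
    for i in range(2):
        for j in range(i, 2):
            vpp = v0.copy(); vpp[i] += h[i]; vpp[j] += h[j]
            vpm = v0.copy(); vpm[i] += h[i]; vpm[j] -= h[j]
            vmp = v0.copy(); vmp[i] -= h[i]; vmp[j] += h[j]
            vmm = v0.copy(); vmm[i] -= h[i]; vmm[j] -= h[j]
            H[i, j] = H[j, i] = (f(vpp) - f(vpm) - f(vmp) + f(vmm)) / (4 * h[i] * h[j])
    try:
        cov = 2.0 * np.linalg.inv(H)
        d = np.diag(cov)
        return (
            math.sqrt(d[0]) if d[0] > 0 else math.nan,
            math.sqrt(d[1]) if d[1] > 0 else math.nan,
        )
    except np.linalg.LinAlgError:
        return math.nan, math.nan


def _design(table: LongTable, fix_d_at_one: bool) -> tuple[np.ndarray, np.ndarray]:
    """Response vector and fixed-effects design matrix (intercept first,
    then covariates, then log dose when d is estimated)."""
    logy = np.log(table.response)
    logd = np.log(table.dose)
    cols = [np.ones(table.n_obs), table.covariates]
    if fix_d_at_one:
        y = logy - logd
    else:
        y = logy
        cols.append(logd[:, None])
    X = np.column_stack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in cols])
    return y, X


def fit_random_intercept(
    data: LongTable,
    fix_d_at_one: bool = False,
    method: str = "REML",
) -> FitResult:
    """Fit the random-intercept model by maximum (restricted) likelihood.

    Parameters
    ----------
    data:
        Long-format repeated-measures table.
    fix_d_at_one:
        If True, constrain the dose exponent to 1 (linear kinetics) by
        modelling ``log(response/dose)``; otherwise ``d`` is estimated as the
        coefficient of log dose.
    method:
        ``"REML"`` (default) or ``"ML"``.
    """
    method = method.upper()
    if method not in ("ML", "REML"):
        raise ValueError(f"unknown method {method!r}; expected 'ML' or 'REML'")
    codes = data.group_codes()
    counts = np.bincount(codes)
    if counts.size < 2:
        raise ValueError("at least 2 patients are required")
    if counts.max() < 2:
        raise ValueError(
            "variance components not separable: every patient has a single observation"
        )
    y, X = _design(data, fix_d_at_one)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient; drop collinear covariates"
        )
    if X.shape[0] <= X.shape[1]:
        raise ValueError("more parameters than observations")

    reml = method == "REML"
    coef, sa2, se2, loglik, cov_fixed = _fit_arrays(y, X, codes, reml)

    k = data.n_covariates
    mu_alpha = float(coef[0])
    beta = np.asarray(coef[1 : 1 + k], dtype=float)
    d = 1.0 if fix_d_at_one else float(coef[-1])
    if d <= 0:
        return FitResult(
            model=PopulationModel(mu_alpha, sa2, se2, beta, 1.0, data.covariate_names),
            standard_errors={},
            log_likelihood=loglik,
            method=method,
            converged=False,
            n_patients=data.n_patients,
            n_obs=data.n_obs,
            fix_d_at_one=fix_d_at_one,
            message=f"estimated dose exponent d={d:.4g} is nonpositive",
        )
    model = PopulationModel(
        mu_alpha=mu_alpha,
        sigma_alpha2=sa2,
        sigma_eps2=se2,
        beta=beta,
        d=d,
        covariate_names=data.covariate_names,
    )
    fe_se = np.sqrt(np.maximum(np.diag(cov_fixed), 0.0))
    ses: dict[str, float] = {"mu_alpha": float(fe_se[0])}
    for j, name in enumerate(data.covariate_names):
        ses[name] = float(fe_se[1 + j])
    if not fix_d_at_one:
        ses["d"] = float(fe_se[-1])
    s = _Sums(y, X, codes)
    se_sa2, se_se2 = _variance_ses(sa2, se2, s, reml)
    ses["sigma_alpha2"] = se_sa2
    ses["sigma_eps2"] = se_se2

    converged = bool(np.isfinite(loglik) and se2 > 0)
    return FitResult(
        model=model,
        standard_errors=ses,
        log_likelihood=loglik,
        method=method,
        converged=converged,
        n_patients=data.n_patients,
        n_obs=data.n_obs,
        fix_d_at_one=fix_d_at_one,
        message="" if converged else "non-finite objective at optimum",
    )


def log_likelihood(
    data: LongTable,
    model: PopulationModel,
    method: str = "ML",
    fix_d_at_one: bool = False,
) -> float:
    """Log (restricted) likelihood of ``data`` at the given parameter values.

    For ``method="ML"`` all parameters of ``model`` are used.  For
    ``method="REML"`` the criterion depends on the variance components only
    (fixed effects are profiled out), so the mean parameters of ``model`` are
    ignored; this is the quantity maximized by :func:`fit_random_intercept`
    with ``method="REML"``.
    """
    method = method.upper()
    codes = data.group_codes()
    y, X = _design(data, fix_d_at_one)
    s = _Sums(y, X, codes)
    if method == "REML":
        return -0.5 * _neg2_at(model.sigma_alpha2, model.sigma_eps2, s, reml=True)
    if method != "ML":
        raise ValueError(f"unknown method {method!r}")
    coef = np.r_[model.mu_alpha, model.beta]
    if not fix_d_at_one:
        coef = np.r_[coef, model.d]
    lam = model.sigma_alpha2 / model.sigma_eps2
    se2 = model.sigma_eps2
    c = lam / (1.0 + lam * s.ng)
    e = y - X @ coef
    order = np.argsort(codes, kind="stable")
    es = e[order]
    starts = np.flatnonzero(np.r_[True, np.diff(codes[order]) != 0])
    Se = np.add.reduceat(es, starts)
    quad = float(es @ es - c @ (Se**2)) / se2
    ld = s.N * math.log(2.0 * math.pi * se2) + float(np.sum(np.log1p(lam * s.ng)))
    return -0.5 * (ld + quad)


def log_residuals(
    model: PopulationModel,
    patient_covariates: Sequence[float],
    doses: Sequence[float],
    responses: Sequence[float],
) -> np.ndarray:
    """Per-observation signal ``r_j = log Y_j - beta'x - d log D_j``.

    Under the model, ``r_j = alpha + eps_j``: the patient-specific intercept
    plus noise, with dose and covariate contributions removed.
    """
    doses = np.asarray(doses, dtype=float).reshape(-1)
    responses = np.asarray(responses, dtype=float).reshape(-1)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have equal length")
    if np.any(doses <= 0) or np.any(responses <= 0):
        raise ValueError("doses and responses must be strictly positive")
    xb = model.linear_predictor(patient_covariates)
    return np.log(responses) - xb - model.d * np.log(doses)


def save_model(path, fit_or_model: FitResult | PopulationModel) -> None:
    """Serialize a fitted model (or a bare :class:`PopulationModel`) to JSON."""
    if isinstance(fit_or_model, FitResult):
        payload = fit_or_model.model.to_dict()
        payload["method"] = fit_or_model.method
        payload["log_likelihood"] = float(fit_or_model.log_likelihood)
        payload["standard_errors"] = {
            k: (None if not np.isfinite(v) else float(v))
            for k, v in fit_or_model.standard_errors.items()
        }
    else:
        payload = fit_or_model.to_dict()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_model(path) -> PopulationModel:
    """Load a :class:`PopulationModel` from a JSON file written by
    :func:`save_model`."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return PopulationModel.from_dict(payload)
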