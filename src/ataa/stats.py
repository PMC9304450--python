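"""Censored lifespan regression and biomarker correlation maps.

A right-censored Gaussian (Tobit) regression links biomarkers to lifespan:
subjects still alive at the censor level (default 25 months) contribute
survival terms to the likelihood.  Goodness of fit is summarized by a
pseudo-r-squared; two conventions are provided:

``"mckelvey_zavoina"``
    Explained latent variance ``sum((yhat - mean(yhat))^2)`` over itself
    plus ``N * sigma^2`` with the MLE error variance.
``"squared_correlation"``
    Squared Pearson correlation between observed responses and fitted
    values.

Both reduce exactly to the OLS r-squared when no observation is censored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "DEFAULT_CENSOR_LEVEL",
    "CohortTable",
    "TobitFit",
    "CorrelationMap",
    "tobit_fit",
    "pseudo_r2",
    "correlation_map",
    "delta_biomarkers",
]

DEFAULT_CENSOR_LEVEL = 25.0  # months

PSEUDO_R2_METHODS = ("mckelvey_zavoina", "squared_correlation")


@dataclass
class CohortTable:
    """Per-subject biomarker/lifespan table with right-censoring flags."""

    df: pd.DataFrame
    censor_level: float = DEFAULT_CENSOR_LEVEL
    lifespan_col: str = "lifespan_months"
    censored_col: str = "censored"
    subject_col: str = "subject_id"
    strict: bool = True

    def __post_init__(self) -> None:
        for col in (self.subject_col, self.lifespan_col, self.censored_col):
            if col not in self.df.columns:
                raise ValueError(f"cohort table missing column {col!r}")
        if len(self.df) < 3:
            raise ValueError("cohort needs at least 3 subjects")
        ls = self.df[self.lifespan_col].to_numpy(dtype=float)
        cen = self.df[self.censored_col].to_numpy(dtype=bool)
        if np.any(ls > self.censor_level + 1e-9):
            raise ValueError("lifespan exceeds the censor level")
        if self.strict:
            at_max = np.isclose(ls, self.censor_level)
            if not np.array_equal(cen, at_max):
                raise ValueError(
                    "censored flag must equal (lifespan == censor level); "
                    "pass strict=False to override")

    @property
    def biomarker_columns(self) -> list[str]:
        skip = {self.subject_col, self.lifespan_col, self.censored_col}
        return [c for c in self.df.columns
                if c not in skip and pd.api.types.is_numeric_dtype(self.df[c])]

    @classmethod
    def from_csv(cls, path, censor_level: float = DEFAULT_CENSOR_LEVEL,
                 **kw) -> "CohortTable":
        return cls(pd.read_csv(path, comment="#"),
                   censor_level=censor_level, **kw)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class TobitFit:
    beta: np.ndarray            # intercept first, then slope(s)
    sigma: float
    loglik: float
    pseudo_r2: float
    slope_sign: int
    converged: bool
    n_obs: int
    n_censored: int
    y_max: float
    standard_errors: np.ndarray | None = None
    method: str = "mckelvey_zavoina"

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    @property
    def slope(self) -> float:
        return float(self.beta[1])

    def predict(self, x) -> np.ndarray:
        X = _design(x)
        return X @ self.beta

    def to_dict(self) -> dict:
        return {
            "beta": list(map(float, self.beta)),
            "sigma": self.sigma,
            "loglik": self.loglik,
            "pseudo_r2": self.pseudo_r2,
            "pseudo_r2_method": self.method,
            "slope_sign": self.slope_sign,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_censored": self.n_censored,
            "y_max": self.y_max,
            "standard_errors": (None if self.standard_errors is None
                                else list(map(float, self.standard_errors))),
        }


def _design(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return np.column_stack([np.ones(len(x)), x])


def _neg_loglik(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                cen: np.ndarray, y_max: float) -> float:
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    mu = X @ beta
    ll = np.where(
        cen,
        norm.logsf((y_max - mu) / sigma),
        norm.logpdf((y - mu) / sigma) - log_sigma,
    )
    return -float(ll.sum())


def _numeric_hessian(fun, x0: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    n = len(x0)
    h = np.empty((n, n))
    steps = eps * np.maximum(1.0, np.abs(x0))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            fpp = fun(x0 + ei + ej)
            fpm = fun(x0 + ei - ej)
            fmp = fun(x0 - ei + ej)
            fmm = fun(x0 - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return h


def tobit_fit(x, y, censored, y_max: float = DEFAULT_CENSOR_LEVEL,
              pseudo_r2_method: str = "mckelvey_zavoina") -> TobitFit:
    """Right-censored Gaussian MLE of ``y = X beta + u``.

    Uncensored rows contribute density terms, censored rows survival
    terms ``log(1 - Phi((y_max - X beta)/sigma))``.  Optimization is
    quasi-Newton on ``(beta, log sigma)`` from the OLS starting point and
    is deterministic for fixed data.  With zero censored rows the OLS
    closed form (sigma the MLE variant) is the exact maximizer and is
    returned directly.
    """
    X = _design(x)
    y = np.asarray(y, dtype=float)
    cen = np.asarray(censored, dtype=bool)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if X.shape[0] != n or len(cen) != n:
        raise ValueError("x, y, censored must share one length")
    if cen.all():
        raise ValueError("all observations censored; model is not estimable")
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"predictor column {j - 1} is constant")

    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    sigma_ols = float(np.sqrt(np.mean(resid**2)))
    sigma_ols = max(sigma_ols, 1e-8)

    if not cen.any():
        beta_hat, sigma_hat = beta_ols, sigma_ols
        theta_hat = np.r_[beta_hat, np.log(sigma_hat)]
        converged = True
    else:
        theta0 = np.r_[beta_ols, np.log(sigma_ols)]
        res = minimize(_neg_loglik, theta0, args=(X, y, cen, y_max),
                       method="BFGS",
                       options={"gtol": 1e-8, "maxiter": 1000})
        if not res.success:  # polish with a derivative-free pass
            res2 = minimize(_neg_loglik, res.x, args=(X, y, cen, y_max),
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20000})
            res = res2 if res2.fun <= res.fun else res
        theta_hat = res.x
        beta_hat = theta_hat[:-1]
        sigma_hat = float(np.exp(theta_hat[-1]))
        converged = bool(res.success
                         or np.isfinite(res.fun))

    loglik = -_neg_loglik(theta_hat, X, y, cen, y_max)
    start_ll = -_neg_loglik(np.r_[beta_ols, np.log(sigma_ols)], X, y, cen,
                            y_max)
    if loglik < start_ll - 1e-8:
        converged = False
        warnings.warn("Tobit optimizer ended below its OLS starting point",
                      stacklevel=2)

    se = None
    try:
        hess = _numeric_hessian(
            lambda t: _neg_loglik(t, X, y, cen, y_max), theta_hat)
        cov = np.linalg.inv(hess)
        # delta method for sigma (fitted on the log scale)
        se_full = np.sqrt(np.clip(np.diag(cov), 0, None))
        se = se_full[:-1]
    except np.linalg.LinAlgError:
        pass

    fit = TobitFit(
        beta=beta_hat, sigma=sigma_hat, loglik=loglik, pseudo_r2=np.nan,
        slope_sign=int(np.sign(beta_hat[1])) if len(beta_hat) > 1 else 0,
        converged=converged, n_obs=n, n_censored=int(cen.sum()), y_max=y_max,
        standard_errors=se, method=pseudo_r2_method)
    fit.pseudo_r2 = pseudo_r2(fit, x, y, method=pseudo_r2_method)
    return fit


def pseudo_r2(fit: TobitFit, x, y, method: str = "mckelvey_zavoina") -> float:
    """Pseudo-r-squared of a (possibly censored) fit; in [0, 1].

    ``mckelvey_zavoina`` uses the fitted latent values and the estimated
    error variance; ``squared_correlation`` is the squared Pearson
    correlation of observed vs fitted.  Both equal the OLS r-squared on
    fully uncensored data.
    """
    if method not in PSEUDO_R2_METHODS:
        raise ValueError(f"unknown pseudo-r2 method {method!r}")
    if not fit.converged:
        raise ValueError("pseudo_r2 requires a converged fit")
    y = np.asarray(y, dtype=float)
    yhat = fit.predict(x)
    if method == "mckelvey_zavoina":
        ssm = float(np.sum((yhat - yhat.mean()) ** 2))
        denom = ssm + fit.n_obs * fit.sigma**2
        if denom <= 0:
            warnings.warn("degenerate variance; pseudo-r2 set to 0",
                          stacklevel=2)
            return 0.0
        return ssm / denom
    sy = float(np.std(y))
    syh = float(np.std(yhat))
    if sy == 0 or syh == 0:
        warnings.warn("degenerate variance; pseudo-r2 set to 0", stacklevel=2)
        return 0.0
    r = float(np.corrcoef(y, yhat)[0, 1])
    return min(r * r, 1.0)


@dataclass
class CorrelationMap:
    """Pairwise signed r-squared matrix over cohort variables.

    Cells with lifespan as the dependent variable use the censored (Tobit)
    fit and its pseudo-r-squared; biomarker-biomarker cells use plain OLS
    r-squared.  ``signs`` carries the fitted slope sign, ``methods`` which
    route produced each cell.
    """

    variables: list[str]
    r2: pd.DataFrame
    signs: pd.DataFrame
    methods: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def signed(self) -> pd.DataFrame:
        return self.r2 * self.signs

    def to_csv(self, path) -> None:
        self.signed().to_csv(path)

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, indent=2, sort_keys=True)


def correlation_map(table: CohortTable, variables: list[str] | None = None,
                    pseudo_r2_method: str = "mckelvey_zavoina",
                    lifespan_label: str = "LS") -> CorrelationMap:
    """Build the biomarker/lifespan correlation map.

    ``variables`` defaults to every numeric biomarker column; the lifespan
    column is always appended (labelled ``lifespan_label``).
    """
    if variables is None:
        variables = table.biomarker_columns
    missing = [v for v in variables if v not in table.df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if len(variables) < 1:
        raise ValueError("need at least one biomarker variable")

    df = table.df
    y = df[table.lifespan_col].to_numpy(dtype=float)
    cen = df[table.censored_col].to_numpy(dtype=bool)
    labels = list(variables) + [lifespan_label]
    k = len(labels)
    r2_m = pd.DataFrame(np.eye(k), index=labels, columns=labels)
    sign_m = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    meth_m = pd.DataFrame([["self"] * k for _ in range(k)],
                          index=labels, columns=labels)
    manifest: dict = {"n_subjects": len(df), "n_censored": int(cen.sum()),
                      "pseudo_r2_method": pseudo_r2_method,
                      "n_tests": 0, "cells": {}}

    def ols_cell(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return 0.0, 0
        r = float(np.corrcoef(a, b)[0, 1])
        return r * r, int(np.sign(r)) or 1

    for i, vi in enumerate(variables):
        xi = df[vi].to_numpy(dtype=float)
        # lifespan-dependent cell via censored regression
        fit = tobit_fit(xi, y, cen, y_max=table.censor_level,
                        pseudo_r2_method=pseudo_r2_method)
        r2v, sg = fit.pseudo_r2, fit.slope_sign or 1
        for a, b in ((vi, lifespan_label), (lifespan_label, vi)):
            r2_m.loc[a, b] = r2v
            sign_m.loc[a, b] = sg
            meth_m.loc[a, b] = "tobit"
        manifest["cells"][f"{vi}|{lifespan_label}"] = fit.to_dict()
        manifest["n_tests"] += 1
        for vj in variables[i + 1:]:
            xj = df[vj].to_numpy(dtype=float)
            r2v, sg = ols_cell(xi, xj)
            for a, b in ((vi, vj), (vj, vi)):
                r2_m.loc[a, b] = r2v
                sign_m.loc[a, b] = sg
                meth_m.loc[a, b] = "ols"
            manifest["cells"][f"{vi}|{vj}"] = {"r2": r2v, "sign": sg}
            manifest["n_tests"] += 1

    return CorrelationMap(variables=labels, r2=r2_m, signs=sign_m,
                          methods=meth_m, manifest=manifest)


def delta_biomarkers(table_t1: CohortTable, table_t2: CohortTable,
                     prefix: str = "delta_") -> pd.DataFrame:
    """Absolute between-timepoint differences per subject and biomarker.

    Returns one row per subject with ``delta_<col> = |x_t2 - x_t1|`` for
    every biomarker column present in both tables, plus the (t2) lifespan
    and censoring columns.
    """
    sc = table_t1.subject_col
    ids1 = set(table_t1.df[sc])
    ids2 = set(table_t2.df[sc])
    unmatched = sorted(ids1 ^ ids2)
    if unmatched:
        raise ValueError(f"unmatched subject ids: {unmatched}")
    common = [c for c in table_t1.biomarker_columns
              if c in table_t2.biomarker_columns]
    d1 = table_t1.df.set_index(sc)
    d2 = table_t2.df.set_index(sc).loc[d1.index]
    out = pd.DataFrame(index=d1.index)
    for c in common:
        out[prefix + c] = (d2[c] - d1[c]).abs()
    out[table_t2.lifespan_col] = d2[table_t2.lifespan_col]
    out[table_t2.censored_col] = d2[table_t2.censored_col]
    return out.reset_index()
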