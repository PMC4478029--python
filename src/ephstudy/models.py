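"""Linear-regression models for ePASP over multiply-imputed data.

Two model stages, mirroring a conventional two-step epidemiological
association analysis:

* **Model A** — one fit per factor of interest, adjusted for age and
  sex (age's own fit adjusts for sex only, sex's for age only); fitted
  in every imputed copy and pooled with Rubin's rules.
* **Model B** — a single multivariable fit containing exactly the
  factors whose pooled Model-A p-value is below 0.05 (strict, on the
  unrounded value), entered simultaneously and pooled the same way.

Fits are restricted to participants with estimable ePASP; the outcome
is never imputed.  Internally coefficients are estimated on raw scales;
reported effects are rescaled deterministically to the conventional
display units (per 10 years of age, per 5 kg/m^2 of BMI, per 10% of
fractional shortening).

Pooling follows Rubin's rules: pooled estimate = mean of per-copy
estimates; total variance T = W + (1 + 1/m) B with W the mean
within-copy variance and B the between-copy variance; single-parameter
inference uses a t reference with the standard MI degrees of freedom,
multi-parameter (factor-level) tests use the pooled Wald statistic with
an average relative-variance correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .impute import ImputedSet

OUTCOME = "epasp"


@dataclass(frozen=True)
class Factor:
    """One candidate determinant of ePASP and how it enters the design."""

    name: str
    kind: str                      # continuous | binary | categorical
    scale: float = 1.0             # display units per raw unit (divisor)
    label: str = ""
    levels: tuple = ()             # categorical only; first level = reference

    def terms(self) -> list[str]:
        if self.kind == "categorical":
            return [f"{self.name}[{lv}]" for lv in self.levels[1:]]
        return [self.name]

    def columns(self, df: pd.DataFrame) -> np.ndarray:
        if self.kind == "categorical":
            v = df[self.name].to_numpy(object)
            return np.column_stack([(v == lv).astype(float) for lv in self.levels[1:]])
        return df[self.name].to_numpy(float).reshape(-1, 1)


FACTORS: dict[str, Factor] = {
    "age": Factor("age", "continuous", scale=10.0, label="Age, per 10 years"),
    "female": Factor("female", "binary", label="Women"),
    "bmi": Factor("bmi", "continuous", scale=5.0,
                  label="Body mass index, per 5 kg/m^2"),
    "smoking": Factor("smoking", "categorical", label="Smoking",
                      levels=("never", "former", "current")),
    "fs": Factor("fs", "continuous", scale=10.0,
                 label="LV fractional shortening, per 10%"),
    "diastolic_stage": Factor("diastolic_stage", "categorical",
                              label="LV diastolic dysfunction",
                              levels=("normal_or_stage1", "stage2", "stage3_4")),
    "copd": Factor("copd", "binary", label="COPD"),
    "diabetes": Factor("diabetes", "binary", label="Diabetes mellitus"),
    "hypertension": Factor("hypertension", "binary", label="Systemic hypertension"),
}


@dataclass
class PooledTerm:
    term: str
    factor: str
    estimate: float      # display scale
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    df: float


@dataclass
class ModelFit:
    label: str                      # "A:<factor>" or "B"
    m: int
    n: int
    terms: list[PooledTerm]
    factor_p: dict[str, float]      # omnibus p per factor
    selected: list[str] = field(default_factory=list)

    def term(self, name: str) -> PooledTerm:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"model": self.label, "factor": t.factor, "term": t.term,
                 "estimate": t.estimate, "se": t.se,
                 "ci_low": t.ci_low, "ci_high": t.ci_high,
                 "p_value": t.p_value, "factor_p": self.factor_p.get(t.factor)}
                for t in self.terms]
        return pd.DataFrame(rows)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classical OLS point estimates and parameter covariance."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    if dof <= 0:
        raise ValueError("more parameters than observations")
    sigma2 = (resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return beta, cov


def rubin_pool(estimates: np.ndarray, covariances: np.ndarray,
               dfcom: float | None = None):
    """Rubin's rules for m sets of estimates with covariances.

    Returns ``(qbar, T, df)``: pooled estimates, total-variance matrix
    and per-parameter degrees of freedom (Barnard–Rubin small-sample
    adjustment when ``dfcom`` is given; +inf where the between-copy
    variance vanishes).
    """
    estimates = np.asarray(estimates, float)
    covariances = np.asarray(covariances, float)
    m = estimates.shape[0]
    if m < 2:
        raise ValueError("pooling needs m >= 2 fits")
    if covariances.shape[0] != m:
        raise ValueError("mismatched number of estimate/covariance sets")
    qbar = estimates.mean(axis=0)
    W = covariances.mean(axis=0)
    dev = estimates - qbar
    B = dev.T @ dev / (m - 1)
    T = W + (1.0 + 1.0 / m) * B

    bd = np.diag(B)
    td = np.diag(T)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = (1.0 + 1.0 / m) * bd / td
        df_old = np.where(bd > 0, (m - 1) / np.square(lam), np.inf)
    if dfcom is not None:
        df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
        df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    else:
        df = df_old
    return qbar, T, df


def _wald_factor_p(qbar, W, B, T, idx, m) -> float:
    """Pooled multi-parameter Wald test for the terms at ``idx``.

    Single-df factors reduce to the pooled t test; multi-df factors use
    the pooled Wald statistic on the within covariance with the average
    relative-increase-in-variance correction.
    """
    idx = np.asarray(idx)
    k = len(idx)
    q = qbar[idx]
    if k == 1:
        t2 = q[0] ** 2 / T[idx[0], idx[0]]
        lam = (1 + 1.0 / m) * B[idx[0], idx[0]] / T[idx[0], idx[0]]
        df = (m - 1) / lam ** 2 if lam > 0 else np.inf
        return float(2 * stats.t.sf(np.sqrt(t2), df))
    Wk = W[np.ix_(idx, idx)]
    Bk = B[np.ix_(idx, idx)]
    r = (1 + 1.0 / m) * np.trace(Bk @ np.linalg.pinv(Wk)) / k
    F = q @ np.linalg.pinv(Wk) @ q / (k * (1 + r))
    t = k * (m - 1)
    if r <= 0:
        df2 = np.inf
    elif t > 4:
        df2 = 4 + (t - 4) * (1 + (1 - 2.0 / t) / r) ** 2
    else:
        df2 = t * (1 + 1.0 / k) * (1 + 1.0 / r) ** 2 / 2.0
    return float(stats.f.sf(F, k, df2))


def _design(df: pd.DataFrame, factors: list[Factor]):
    """Intercept-first design matrix; duplicate columns are dropped."""
    names = ["intercept"]
    cols = [np.ones(len(df))]
    owner = [None]
    for f in factors:
        block = f.columns(df)
        for j, term in enumerate(f.terms()):
            if term in names:
                continue
            names.append(term)
            cols.append(block[:, j])
            owner.append(f.name)
    return np.column_stack(cols), names, owner


def _fit_pooled(imputed: ImputedSet, factors: list[Factor], label: str) -> ModelFit:
    ests, covs, n_used = [], [], 0
    for copy in imputed.copies:
        sub = copy[copy[OUTCOME].notna()]
        X, names, owner = _design(sub, factors)
        y = sub[OUTCOME].to_numpy(float)
        beta, cov = _ols(X, y)
        ests.append(beta)
        covs.append(cov)
        n_used = len(sub)
    ests = np.asarray(ests)
    covs = np.asarray(covs)
    dfcom = n_used - ests.shape[1]
    qbar, T, df = rubin_pool(ests, covs, dfcom=dfcom)
    W = covs.mean(axis=0)
    dev = ests - qbar
    B = dev.T @ dev / (len(ests) - 1)

    terms = []
    for j, (term, fac) in enumerate(zip(names, owner)):
        if fac is None:
            continue
        scale = next(f.scale for f in factors if f.name == fac)
        se = np.sqrt(T[j, j])
        tcrit = stats.t.ppf(0.975, df[j]) if np.isfinite(df[j]) else stats.norm.ppf(0.975)
        p = 2 * stats.t.sf(abs(qbar[j]) / se, df[j]) if se > 0 else np.nan
        terms.append(PooledTerm(
            term=term, factor=fac,
            estimate=qbar[j] * scale, se=se * scale,
            ci_low=(qbar[j] - tcrit * se) * scale,
            ci_high=(qbar[j] + tcrit * se) * scale,
            p_value=float(p), df=float(df[j]),
        ))
    factor_p = {}
    for f in factors:
        idx = [j for j, fac in enumerate(owner) if fac == f.name]
        if idx:
            factor_p[f.name] = _wald_factor_p(qbar, W, B, T, idx, imputed.m)
    return ModelFit(label=label, m=imputed.m, n=n_used, terms=terms,
                    factor_p=factor_p)


def fit_model_a(imputed: ImputedSet, factor: str,
                factors: dict[str, Factor] = FACTORS) -> ModelFit:
    """Age- and sex-adjusted fit for one factor, pooled over imputations.

    When the factor of interest is age or sex itself, the fit adjusts
    only for the other of the two (no duplicated column).
    """
    f = factors[factor]
    if imputed.copies[0][f.name].nunique(dropna=True) < 2:
        raise ValueError(f"factor {factor!r} is constant")
    adjust = [factors[a] for a in ("age", "female") if a != factor]
    return _fit_pooled(imputed, [f] + adjust, label=f"A:{factor}")


def select_factors(model_a_fits: dict[str, ModelFit], alpha: float = 0.05) -> list[str]:
    """Factors whose pooled Model-A omnibus p is strictly below alpha."""
    return [name for name, fit in model_a_fits.items()
            if fit.factor_p.get(name, np.inf) < alpha]


def fit_model_b(imputed: ImputedSet, model_a_fits: dict[str, ModelFit],
                factors: dict[str, Factor] = FACTORS,
                alpha: float = 0.05) -> ModelFit:
    """Multivariable fit of all Model-A-significant factors, pooled.

    Raises ``ValueError`` when no factor passes the selection rule.
    """
    selected = select_factors(model_a_fits, alpha)
    if not selected:
        raise ValueError("no factor passed the p < %.2f selection rule" % alpha)
    design = [factors[name] for name in selected]
    fit = _fit_pooled(imputed, design, label="B")
    fit.selected = selected
    return fit


def run_models(imputed: ImputedSet,
               factors: dict[str, Factor] = FACTORS,
               alpha: float = 0.05) -> tuple[dict[str, ModelFit], ModelFit]:
    """Full Model A screening plus the Model B multivariable fit."""
    fits_a = {name: fit_model_a(imputed, name, factors) for name in factors}
    fit_b = fit_model_b(imputed, fits_a, factors, alpha)
    return fits_a, fit_b
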