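"""Synthetic cohort generator for the echo pulmonary-hypertension pipeline.

Generates per-participant records with the statistical structure the
analysis assumes, so that every downstream stage (derivation, case
ascertainment, prevalence tables, imputation and regression) can be
exercised end-to-end without any external data:

* covariate marginals of an elderly population-based echo cohort
  (age 76.4 +/- 6.2 truncated at 65, 59% women, BMI 27.2 +/- 4.0,
  smoking 35.3/55.5/9.2%, COPD 10.4%, diabetes 12.8%, systemic
  hypertension 87.1%, diastolic stages 61.5/35.0/3.5%), with a small
  Gaussian-copula layer inducing age-COPD, age-diastolic-stage and
  BMI-hypertension correlations;
* a true ePASP built as a linear predictor over those covariates (the
  default effect vector is the multivariable association structure the
  package's regression stage is meant to recover) plus a right-skewed
  zero-mean log-normal residual;
* an exact echo decomposition: RAP is drawn from {3, 8, 15} mmHg, TRV is
  back-derived as sqrt((ePASP - RAP)/4), and IVC / mitral / LV / RV
  measurements are emitted consistently with the drawn RAP category,
  diastolic stage and fractional shortening — so running the derivation
  stage on an unmasked cohort recovers true ePASP to machine precision;
* an observed-data missingness layer: a no-tricuspid-data excluded
  stratum, TRV unmeasurable with probability decreasing in true ePASP
  (logistic link), MCAR RAP/covariate masking, and prior-visit smoking /
  COPD columns for last-observation-carried-forward.

The generated table never contains ground-truth columns; those go to a
separate truth table joining 1:1 on participant id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import echo

log = logging.getLogger(__name__)

SMOKING_LEVELS = ("never", "former", "current")


@dataclass(frozen=True)
class EffectVector:
    """Linear-model truth for ePASP (mmHg), on conventional display scales.

    Coefficients are stored on the scales association tables print them
    (per 10 years, per 5 kg/m^2, per 10% shortening); the generator
    divides by the scale internally.  ``intercept``, ``resid_sd`` and
    ``log_skew`` were calibrated once, jointly, so that the default
    cohort reproduces mean estimable ePASP 26.3 mmHg (SD 7.0) and a 2.6%
    primary-definition prevalence, and are frozen here.
    """

    intercept: float = 5.4950
    age_per_10y: float = 2.2
    women: float = -0.6
    bmi_per_5: float = 0.7
    fs_per_10: float = -0.5
    stage2: float = 1.1
    stage3_4: float = 7.1
    copd: float = 2.4
    diabetes: float = 0.3
    hypertension: float = 1.3
    resid_sd: float = 6.5425       # SD of the zero-mean residual, mmHg
    log_skew: float = 0.1133       # log-scale sigma of the residual; 0 = Gaussian


@dataclass(frozen=True)
class Marginals:
    age_mean: float = 76.4
    age_sd: float = 6.2
    age_min: float = 65.0
    p_women: float = 0.59
    bmi_mean: float = 27.2
    bmi_sd: float = 4.0
    smoking: tuple[float, float, float] = (0.353, 0.555, 0.092)
    p_copd: float = 0.104
    p_diabetes: float = 0.128
    p_hypertension: float = 0.871
    stage_probs: tuple[float, float, float] = (0.615, 0.350, 0.035)
    fs_mean: float = 41.1
    fs_sd: float = 5.9
    lvedd_mean: float = 48.0
    lvedd_sd: float = 5.0
    rvedd_mean: float = 33.0
    rvedd_sd: float = 4.4
    p_af: float = 0.08
    rap_probs: tuple[float, float, float] = (0.85, 0.13, 0.02)  # 3 / 8 / 15 mmHg


@dataclass(frozen=True)
class Correlations:
    """Gaussian-copula correlations between selected covariates."""

    age_copd: float = 0.20
    age_stage: float = 0.30
    bmi_hypertension: float = 0.25


@dataclass(frozen=True)
class MissingnessConfig:
    """Observed-data pattern, expressed as fractions of the generated cohort.

    ``p_trv_unmeasurable`` is the target overall rate among participants
    with tricuspid data; the logistic intercept is solved on the realised
    ePASP distribution so the rate holds at any ``trv_steepness``
    (mmHg^-1, the strength with which low pressures make the jet
    unmeasurable; 0 gives MCAR masking).
    """

    p_no_tr_data: float = 0.1651          # excluded stratum
    p_trv_unmeasurable: float = 0.2373    # jet absent / too small
    trv_steepness: float = 0.05
    jet_absent_frac: float = 0.5
    p_rap_missing: float = 0.0966         # IVC not assessable
    p_excluded_ivc_present: float = 0.66  # within the excluded stratum
    p_excluded_rv_present: float = 0.68
    p_bmi_missing: float = 0.0043
    p_fs_missing: float = 0.0124          # masks both LV diameters
    p_diastolic_missing: float = 0.0117   # masks the mitral/tissue-Doppler set
    p_diabetes_missing: float = 0.0414
    p_hypertension_missing: float = 0.0177
    p_smoking_missing: float = 0.03       # recoverable via LOCF
    p_copd_missing: float = 0.03
    p_prior_missing: float = 0.10         # prior visit itself unavailable


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 3381
    seed: int = 0
    effects: EffectVector = field(default_factory=EffectVector)
    marginals: Marginals = field(default_factory=Marginals)
    correlations: Correlations = field(default_factory=Correlations)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def load_generator_config(path: str | Path | None = None, **overrides) -> GeneratorConfig:
    """Build a config from a YAML file (missing keys keep defaults)."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    for key, cls in [("effects", EffectVector), ("marginals", Marginals),
                     ("correlations", Correlations), ("missingness", MissingnessConfig)]:
        if key in raw:
            sub = raw[key]
            for f in ("smoking", "stage_probs", "rap_probs"):
                if f in sub:
                    sub[f] = tuple(sub[f])
            raw[key] = cls(**sub)
    raw.update(overrides)
    return GeneratorConfig(**raw)


def _validate(config: GeneratorConfig) -> None:
    m = config.marginals
    if config.n < 1:
        raise ValueError("cohort size must be >= 1")
    for name, probs in [("smoking", m.smoking), ("stage_probs", m.stage_probs),
                        ("rap_probs", m.rap_probs)]:
        if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
            raise ValueError(f"{name} must be a probability partition, got {probs}")
    for name, p in [("p_women", m.p_women), ("p_copd", m.p_copd),
                    ("p_diabetes", m.p_diabetes), ("p_hypertension", m.p_hypertension),
                    ("p_af", m.p_af)]:
        if not 0 <= p <= 1:
            raise ValueError(f"{name} outside [0, 1]")
    if config.effects.resid_sd <= 0:
        raise ValueError("residual SD must be positive")


def _truncnorm_parent(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose lower-truncated normal has the given moments.

    The configured age mean/SD describe the realised (truncated) marginal,
    so the underlying parent distribution is solved for numerically.
    """
    from scipy.optimize import root

    def eqs(x):
        mu, log_sig = x
        sig = np.exp(log_sig)
        a = (lower - mu) / sig
        mom_mean, mom_var = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sig,
                                                  moments="mv")
        return [mom_mean - mean, np.sqrt(mom_var) - sd]

    sol = root(eqs, x0=[mean, np.log(sd)], tol=1e-10)
    if not sol.success:
        raise RuntimeError(f"truncated-normal moment match failed: {sol.message}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _copula_draws(rng: np.random.Generator, n: int, c: Correlations) -> np.ndarray:
    """Latent uniforms for (age, bmi, copd, hypertension, stage)."""
    corr = np.eye(5)
    corr[0, 2] = corr[2, 0] = c.age_copd
    corr[0, 4] = corr[4, 0] = c.age_stage
    corr[1, 3] = corr[3, 1] = c.bmi_hypertension
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 5)) @ chol.T
    return stats.norm.cdf(z)


def _residual(rng: np.random.Generator, n: int, eff: EffectVector) -> np.ndarray:
    """Zero-mean residual with SD ``resid_sd``; log-normal when log_skew > 0."""
    if eff.log_skew <= 0:
        return rng.normal(0.0, eff.resid_sd, n)
    tau = eff.log_skew
    ln = np.exp(rng.normal(0.0, tau, n))
    mean_ln = np.exp(tau ** 2 / 2.0)
    sd_ln = np.sqrt((np.exp(tau ** 2) - 1.0) * np.exp(tau ** 2))
    return eff.resid_sd * (ln - mean_ln) / sd_ln


def linear_predictor(cov: pd.DataFrame, eff: EffectVector) -> np.ndarray:
    """True-model linear predictor (mmHg) from a covariate frame."""
    stage = cov["diastolic_stage_true"].to_numpy(object)
    return (
        eff.intercept
        + eff.age_per_10y / 10.0 * cov["age"].to_numpy(float)
        + eff.women * cov["female"].to_numpy(float)
        + eff.bmi_per_5 / 5.0 * cov["bmi"].to_numpy(float)
        + eff.fs_per_10 / 10.0 * cov["fs_true"].to_numpy(float)
        + eff.stage2 * (stage == echo.STAGE_2)
        + eff.stage3_4 * (stage == echo.STAGE_3_4)
        + eff.copd * cov["copd"].to_numpy(float)
        + eff.diabetes * cov["diabetes"].to_numpy(float)
        + eff.hypertension * cov["hypertension"].to_numpy(float)
    )


def generate(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a complete (unmasked) cohort and its truth table.

    Returns ``(cohort, truth)``; apply :func:`apply_missingness` to
    obtain the observed-data pattern.  Identical config (incl. seed)
    gives byte-identical output.
    """
    _validate(config)
    rng = np.random.default_rng(config.seed)
    n, m, eff = config.n, config.marginals, config.effects

    u = _copula_draws(rng, n, config.correlations)
    mu_age, sig_age = _truncnorm_parent(m.age_mean, m.age_sd, m.age_min)
    lower = (m.age_min - mu_age) / sig_age
    age = stats.truncnorm.ppf(u[:, 0], lower, np.inf, loc=mu_age, scale=sig_age)
    bmi = np.clip(m.bmi_mean + m.bmi_sd * stats.norm.ppf(u[:, 1]), 15.0, 55.0)
    copd = u[:, 2] > 1.0 - m.p_copd
    hypertension = u[:, 3] > 1.0 - m.p_hypertension
    stage_cut = np.cumsum(m.stage_probs)
    stage = np.select(
        [u[:, 4] < stage_cut[0], u[:, 4] < stage_cut[1]],
        [echo.STAGE_NORMAL, echo.STAGE_2], default=echo.STAGE_3_4,
    ).astype(object)

    female = rng.random(n) < m.p_women
    smoking = rng.choice(SMOKING_LEVELS, size=n, p=m.smoking).astype(object)
    diabetes = rng.random(n) < m.p_diabetes
    af = rng.random(n) < m.p_af
    fs = np.clip(rng.normal(m.fs_mean, m.fs_sd, n), 12.0, 65.0)
    lvedd = np.clip(rng.normal(m.lvedd_mean, m.lvedd_sd, n), 35.0, 65.0)
    lvesd = lvedd * (1.0 - fs / 100.0)
    rvedd = np.clip(rng.normal(m.rvedd_mean, m.rvedd_sd, n), 20.0, 55.0)

    cov = pd.DataFrame({
        "age": age, "female": female, "bmi": bmi, "copd": copd,
        "hypertension": hypertension, "diabetes": diabetes,
        "diastolic_stage_true": stage, "fs_true": fs,
    })
    lp = linear_predictor(cov, eff)
    rap = rng.choice([3.0, 8.0, 15.0], size=n, p=m.rap_probs)
    epasp = lp + _residual(rng, n, eff)
    floored = epasp < rap
    if floored.any():
        log.info("floored %d of %d ePASP values at RAP", int(floored.sum()), n)
    epasp = np.maximum(epasp, rap)
    trv = np.sqrt((epasp - rap) / 4.0)

    ivc_diameter, ivc_collapse = _ivc_from_rap(rng, rap)
    e_peak, a_peak, e_prime, dec_time = _mitral_from_stage(rng, stage, af)

    cohort = pd.DataFrame({
        "pid": np.arange(1, n + 1),
        "age": age, "female": female.astype(int), "bmi": bmi,
        "smoking": smoking, "smoking_prior": smoking.copy(),
        "copd": copd.astype(int), "copd_prior": copd.astype(int).astype(float),
        "diabetes": diabetes.astype(float), "hypertension": hypertension.astype(float),
        "af": af.astype(int),
        "trv": trv, "trv_missing_reason": np.full(n, None, dtype=object),
        "ivc_diameter": ivc_diameter, "ivc_collapse": ivc_collapse,
        "lvedd": lvedd, "lvesd": lvesd, "rvedd": rvedd,
        "e_peak": e_peak, "a_peak": a_peak, "e_prime": e_prime, "dec_time": dec_time,
    })
    truth = pd.DataFrame({
        "pid": cohort["pid"],
        "true_epasp": epasp, "true_rap": rap, "true_gradient": epasp - rap,
        "true_trv": trv, "linear_predictor": lp,
        "true_case": (epasp > 40.0).astype(int),
        "true_fs": fs, "true_diastolic_stage": stage,
        "floored_at_rap": floored.astype(int),
    })
    return cohort, truth


def _ivc_from_rap(rng, rap):
    """IVC diameter/collapse consistent with the drawn RAP category."""
    n = len(rap)
    d = np.empty(n)
    c = np.empty(n)
    low, mid, high = rap == 3.0, rap == 8.0, rap == 15.0
    d[low] = rng.uniform(12.0, 21.0, low.sum())
    c[low] = rng.uniform(0.55, 0.90, low.sum())
    d[high] = rng.uniform(21.5, 30.0, high.sum())
    c[high] = rng.uniform(0.05, 0.45, high.sum())
    # intermediate: small-but-noncollapsing or large-but-collapsing, 50/50
    k = int(mid.sum())
    big = rng.random(k) < 0.5
    dm = np.where(big, rng.uniform(21.5, 30.0, k), rng.uniform(12.0, 21.0, k))
    cm = np.where(big, rng.uniform(0.55, 0.90, k), rng.uniform(0.10, 0.50, k))
    d[mid], c[mid] = dm, cm
    return d, c


def _mitral_from_stage(rng, stage, af):
    """Mitral inflow / tissue-Doppler values consistent with the stage.

    Values are drawn inside the decision windows of the default staging
    thresholds for both the sinus-rhythm and the AF branch, so the
    derivation stage recovers the assigned stage exactly; AF rows carry
    no A wave.
    """
    n = len(stage)
    e_prime = np.empty(n)
    ee = np.empty(n)
    ea = np.empty(n)
    dt = np.empty(n)
    s0 = stage == echo.STAGE_NORMAL
    s2 = stage == echo.STAGE_2
    s3 = stage == echo.STAGE_3_4
    e_prime[s0] = rng.uniform(8.5, 14.0, s0.sum())
    ee[s0] = rng.uniform(5.0, 9.5, s0.sum())
    ea[s0] = rng.uniform(0.85, 1.40, s0.sum())
    dt[s0] = rng.uniform(230.0, 320.0, s0.sum())
    e_prime[s2] = rng.uniform(5.0, 7.5, s2.sum())
    ee[s2] = rng.uniform(10.5, 14.0, s2.sum())
    ea[s2] = rng.uniform(0.85, 1.40, s2.sum())
    dt[s2] = rng.uniform(150.0, 220.0, s2.sum())
    e_prime[s3] = rng.uniform(3.0, 6.0, s3.sum())
    ee[s3] = rng.uniform(14.0, 20.0, s3.sum())
    ea[s3] = rng.uniform(1.60, 2.40, s3.sum())
    dt[s3] = rng.uniform(90.0, 135.0, s3.sum())
    e_peak = ee * e_prime / 100.0
    a_peak = np.where(af, np.nan, e_peak / ea)
    return e_peak, a_peak, e_prime, dt


def apply_missingness(cohort: pd.DataFrame, truth: pd.DataFrame,
                      config: GeneratorConfig,
                      seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impose the observed-data pattern on a complete cohort.

    Returns a masked copy of the cohort plus the truth table augmented
    with the masking indicators (``stratum``, ``trv_masked``,
    ``rap_masked``).  Uses its own RNG stream (``seed`` defaults to
    ``config.seed + 1``) so generation and masking are independently
    reproducible.
    """
    mc = config.missingness
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = len(cohort)
    out = cohort.copy()
    truth = truth.copy()

    excluded = rng.random(n) < mc.p_no_tr_data
    epasp = truth["true_epasp"].to_numpy(float)

    # TRV unmeasurable, more likely at low pressure: pi = expit(a - b*ePASP),
    # with `a` solved so the mean over non-excluded rows hits the target rate.
    b = mc.trv_steepness
    rest = ~excluded
    if mc.p_trv_unmeasurable > 0 and rest.any():
        y = epasp[rest]
        target = mc.p_trv_unmeasurable
        if b == 0:
            pi_rest = np.full(rest.sum(), target)
        else:
            a = brentq(lambda a_: expit(a_ - b * y).mean() - target,
                       logit(min(target, 1 - 1e-9)) + b * y.min() - 50.0,
                       logit(max(target, 1e-9)) + b * y.max() + 50.0)
            pi_rest = expit(a - b * y)
        unmeasurable = np.zeros(n, dtype=bool)
        unmeasurable[rest] = rng.random(rest.sum()) < pi_rest
    else:
        unmeasurable = np.zeros(n, dtype=bool)

    reason = np.full(n, None, dtype=object)
    jet_absent = rng.random(n) < mc.jet_absent_frac
    reason[unmeasurable & jet_absent] = "jet_absent"
    reason[unmeasurable & ~jet_absent] = "jet_too_small"
    reason[excluded] = "not_recorded"
    trv_masked = unmeasurable | excluded
    out.loc[trv_masked, "trv"] = np.nan
    out["trv_missing_reason"] = reason

    rap_masked = rng.random(n) < mc.p_rap_missing
    keep_ivc_excl = rng.random(n) < mc.p_excluded_ivc_present
    rap_masked |= excluded & ~keep_ivc_excl
    out.loc[rap_masked, ["ivc_diameter", "ivc_collapse"]] = np.nan

    rv_masked = excluded & (rng.random(n) >= mc.p_excluded_rv_present)
    out.loc[rv_masked, "rvedd"] = np.nan

    out.loc[rng.random(n) < mc.p_bmi_missing, "bmi"] = np.nan
    out.loc[rng.random(n) < mc.p_fs_missing, ["lvedd", "lvesd"]] = np.nan
    out.loc[rng.random(n) < mc.p_diastolic_missing,
            ["e_peak", "a_peak", "e_prime", "dec_time"]] = np.nan
    out.loc[rng.random(n) < mc.p_diabetes_missing, "diabetes"] = np.nan
    out.loc[rng.random(n) < mc.p_hypertension_missing, "hypertension"] = np.nan

    out.loc[rng.random(n) < mc.p_smoking_missing, "smoking"] = None
    out["copd"] = out["copd"].astype(float)
    out.loc[rng.random(n) < mc.p_copd_missing, "copd"] = np.nan
    prior_gone = rng.random(n) < mc.p_prior_missing
    out.loc[prior_gone, "smoking_prior"] = None
    out.loc[prior_gone, "copd_prior"] = np.nan

    truth["stratum"] = np.where(excluded, "excluded", "analysis")
    truth["trv_masked"] = trv_masked.astype(int)
    truth["rap_masked"] = rap_masked.astype(int)
    return out, truth
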