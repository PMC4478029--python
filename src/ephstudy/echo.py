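"""Per-participant derivation of echocardiographic quantities.

Raw measurements (TRV, IVC, LV/RV diameters, mitral inflow and tissue
Doppler) are turned into the derived measures the analysis runs on:

* right atrial pressure (RAP), estimated categorically as 3 / 8 / 15 mmHg
  from IVC diameter and sniff-test collapse;
* the tricuspid pressure gradient 4*TRV**2 (simplified Bernoulli);
* ePASP = gradient + RAP;
* LV fractional shortening and the systolic-dysfunction flag (FS < 29%);
* the three-level LV diastolic-function stage, with a deceleration-time
  branch for atrial fibrillation;
* the dilated-right-ventricle flag (RVEDD > 42 mm).

Missingness is carried as NaN (numeric) / None (categorical) plus, for
TRV, an explicit reason code in ``trv_missing_reason``; no sentinel
numbers are ever used.  Scalar functions implement each rule; the
vectorised :func:`derive_measures` applies them to a cohort DataFrame.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import Thresholds

# Diastolic stage labels, ordered by severity.
STAGE_NORMAL = "normal_or_stage1"
STAGE_2 = "stage2"
STAGE_3_4 = "stage3_4"
STAGES = (STAGE_NORMAL, STAGE_2, STAGE_3_4)

# Reasons a TRV measurement can be absent.  The first two mean the jet was
# looked for but could not be quantified (assumed normal pressures
# downstream); the last means no tricuspid data were recorded at all.
TRV_REASONS = ("jet_absent", "jet_too_small", "not_recorded")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def estimate_rap(ivc_diameter: float, ivc_collapse: float,
                 thresholds: Thresholds | None = None) -> float:
    """Categorical right atrial pressure (mmHg) from the IVC.

    3 mmHg when the IVC is small (<= 21 mm) and collapses > 50% on sniff,
    15 mmHg when it is large (> 21 mm) and collapses < 50%, 8 mmHg in all
    intermediate cases (including exact boundary values).  Missing input
    yields NaN so the caller can fall back to the gradient-only criterion.
    """
    t = (thresholds or Thresholds()).rap
    if _missing(ivc_diameter) or _missing(ivc_collapse):
        return float("nan")
    if ivc_diameter <= t.ivc_diameter and ivc_collapse > t.ivc_collapse:
        return t.rap_low
    if ivc_diameter > t.ivc_diameter and ivc_collapse < t.ivc_collapse:
        return t.rap_high
    return t.rap_mid


def tricuspid_gradient(trv: float) -> float:
    """Tricuspid pressure gradient in mmHg: 4*TRV**2 (simplified Bernoulli)."""
    if _missing(trv):
        return float("nan")
    return 4.0 * trv ** 2


def compute_epasp(gradient: float, rap: float) -> float:
    """ePASP = tricuspid gradient + RAP; NaN when either term is missing."""
    if _missing(gradient) or _missing(rap):
        return float("nan")
    return gradient + rap


def fractional_shortening(lvedd: float, lvesd: float) -> float:
    """LV fractional shortening in percent: (LVEDD - LVESD) / LVEDD * 100.

    Raises ``ValueError`` on physically inconsistent diameters (LVESD
    exceeding LVEDD, or non-positive LVEDD) rather than silently
    propagating a nonsense value.
    """
    if _missing(lvedd) or _missing(lvesd):
        return float("nan")
    if lvedd <= 0:
        raise ValueError(f"LV end-diastolic diameter must be positive, got {lvedd}")
    if lvesd > lvedd:
        raise ValueError(
            f"LV end-systolic diameter {lvesd} exceeds end-diastolic {lvedd}"
        )
    return (lvedd - lvesd) / lvedd * 100.0


def classify_lv_systolic(fs: float, thresholds: Thresholds | None = None):
    """True iff fractional shortening is below 29% (strict); NaN propagates."""
    t = (thresholds or Thresholds()).case
    if _missing(fs):
        return None
    return bool(fs < t.fs_dysfunction)


def classify_rv_dilated(rvedd: float, thresholds: Thresholds | None = None):
    """True iff basal RV end-diastolic diameter exceeds 42 mm (strict)."""
    t = (thresholds or Thresholds()).case
    if _missing(rvedd):
        return None
    return bool(rvedd > t.rvedd_dilated)


def stage_diastolic(e_peak: float, a_peak: float, e_prime: float,
                    dec_time: float, af: bool,
                    thresholds: Thresholds | None = None):
    """Three-level LV diastolic-function stage.

    Sinus rhythm: the E/A ratio places the participant in the impaired-
    relaxation, pseudonormal or restrictive window, and a raised E/E'
    (>= 10) or a low annular E' (< 8 cm/s) is required to call the
    pseudonormal and restrictive grades; normal filling and isolated
    impaired relaxation both map to ``normal_or_stage1``.

    Atrial fibrillation: the A wave is unusable, so the E/A window is
    replaced by the deceleration time — < 140 ms grades restrictive,
    otherwise a raised-filling-pressure signal grades pseudonormal.  The
    AF branch never reads ``a_peak``.

    Returns ``None`` when the required inputs for the applicable branch
    are missing.
    """
    t = (thresholds or Thresholds()).diastolic
    if _missing(e_peak) or _missing(e_prime) or e_prime <= 0:
        return None
    ee = e_peak * 100.0 / e_prime  # E in m/s, E' in cm/s
    raised_pressure = ee >= t.e_over_eprime or e_prime < t.e_prime_low
    if af:
        if _missing(dec_time):
            return None
        if dec_time < t.dec_time_restrictive:
            return STAGE_3_4
        return STAGE_2 if raised_pressure else STAGE_NORMAL
    if _missing(a_peak) or a_peak <= 0:
        return None
    ea = e_peak / a_peak
    if ea >= t.ea_upper and raised_pressure:
        return STAGE_3_4
    if t.ea_lower < ea < t.ea_upper and raised_pressure:
        return STAGE_2
    return STAGE_NORMAL


def derive_measures(cohort: pd.DataFrame,
                    thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Vectorised derivation for a whole cohort.

    Expects the cohort column layout of :mod:`ephstudy.io` (``trv``,
    ``ivc_diameter``, ``ivc_collapse``, ``lvedd``, ``lvesd``, ``rvedd``,
    ``e_peak``, ``a_peak``, ``e_prime``, ``dec_time``, ``af``) and returns
    a DataFrame indexed like the input with columns ``rap``, ``gradient``,
    ``epasp``, ``fs``, ``lv_sys_dysfunction``, ``diastolic_stage`` and
    ``rv_dilated``.  Physically inconsistent LV diameters raise.
    """
    th = thresholds or Thresholds()
    n = len(cohort)
    out = pd.DataFrame(index=cohort.index)

    d = cohort["ivc_diameter"].to_numpy(float)
    c = cohort["ivc_collapse"].to_numpy(float)
    rap = np.full(n, th.rap.rap_mid)
    with np.errstate(invalid="ignore"):
        rap[(d <= th.rap.ivc_diameter) & (c > th.rap.ivc_collapse)] = th.rap.rap_low
        rap[(d > th.rap.ivc_diameter) & (c < th.rap.ivc_collapse)] = th.rap.rap_high
    rap[np.isnan(d) | np.isnan(c)] = np.nan
    out["rap"] = rap

    trv = cohort["trv"].to_numpy(float)
    gradient = 4.0 * trv ** 2
    out["gradient"] = gradient
    out["epasp"] = gradient + rap

    lvedd = cohort["lvedd"].to_numpy(float)
    lvesd = cohort["lvesd"].to_numpy(float)
    both = ~np.isnan(lvedd) & ~np.isnan(lvesd)
    bad = both & ((lvedd <= 0) | (lvesd > lvedd))
    if bad.any():
        rows = cohort.index[bad].tolist()[:5]
        raise ValueError(
            f"{int(bad.sum())} row(s) with inconsistent LV diameters "
            f"(LVESD > LVEDD or LVEDD <= 0), e.g. index {rows}"
        )
    with np.errstate(invalid="ignore"):
        fs = (lvedd - lvesd) / lvedd * 100.0
    out["fs"] = fs
    out["lv_sys_dysfunction"] = _nullable_bool(fs < th.case.fs_dysfunction, np.isnan(fs))

    rvedd = cohort["rvedd"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        out["rv_dilated"] = _nullable_bool(rvedd > th.case.rvedd_dilated, np.isnan(rvedd))

    out["diastolic_stage"] = _stage_vector(cohort, th)
    return out


def _nullable_bool(values: np.ndarray, missing: np.ndarray) -> pd.Series:
    s = pd.Series(values, dtype="boolean")
    s[missing] = pd.NA
    return s.values


def _stage_vector(cohort: pd.DataFrame, th: Thresholds) -> pd.Series:
    t = th.diastolic
    e = cohort["e_peak"].to_numpy(float)
    a = cohort["a_peak"].to_numpy(float)
    ep = cohort["e_prime"].to_numpy(float)
    dt = cohort["dec_time"].to_numpy(float)
    af = cohort["af"].to_numpy(bool)

    with np.errstate(invalid="ignore", divide="ignore"):
        ee = e * 100.0 / ep
        ea = e / a
    ep_ok = ~np.isnan(e) & ~np.isnan(ep) & (ep > 0)
    raised = ep_ok & ((ee >= t.e_over_eprime) | (ep < t.e_prime_low))

    stage = np.full(len(cohort), None, dtype=object)

    sinus = ~af & ep_ok & ~np.isnan(a) & (a > 0)
    stage[sinus] = STAGE_NORMAL
    stage[sinus & (ea > t.ea_lower) & (ea < t.ea_upper) & raised] = STAGE_2
    stage[sinus & (ea >= t.ea_upper) & raised] = STAGE_3_4

    af_ok = af & ep_ok & ~np.isnan(dt)
    stage[af_ok] = STAGE_NORMAL
    stage[af_ok & raised] = STAGE_2
    stage[af_ok & (dt < t.dec_time_restrictive)] = STAGE_3_4
    return pd.Series(stage, index=cohort.index)
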