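"""Case ascertainment for echocardiographic pulmonary hypertension (ePH).

Three definitions are applied to every participant:

* **primary** — ePASP > 40 mmHg; when RAP (and hence ePASP) could not be
  estimated, a tricuspid gradient > 36 mmHg (TRV > 3.0 m/s) is used
  instead; participants whose regurgitation jet was absent or too small
  to measure are counted as non-cases (they almost certainly have normal
  pulmonary pressures); participants with no tricuspid data at all are
  excluded.
* **rv_augmented** — a primary case *or* a dilated right ventricle
  (basal RVEDD > 42 mm).  Participants with RV data but no tricuspid
  data are classifiable here, so this denominator can exceed the
  primary one.
* **stringent** — the primary hierarchy at ePASP > 50 mmHg with a
  TRV > 3.4 m/s fallback, ignoring RV size.

Every participant maps to exactly one status per definition, and the
ascertainment path taken by the primary hierarchy is recorded.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import Thresholds

CASE, NONCASE, EXCLUDED = "case", "noncase", "excluded"

PATH_EPASP = "epasp_measured"
PATH_FALLBACK = "trv_fallback"
PATH_ASSUMED = "assumed_noncase"
PATH_NO_DATA = "no_tr_data"

_ASSUMED_REASONS = ("jet_absent", "jet_too_small")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def _hierarchy(epasp, gradient, trv_missing_reason,
               epasp_cut: float, gradient_cut: float):
    """The shared four-step ascertainment hierarchy; returns (status, path)."""
    if not _missing(epasp):
        return (CASE if epasp > epasp_cut else NONCASE), PATH_EPASP
    if not _missing(gradient):
        return (CASE if gradient > gradient_cut else NONCASE), PATH_FALLBACK
    if trv_missing_reason in _ASSUMED_REASONS:
        return NONCASE, PATH_ASSUMED
    return EXCLUDED, PATH_NO_DATA


def classify_primary(epasp, gradient, trv_missing_reason,
                     thresholds: Thresholds | None = None):
    """Primary ePH status and ascertainment path for one participant."""
    t = (thresholds or Thresholds()).case
    return _hierarchy(epasp, gradient, trv_missing_reason,
                      t.epasp_primary, t.gradient_primary)


def classify_stringent(epasp, gradient, trv_missing_reason,
                       thresholds: Thresholds | None = None) -> str:
    """Stringent-threshold status (50 mmHg / TRV > 3.4 m/s), RV size ignored."""
    t = (thresholds or Thresholds()).case
    status, _ = _hierarchy(epasp, gradient, trv_missing_reason,
                           t.epasp_stringent, t.gradient_stringent)
    return status


def classify_rv_augmented(primary_status: str, rv_dilated) -> str:
    """RV-augmented status: primary case OR dilated right ventricle.

    A participant excluded from the primary definition (no tricuspid
    data) is classifiable here whenever the RV diameter was measured.
    """
    if primary_status == CASE or rv_dilated is True:
        return CASE
    if primary_status == EXCLUDED:
        return NONCASE if rv_dilated is False else EXCLUDED
    return NONCASE


def classify_cohort(derived: pd.DataFrame, cohort: pd.DataFrame,
                    thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Apply all three definitions to a derived-measures table.

    ``derived`` must carry ``epasp``, ``gradient`` and ``rv_dilated``;
    ``cohort`` supplies ``trv_missing_reason``.  Returns a DataFrame with
    columns ``primary_def``, ``rv_augmented_def``, ``stringent_def`` and
    ``path`` aligned on the input index.
    """
    t = (thresholds or Thresholds()).case
    epasp = derived["epasp"].to_numpy(float)
    gradient = derived["gradient"].to_numpy(float)
    reason = cohort["trv_missing_reason"].astype(object).to_numpy()
    rvd = derived["rv_dilated"]

    def vector_hierarchy(epasp_cut, gradient_cut):
        status = np.full(len(derived), EXCLUDED, dtype=object)
        path = np.full(len(derived), PATH_NO_DATA, dtype=object)
        has_e = ~np.isnan(epasp)
        has_g = ~has_e & ~np.isnan(gradient)
        assumed = ~has_e & ~has_g & np.isin(reason, _ASSUMED_REASONS)
        status[has_e] = np.where(epasp[has_e] > epasp_cut, CASE, NONCASE)
        path[has_e] = PATH_EPASP
        status[has_g] = np.where(gradient[has_g] > gradient_cut, CASE, NONCASE)
        path[has_g] = PATH_FALLBACK
        status[assumed] = NONCASE
        path[assumed] = PATH_ASSUMED
        return status, path

    primary, path = vector_hierarchy(t.epasp_primary, t.gradient_primary)
    stringent, _ = vector_hierarchy(t.epasp_stringent, t.gradient_stringent)

    dilated = pd.array(np.asarray(rvd, dtype=object), dtype="boolean")
    has_rv = ~dilated.isna()
    is_dilated = dilated.fillna(False).to_numpy(dtype=bool)
    rv_aug = np.where(primary == EXCLUDED, EXCLUDED, NONCASE).astype(object)
    rv_aug[(primary == EXCLUDED) & has_rv] = NONCASE
    rv_aug[(primary == CASE) | is_dilated] = CASE

    return pd.DataFrame(
        {
            "primary_def": primary,
            "rv_augmented_def": rv_aug,
            "stringent_def": stringent,
            "path": path,
        },
        index=derived.index,
    )
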