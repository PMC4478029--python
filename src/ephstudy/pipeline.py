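"""End-to-end orchestration: simulate -> derive -> classify -> tables.

Runs the full analysis on a generated cohort and renders the four
result tables (participant characteristics, subgroup prevalences,
alternative case definitions, regression models) plus a reproducibility
manifest with stage counts and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import echo
from .cohort import GeneratorConfig, generate, apply_missingness
from .config import Thresholds
from .definitions import classify_cohort, EXCLUDED, CASE, PATH_EPASP, PATH_FALLBACK, PATH_ASSUMED
from .echo import derive_measures
from .impute import impute, locf
from .models import run_models, FACTORS
from .prevalence import (
    prevalence_from_status, subgroup_prevalences, compare_populations,
    age_bands, CONTINUOUS, BINARY, CATEGORICAL,
)

log = logging.getLogger(__name__)

TABLE1_COLUMNS = {
    "age": CONTINUOUS, "female": BINARY, "bmi": CONTINUOUS,
    "smoking": CATEGORICAL, "trv": CONTINUOUS, "rap": CONTINUOUS,
    "epasp": CONTINUOUS, "rvedd": CONTINUOUS, "fs": CONTINUOUS,
    "lv_sys_dysfunction": BINARY, "diastolic_stage": CATEGORICAL,
    "copd": BINARY, "diabetes": BINARY, "hypertension": BINARY,
}

SUBGROUPS = ["sex", "age_band", "smoking", "bmi_band", "copd",
             "hypertension", "diabetes", "lv_sys_dysfunction", "diastolic_stage"]


def build_analysis_table(cohort: pd.DataFrame, derived: pd.DataFrame,
                         status: pd.DataFrame) -> pd.DataFrame:
    """Analysis table (one row per non-excluded participant).

    Applies LOCF to smoking and COPD, merges the derived echo measures,
    and carries TRV / RAP / RVEDD along as never-imputed predictors.
    """
    df = pd.DataFrame({
        "pid": cohort["pid"],
        "epasp": derived["epasp"],
        "age": cohort["age"],
        "female": cohort["female"].astype(float),
        "bmi": cohort["bmi"],
        "smoking": locf(cohort["smoking"], cohort["smoking_prior"]),
        "fs": derived["fs"],
        "diastolic_stage": derived["diastolic_stage"],
        "copd": locf(cohort["copd"], cohort["copd_prior"]),
        "diabetes": cohort["diabetes"].astype(float),
        "hypertension": cohort["hypertension"].astype(float),
        "trv": cohort["trv"],
        "rap": derived["rap"],
        "rvedd": cohort["rvedd"],
    })
    keep = (status["primary_def"] != EXCLUDED).to_numpy()
    return df.loc[keep].set_index("pid")


def characteristics_frame(cohort: pd.DataFrame, derived: pd.DataFrame) -> pd.DataFrame:
    """Covariates + derived measures in Table-1 layout for one population."""
    return pd.DataFrame({
        "age": cohort["age"], "female": cohort["female"].astype(float),
        "bmi": cohort["bmi"], "smoking": cohort["smoking"],
        "trv": cohort["trv"], "rap": derived["rap"], "epasp": derived["epasp"],
        "rvedd": cohort["rvedd"], "fs": derived["fs"],
        "lv_sys_dysfunction": derived["lv_sys_dysfunction"].astype("boolean"),
        "diastolic_stage": derived["diastolic_stage"],
        "copd": cohort["copd"].astype(float), "diabetes": cohort["diabetes"].astype(float),
        "hypertension": cohort["hypertension"].astype(float),
    })


def grouping_frame(analysis: pd.DataFrame) -> pd.DataFrame:
    """Subgroup variables on the analysis table (Table-2 groupings)."""
    g = pd.DataFrame(index=analysis.index)
    g["sex"] = np.where(analysis["female"] > 0.5, "women", "men")
    g["age_band"] = age_bands(analysis["age"]).to_numpy()
    g["smoking"] = analysis["smoking"]
    g["bmi_band"] = np.where(analysis["bmi"].isna(), None,
                             np.where(analysis["bmi"] < 25.0, "<25", ">=25"))
    for flag in ("copd", "hypertension", "diabetes"):
        g[flag] = analysis[flag].map({1.0: "yes", 0.0: "no"})
    g["lv_sys_dysfunction"] = pd.Series(
        np.where(analysis["fs"].isna(), None,
                 np.where(analysis["fs"] < 29.0, "yes", "no")), index=analysis.index)
    g["diastolic_stage"] = analysis["diastolic_stage"]
    return g


def subgroup_table(status: pd.Series, groupings: pd.DataFrame,
                   subgroups: list[str] = SUBGROUPS) -> pd.DataFrame:
    """Stacked per-subgroup prevalence table (Table-2 analogue)."""
    overall = prevalence_from_status(status)
    rows = [pd.DataFrame([{"grouping": "overall", "level": "all",
                           "k": overall.k, "n": overall.n,
                           "prevalence_pct": overall.p,
                           "ci_low_pct": overall.ci_low,
                           "ci_high_pct": overall.ci_high,
                           "display": str(overall), "p_value": np.nan}])]
    for var in subgroups:
        tab = subgroup_prevalences(status.loc[groupings.index], groupings[var])
        tab.insert(0, "grouping", var)
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)


def definitions_table(status: pd.DataFrame, groupings: pd.DataFrame) -> pd.DataFrame:
    """Overall and by-sex prevalence under the three definitions (Table 3)."""
    rows = []
    for definition in ("primary_def", "rv_augmented_def", "stringent_def"):
        st = status[definition]
        overall = prevalence_from_status(st)
        rows.append({"definition": definition, "level": "overall",
                     "k": overall.k, "n": overall.n, "display": str(overall),
                     "p_value": np.nan})
        bysex = subgroup_prevalences(st.loc[groupings.index], groupings["sex"],
                                     levels=["women", "men"])
        for _, r in bysex.iterrows():
            rows.append({"definition": definition, "level": r["level"],
                         "k": r["k"], "n": r["n"], "display": r["display"],
                         "p_value": r["p_value"]})
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: GeneratorConfig, outdir: str | Path,
                 thresholds: Thresholds | None = None,
                 m_imputations: int = 5,
                 write_report: bool = True) -> dict:
    """Execute every stage and write tables + manifest under ``outdir``.

    Returns the manifest dictionary.  Stage counts satisfy
    generated = excluded + analysis and
    analysis = ePASP-estimable + TRV-fallback + assumed-noncase.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = thresholds or Thresholds()

    log.info("generating cohort n=%d seed=%d", config.n, config.seed)
    cohort, truth = generate(config)
    cohort, truth = apply_missingness(cohort, truth, config)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    truth.to_csv(outdir / "truth.csv", index=False)

    derived = derive_measures(cohort, th)
    derived_out = pd.concat([cohort[["pid"]], derived], axis=1)
    derived_out.to_csv(outdir / "derived.csv", index=False)

    status = classify_cohort(derived, cohort, th)
    status_out = pd.concat([cohort[["pid"]], status], axis=1)
    status_out.to_csv(outdir / "status.csv", index=False)

    excluded_mask = (status["primary_def"] == EXCLUDED).to_numpy()
    chars = characteristics_frame(cohort, derived)
    table1 = compare_populations(chars[~excluded_mask], chars[excluded_mask],
                                 TABLE1_COLUMNS)
    table1.to_csv(outdir / "table1.csv", index=False)

    analysis = build_analysis_table(cohort, derived, status)
    groupings = grouping_frame(analysis)
    status_idx = status.set_index(cohort["pid"])
    table2 = subgroup_table(status_idx["primary_def"].loc[analysis.index], groupings)
    table2.to_csv(outdir / "table2.csv", index=False)

    groupings_all = grouping_frame(
        build_analysis_table(cohort, derived,
                             status.assign(primary_def="noncase")))
    table3 = definitions_table(status_idx, groupings_all)
    table3.to_csv(outdir / "table3.csv", index=False)

    log.info("imputing m=%d and fitting models on %d analysis rows",
             m_imputations, len(analysis))
    imputed = impute(analysis, m=m_imputations, seed=config.seed + 2)
    fits_a, fit_b = run_models(imputed)
    table4 = pd.concat([f.to_frame() for f in fits_a.values()]
                       + [fit_b.to_frame()], ignore_index=True)
    table4.to_csv(outdir / "table4.csv", index=False)

    n = len(cohort)
    counts = {
        "generated": n,
        "excluded_no_tr_data": int(excluded_mask.sum()),
        "analysis_set": int(n - excluded_mask.sum()),
        "epasp_estimable": int((status["path"] == PATH_EPASP).sum()),
        "trv_fallback": int((status["path"] == PATH_FALLBACK).sum()),
        "assumed_noncase": int((status["path"] == PATH_ASSUMED).sum()),
        "primary_cases": int((status["primary_def"] == CASE).sum()),
    }
    assert counts["generated"] == counts["excluded_no_tr_data"] + counts["analysis_set"]
    assert counts["analysis_set"] == (counts["epasp_estimable"]
                                      + counts["trv_fallback"]
                                      + counts["assumed_noncase"])

    files = ["cohort.csv", "truth.csv", "derived.csv", "status.csv",
             "table1.csv", "table2.csv", "table3.csv", "table4.csv"]
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "thresholds": th.to_dict(),
        "m_imputations": m_imputations,
        "counts": counts,
        "model_b_selected": fit_b.selected,
        "checksums": {f: _sha256(outdir / f) for f in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if write_report:
        _write_report(outdir, counts, derived)
    return manifest


def _write_report(outdir: Path, counts: dict, derived: pd.DataFrame) -> None:
    """Small HTML report: stage accounting, the four tables, ePASP histogram."""
    parts = ["<html><head><title>ePH pipeline report</title></head><body>",
             "<h1>Echocardiographic PH pipeline</h1>",
             "<h2>Stage accounting</h2><ul>"]
    parts += [f"<li>{k}: {v}</li>" for k, v in counts.items()]
    parts.append("</ul>")
    try:  # histogram of estimable ePASP (optional, needs matplotlib)
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.hist(derived["epasp"].dropna(), bins=40, color="#4878a8")
        ax.set_xlabel("ePASP (mmHg)")
        ax.set_ylabel("participants")
        fig.tight_layout()
        fig.savefig(outdir / "epasp_hist.png", dpi=100)
        plt.close(fig)
        parts.append('<h2>ePASP distribution</h2><img src="epasp_hist.png"/>')
    except Exception:  # pragma: no cover
        log.warning("matplotlib unavailable; skipping histogram")
    for i in range(1, 5):
        parts.append(f"<h2>Table {i}</h2>")
        parts.append(pd.read_csv(outdir / f"table{i}.csv").to_html(index=False))
    parts.append("</body></html>")
    (outdir / "report.html").write_text("\n".join(parts))
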