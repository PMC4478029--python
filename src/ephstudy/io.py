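"""Cohort CSV reading/writing with a shipped column dictionary.

Each cohort column is declared with its unit, allowed range and missing
convention; the reader refuses files with unknown or missing required
columns and flags out-of-range values instead of silently coercing them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ColumnSpec:
    unit: str
    kind: str                       # numeric | flag | category
    lo: float = -np.inf
    hi: float = np.inf
    levels: tuple = ()
    required: bool = True
    description: str = ""


COLUMN_DICTIONARY: dict[str, ColumnSpec] = {
    "pid": ColumnSpec("", "numeric", 0, np.inf, description="participant id"),
    "age": ColumnSpec("years", "numeric", 45, 110),
    "female": ColumnSpec("", "flag"),
    "bmi": ColumnSpec("kg/m^2", "numeric", 10, 70),
    "smoking": ColumnSpec("", "category", levels=("never", "former", "current")),
    "smoking_prior": ColumnSpec("", "category",
                                levels=("never", "former", "current"), required=False),
    "copd": ColumnSpec("", "flag"),
    "copd_prior": ColumnSpec("", "flag", required=False),
    "diabetes": ColumnSpec("", "flag"),
    "hypertension": ColumnSpec("", "flag"),
    "af": ColumnSpec("", "flag", description="atrial fibrillation"),
    "trv": ColumnSpec("m/s", "numeric", 0, 8,
                      description="tricuspid regurgitation peak velocity"),
    "trv_missing_reason": ColumnSpec(
        "", "category", levels=("jet_absent", "jet_too_small", "not_recorded")),
    "ivc_diameter": ColumnSpec("mm", "numeric", 1, 60),
    "ivc_collapse": ColumnSpec("fraction", "numeric", 0, 1),
    "lvedd": ColumnSpec("mm", "numeric", 1, 100),
    "lvesd": ColumnSpec("mm", "numeric", 0, 100),
    "rvedd": ColumnSpec("mm", "numeric", 1, 100),
    "e_peak": ColumnSpec("m/s", "numeric", 0, 4),
    "a_peak": ColumnSpec("m/s", "numeric", 0, 4),
    "e_prime": ColumnSpec("cm/s", "numeric", 0, 40),
    "dec_time": ColumnSpec("ms", "numeric", 20, 1000),
}


def read_cohort(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read a cohort CSV and validate it against the column dictionary.

    Raises ``ValueError`` on missing required columns, unknown columns
    (when ``strict``), non-dictionary category codes, or numeric values
    outside their allowed range.
    """
    df = pd.read_csv(path)
    missing = [c for c, s in COLUMN_DICTIONARY.items() if s.required and c not in df]
    if missing:
        raise ValueError(f"cohort file lacks required columns: {missing}")
    unknown = [c for c in df.columns if c not in COLUMN_DICTIONARY]
    if unknown and strict:
        raise ValueError(f"unknown columns (units cannot be verified): {unknown}")
    for col, spec in COLUMN_DICTIONARY.items():
        if col not in df:
            continue
        if spec.kind == "category":
            vals = df[col].dropna()
            bad = set(vals.unique()) - set(spec.levels)
            if bad:
                raise ValueError(f"column {col!r} has undeclared codes: {sorted(map(str, bad))}")
        else:
            df[col] = pd.to_numeric(df[col], errors="raise")
            vals = df[col].dropna()
            out = vals[(vals < spec.lo) | (vals > spec.hi)]
            if len(out):
                raise ValueError(
                    f"column {col!r} ({spec.unit}) has {len(out)} value(s) outside "
                    f"[{spec.lo}, {spec.hi}], e.g. {out.iloc[0]}"
                )
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
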