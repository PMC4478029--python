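"""Prevalence estimation with Wald intervals, subgroup tables and
included-vs-excluded population comparisons.

Point estimates are binomial proportions; 95% intervals are plain Wald
intervals (normal approximation, no continuity correction), truncated to
[0, 100] in percent.  Printed values use half-up rounding to one decimal
so published-style triples like ``2.6% (2.0; 3.2)`` are reproducible
bit-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .definitions import CASE, EXCLUDED
from .utils import round_half_up, fmt_pct


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Binomial prevalence with a Wald 95% interval, in percent."""

    k: int
    n: int
    p: float        # percent, unrounded
    ci_low: float   # percent, unrounded, truncated at 0
    ci_high: float  # percent, unrounded, truncated at 100

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        """(p, low, high) after half-up rounding — the printable triple."""
        return (round_half_up(self.p, ndigits),
                round_half_up(self.ci_low, ndigits),
                round_half_up(self.ci_high, ndigits))

    def __str__(self) -> str:
        p, lo, hi = self.rounded()
        return f"{p:.1f}% ({lo:.1f}; {hi:.1f})"


def wald_ci(k: int, n: int, level: float = 0.95) -> PrevalenceEstimate:
    """Wald interval for a binomial proportion, reported in percent.

    p_hat = k/n with bounds p_hat +/- z*sqrt(p_hat(1-p_hat)/n); bounds are
    truncated to [0, 1] before conversion to percent.
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"case count {k} outside [0, {n}]")
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = k / n
    half = z * np.sqrt(p * (1.0 - p) / n)
    return PrevalenceEstimate(
        k=int(k), n=int(n), p=100.0 * p,
        ci_low=100.0 * max(0.0, p - half),
        ci_high=100.0 * min(1.0, p + half),
    )


def prevalence_from_status(status: pd.Series, level: float = 0.95) -> PrevalenceEstimate:
    """Overall prevalence from a case/noncase/excluded status column.

    Excluded participants drop out of the denominator; everyone else —
    including assumed non-cases — stays in.
    """
    in_denominator = status != EXCLUDED
    return wald_ci(int((status == CASE).sum()), int(in_denominator.sum()), level)


def subgroup_prevalences(status: pd.Series, groups: pd.Series,
                         levels: list | None = None,
                         level: float = 0.95) -> pd.DataFrame:
    """Per-level prevalence plus one omnibus p-value across levels.

    ``groups`` is a categorical covariate aligned with ``status``; rows
    excluded from the definition or with a missing group value drop out.
    The p-value is a Pearson chi-square test on the cases-by-level
    contingency table (the package's default between-group test).
    Empty levels are omitted with a warning.
    """
    keep = (status != EXCLUDED) & groups.notna()
    st, gr = status[keep], groups[keep]
    if levels is None:
        levels = list(pd.unique(gr))
    rows, counts = [], []
    for lv in levels:
        mask = gr == lv
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"subgroup level {lv!r} is empty; omitted")
            continue
        k = int((st[mask] == CASE).sum())
        est = wald_ci(k, n, level)
        rows.append({"level": lv, "k": k, "n": n, "prevalence_pct": est.p,
                     "ci_low_pct": est.ci_low, "ci_high_pct": est.ci_high,
                     "display": str(est)})
        counts.append([k, n - k])
    table = pd.DataFrame(rows)
    table["p_value"] = _chi2_p(np.array(counts)) if len(counts) >= 2 else np.nan
    return table


def _chi2_p(counts: np.ndarray) -> float:
    """Pearson chi-square p for a levels x {case, noncase} table."""
    counts = counts[counts.sum(axis=1) > 0]
    if counts.shape[0] < 2 or counts.sum(axis=0).min() == 0:
        return float("nan")
    return float(stats.chi2_contingency(counts, correction=False)[1])


# Column kinds understood by compare_populations.
CONTINUOUS, BINARY, CATEGORICAL = "continuous", "binary", "categorical"


def compare_populations(included: pd.DataFrame, excluded: pd.DataFrame,
                        columns: dict[str, str]) -> pd.DataFrame:
    """Characteristics table for two populations with per-row p-values.

    ``columns`` maps column name -> kind (``continuous`` | ``binary`` |
    ``categorical``).  Continuous rows report mean (SD) per group and a
    Welch two-sample t p-value; binary and categorical rows report
    percentages and a single omnibus Pearson chi-square p-value.
    All-missing columns are omitted with a warning.
    """
    rows = []
    for col, kind in columns.items():
        a, b = included[col].dropna(), excluded[col].dropna()
        if len(a) == 0 or len(b) == 0:
            warnings.warn(f"column {col!r} all-missing in one group; omitted")
            continue
        if kind == CONTINUOUS:
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
            summary_a = f"{a.mean():.1f} ({a.std(ddof=1):.1f})"
            summary_b = f"{b.mean():.1f} ({b.std(ddof=1):.1f})"
        else:
            if kind == BINARY:
                a, b = a.astype(bool), b.astype(bool)
                tab = np.array([[a.sum(), (~a).sum()], [b.sum(), (~b).sum()]])
                summary_a = f"{fmt_pct(100 * a.mean())}%"
                summary_b = f"{fmt_pct(100 * b.mean())}%"
            else:
                lv = sorted(set(a) | set(b), key=str)
                tab = np.array([[ (g == v).sum() for v in lv] for g in (a, b)])
                summary_a = "/".join(f"{fmt_pct(100 * (a == v).mean())}" for v in lv)
                summary_b = "/".join(f"{fmt_pct(100 * (b == v).mean())}" for v in lv)
            p = _chi2_p(tab.T) if kind == CATEGORICAL else _chi2_p(tab)
        rows.append({"characteristic": col, "kind": kind,
                     "n_included": len(a), "included": summary_a,
                     "n_excluded": len(b), "excluded": summary_b,
                     "p_value": float(p)})
    return pd.DataFrame(rows)


def age_bands(age: pd.Series) -> pd.Series:
    """Five-year age bands from 65 ('65-70', ..., '85+'), as ordered strings."""
    edges = [65, 70, 75, 80, 85, np.inf]
    labels = ["65-70", "70-75", "75-80", "80-85", "85+"]
    return pd.cut(age, bins=edges, labels=labels, right=False).astype(object)
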