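"""Rubin pooling, Model A/B fits and their degenerate cases."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import ephstudy as e
from ephstudy.impute import ImputedSet, impute
from ephstudy.models import (
    FACTORS, fit_model_a, fit_model_b, rubin_pool, run_models, select_factors,
)
from ephstudy.pipeline import build_analysis_table


def _complete_table(n=2500, seed=11):
    cfg = e.GeneratorConfig(n=n, seed=seed)
    cohort, _ = e.generate(cfg)
    derived = e.derive_measures(cohort)
    status = e.classify_cohort(derived, cohort)
    return build_analysis_table(cohort, derived, status)


class TestRubinPool:
    def test_identical_fits_pool_to_single_fit(self):
        est = np.array([[1.5, -0.2]] * 4)
        cov = np.array([np.diag([0.04, 0.01])] * 4)
        qbar, T, df = rubin_pool(est, cov)
        np.testing.assert_allclose(qbar, [1.5, -0.2])
        np.testing.assert_allclose(np.diag(T), [0.04, 0.01])
        assert np.isinf(df).all()

    def test_two_fit_arithmetic(self):
        # estimates {1, 3}, zero within-variance: pooled 2, T = 1.5 * 2 = 3
        qbar, T, _ = rubin_pool(np.array([[1.0], [3.0]]),
                                np.zeros((2, 1, 1)))
        assert qbar[0] == 2.0
        assert T[0, 0] == pytest.approx(3.0)

    def test_total_variance_dominates_within(self):
        rng = np.random.default_rng(0)
        est = rng.normal(0, 1, (5, 3))
        cov = np.array([np.diag(rng.uniform(0.1, 1, 3)) for _ in range(5)])
        _, T, _ = rubin_pool(est, cov)
        assert (np.diag(T) >= np.diag(cov.mean(axis=0)) - 1e-12).all()

    def test_structure_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rubin_pool(np.array([[1.0]]), np.zeros((1, 1, 1)))
        with pytest.raises(ValueError):
            rubin_pool(np.array([[1.0], [2.0]]), np.zeros((3, 1, 1)))


class TestDegenerateMi:
    def test_zero_missingness_equals_single_ols(self):
        """With nothing to impute the pooled Model B equals one ordinary
        least-squares fit to machine precision (point estimates and SEs)."""
        table = _complete_table()
        imputed = impute(table, m=5, seed=0)
        fits_a, fit_b = run_models(imputed)

        sub = table[table["epasp"].notna()]
        cols = []
        names = []
        for fname in fit_b.selected:
            f = FACTORS[fname]
            block = f.columns(sub)
            for j, term in enumerate(f.terms()):
                cols.append(block[:, j])
                names.append((term, f.scale))
        X = sm.add_constant(np.column_stack(cols))
        res = sm.OLS(sub["epasp"].to_numpy(), X).fit()
        for j, (term, scale) in enumerate(names, start=1):
            t = fit_b.term(term)
            assert t.estimate == pytest.approx(res.params[j] * scale, rel=1e-10)
            assert t.se == pytest.approx(res.bse[j] * scale, rel=1e-10)


class TestModelA:
    def test_sex_fit_adjusts_for_age_only(self):
        table = _complete_table(1500, seed=2)
        imputed = impute(table, m=2, seed=0)
        fit = fit_model_a(imputed, "female")
        assert [t.term for t in fit.terms] == ["female", "age"]
        fit_age = fit_model_a(imputed, "age")
        assert [t.term for t in fit_age.terms] == ["age", "female"]

    def test_display_scale_contract(self):
        # noise-free linear outcome: per-10-years display = 10x raw slope
        n = 400
        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "age": rng.uniform(65, 95, n),
            "female": rng.integers(0, 2, n).astype(float),
        })
        df["epasp"] = 20.0 + 0.22 * df["age"] - 0.6 * df["female"]
        imputed = ImputedSet([df.copy(), df.copy()], seed=0)
        fit = fit_model_a(imputed, "age")
        assert fit.term("age").estimate == pytest.approx(2.2, abs=1e-9)

    def test_constant_factor_rejected(self):
        table = _complete_table(800, seed=3)
        table["copd"] = 0.0
        imputed = impute(table, m=2, seed=0)
        with pytest.raises(ValueError, match="constant"):
            fit_model_a(imputed, "copd")

    def test_null_covariate_ci_coverage(self):
        """A covariate unrelated to the outcome has a Model-A CI covering
        zero in at least ~95% of replicates."""
        rng = np.random.default_rng(12)
        n, covered = 500, 0
        reps = 300
        for _ in range(reps):
            df = pd.DataFrame({
                "age": rng.uniform(65, 95, n),
                "female": rng.integers(0, 2, n).astype(float),
                "noise": rng.normal(0, 1, n),
            })
            df["epasp"] = 25 + 0.2 * df["age"] + rng.normal(0, 6, n)
            imputed = ImputedSet([df, df], seed=0)
            fit = fit_model_a(imputed, "noise",
                              factors={**FACTORS,
                                       "noise": FACTORS["age"].__class__(
                                           "noise", "continuous")})
            t = fit.term("noise")
            covered += t.ci_low <= 0 <= t.ci_high
        assert covered / reps >= 0.93


class TestSelectionAndModelB:
    def test_null_factor_excluded_strong_factor_kept(self):
        table = _complete_table(4000, seed=13)
        rng = np.random.default_rng(0)
        table["smoking"] = rng.choice(["never", "former", "current"], len(table))
        imputed = impute(table, m=2, seed=0)
        fits_a = {name: fit_model_a(imputed, name) for name in ("age", "smoking")}
        selected = select_factors(fits_a)
        assert "age" in selected and "smoking" not in selected

    def test_model_b_contains_exactly_selected_factors(self):
        table = _complete_table(3000, seed=14)
        imputed = impute(table, m=2, seed=0)
        fits_a, fit_b = run_models(imputed)
        assert set(fit_b.selected) == set(select_factors(fits_a))
        factors_in_fit = {t.factor for t in fit_b.terms}
        assert factors_in_fit == set(fit_b.selected)

    def test_empty_selection_raises(self):
        table = _complete_table(600, seed=15)
        imputed = impute(table, m=2, seed=0)
        fits_a = {name: fit_model_a(imputed, name) for name in ("smoking",)}
        rigged = {k: v for k, v in fits_a.items()}
        rigged["smoking"].factor_p["smoking"] = 0.9
        with pytest.raises(ValueError, match="selection"):
            fit_model_b(imputed, rigged)
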