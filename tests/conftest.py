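import numpy as np
import pandas as pd
import pytest

import ephstudy as e


@pytest.fixture(scope="session")
def small_cohort():
    """Masked default-config cohort of 4,000 with derived measures and status."""
    cfg = e.GeneratorConfig(n=4000, seed=123)
    cohort, truth = e.generate(cfg)
    cohort, truth = e.apply_missingness(cohort, truth, cfg)
    derived = e.derive_measures(cohort)
    status = e.classify_cohort(derived, cohort)
    return cfg, cohort, truth, derived, status


@pytest.fixture(scope="session")
def complete_cohort():
    """Unmasked (fully observed) default-config cohort of 3,000."""
    cfg = e.GeneratorConfig(n=3000, seed=321)
    cohort, truth = e.generate(cfg)
    derived = e.derive_measures(cohort)
    status = e.classify_cohort(derived, cohort)
    return cfg, cohort, truth, derived, status


def random_derived_frame(rng: np.random.Generator, n: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random (derived, cohort) pair spanning all ascertainment paths."""
    epasp = rng.uniform(5, 80, n)
    gradient = np.clip(epasp - rng.choice([3.0, 8.0, 15.0], n), 0, None)
    kind = rng.integers(0, 4, n)  # 0: full, 1: fallback, 2: assumed, 3: excluded
    epasp[kind >= 1] = np.nan
    gradient[kind >= 2] = np.nan
    reason = np.full(n, None, dtype=object)
    reason[kind == 2] = rng.choice(["jet_absent", "jet_too_small"], (kind == 2).sum())
    reason[kind == 3] = "not_recorded"
    rv = rng.uniform(25, 50, n)
    rv[rng.random(n) < 0.2] = np.nan
    derived = pd.DataFrame({
        "epasp": epasp, "gradient": gradient,
        "rv_dilated": pd.array(np.where(np.isnan(rv), None, rv > 42.0), dtype="boolean"),
    })
    cohort = pd.DataFrame({"trv_missing_reason": reason})
    return derived, cohort
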