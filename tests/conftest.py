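import numpy as np
import pandas as pd
import pytest

import growthsurv as gs


@pytest.fixture(scope="session")
def small_cohort():
    """Bivariate cohort with deaths, dropout, and practice effects."""
    df, truth = gs.simulate_cohort(gs.default_scenario(n_subjects=120, seed=42))
    return df, truth


@pytest.fixture(scope="session")
def univariate_cohort():
    df, truth = gs.simulate_cohort(
        gs.informative_mortality_scenario(n_subjects=400, seed=7)
    )
    return df, truth


@pytest.fixture(scope="session")
def bivariate_spec():
    return gs.GrowthModelSpec(
        outcomes=("memory", "brain_bpf"),
        intercept_covariates={
            "memory": ("dart_z", "age_c", "sex_c", "stroke_c"),
            "brain_bpf": ("age_c", "sex_c", "stroke_c"),
        },
        slope_covariates={"memory": ("dart_z",)},
        include_survival=False,
    )


@pytest.fixture(scope="session")
def raw_memory_table():
    """Three baseline subjects plus one wave-2 subject scoring exactly the
    baseline means on all three tests."""
    return pd.DataFrame(
        {
            "subject_id": [1, 2, 3, 1],
            "visit_order": [0, 0, 0, 1],
            "wlt_total_recall": [30.0, 37.0, 44.0, 37.0],
            "wlt_delayed_recall": [5.0, 7.0, 9.0, 7.0],
            "rey_delayed_recall": [13.0, 20.0, 27.0, 20.0],
        }
    )


def truth_without_survival(truth, covariates=None):
    """Ground-truth parameters restricted to a non-survival spec."""
    gamma = truth.gamma
    if covariates is not None:
        gamma = {
            k: {c: v for c, v in d.items() if c in covariates}
            for k, d in gamma.items()
        }
    return gs.GrowthParameters(
        alpha=truth.alpha,
        gamma=gamma,
        psi=truth.psi,
        theta=truth.theta,
        theta_cross=truth.theta_cross,
        mu_practice=truth.mu_practice,
        psi_practice=truth.psi_practice,
        survival=None,
    )
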