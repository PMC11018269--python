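"""Synthetic long-format cohorts with ground-truth parameters.

The generator draws, per subject: baseline covariates (correlated
reading-test score and education propensity, sex-specific intracranial
volume, age, stroke history), bivariate random intercepts and slopes for
the memory composite and brain parenchymal fraction, individually-varying
observation times around the planned schedule, a practice effect on
memory with square-root-of-previous-visits loadings, within-occasion
correlated residuals, a discrete-time death process whose logit hazard is
regressed on the subject's latent memory intercept and slope, and
absorbing missing-at-random dropout.

Within each risk interval death is resolved before dropout, so a subject
censored after their last visit is known to have survived the interval
that follows it -- exactly the convention the likelihood uses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .cohort import COL_DIED, COL_MEMORY, COL_SUBJECT, COL_TIME, COL_VISIT
from .model import GrowthParameters, SurvivalBlock
from .scenario import (
    AGE_REF_MEAN,
    DART_REF_MEAN,
    DART_REF_SD,
    FEMALE_REF_PROP,
    STROKE_REF_PROP,
    CovariateConfig,
    SimulationScenario,
)

MODEL_SCALE_COLUMNS = ("dart_z", "age_c", "sex_c", "stroke_c", "icv_z")


def _psd_sqrt(cov: np.ndarray) -> np.ndarray:
    """Matrix square root of a PSD matrix; tolerates singular inputs."""
    vals, vecs = np.linalg.eigh(np.asarray(cov, dtype=float))
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def simulate_reserve_covariates(
    n: int,
    seed: int | None = None,
    config: CovariateConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw a baseline covariate table for ``n`` subjects.

    DART and a continuous education propensity come from a bivariate
    Gaussian with the configured correlation (default .50); the propensity
    is discretized into seven ordered education levels; DART is clipped to
    its admissible range; ICV is drawn per sex with distinct means.
    The latent ``education_propensity`` is retained so that the
    DART-education association can be checked on the continuous scale.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    config = config or CovariateConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(seed)

    rho = config.dart_edu_corr
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    dart = np.clip(config.dart_mean + config.dart_sd * z[:, 0], *config.dart_range)
    edu_prop = z[:, 1]
    cuts = norm.ppf(np.cumsum(config.education_level_probs)[:-1])
    education_level = 1 + np.searchsorted(cuts, edu_prop, side="right")

    sex = (rng.random(n) < config.female_prop).astype(int)  # 1 = female
    icv = np.where(
        sex == 1,
        config.icv_female[0] + config.icv_female[1] * rng.standard_normal(n),
        config.icv_male[0] + config.icv_male[1] * rng.standard_normal(n),
    )
    age = np.clip(
        config.age_mean + config.age_sd * rng.standard_normal(n), *config.age_range
    )
    stroke = (rng.random(n) < config.stroke_prop).astype(int)

    return pd.DataFrame(
        {
            COL_SUBJECT: np.arange(n),
            "baseline_age": age,
            "sex": sex,
            "stroke_history": stroke,
            "dart": dart,
            "education_propensity": edu_prop,
            "education_level": education_level,
            "icv": icv,
        }
    )


def _model_scale_columns(cov: pd.DataFrame, config: CovariateConfig) -> pd.DataFrame:
    """Attach the standardized/centered covariate columns the generative
    effects are defined on.  Reference constants (not sample moments) are
    used so that the generating coefficients are exact population truths."""
    out = cov.copy()
    out["dart_z"] = (cov["dart"] - DART_REF_MEAN) / DART_REF_SD
    out["age_c"] = cov["baseline_age"] - AGE_REF_MEAN
    out["sex_c"] = cov["sex"] - FEMALE_REF_PROP
    out["stroke_c"] = cov["stroke_history"] - STROKE_REF_PROP
    male = cov["sex"] == 0
    icv_z = np.empty(len(cov))
    icv_z[male] = (cov.loc[male, "icv"] - config.icv_male[0]) / config.icv_male[1]
    icv_z[~male] = (cov.loc[~male, "icv"] - config.icv_female[0]) / config.icv_female[1]
    out["icv_z"] = icv_z
    return out


def ground_truth_parameters(scenario: SimulationScenario) -> GrowthParameters:
    """Echo a scenario as the :class:`GrowthParameters` it generates from."""
    outcomes = scenario.outcomes
    alpha = {o: tuple(scenario.factor_means[o]) for o in outcomes}
    gamma = {}
    for o in outcomes:
        for role in ("intercept", "slope"):
            gamma[(o, role)] = dict(scenario.covariate_effects.get((o, role), {}))
    theta = {o: float(scenario.residual_sd[o]) ** 2 for o in outcomes}
    return GrowthParameters(
        alpha=alpha,
        gamma=gamma,
        psi=np.asarray(scenario.factor_cov, dtype=float).copy(),
        theta=theta,
        theta_cross=scenario.residual_cross_cov if len(outcomes) == 2 else 0.0,
        mu_practice=scenario.practice_mean,
        psi_practice=0.0,
        survival=SurvivalBlock(
            tau=tuple(scenario.hazard_thresholds),
            gamma0=scenario.hazard_loadings[0],
            gamma1=scenario.hazard_loadings[1],
        ),
    )


def simulate_cohort(
    scenario: SimulationScenario,
) -> tuple[pd.DataFrame, GrowthParameters]:
    """Generate one long-format cohort plus its ground-truth parameters.

    Outcomes follow ``y_oij = eta0_oi + eta1_oi * t_ij + lambda_j * mu_p +
    eps_oij`` with latent factors drawn around covariate-shifted means from
    the scenario's 2K x 2K covariance.  Death indicators are drawn from the
    discrete-time logit hazard given each subject's latent *memory* factors
    (covariate contributions included).  Bit-identical output for a fixed
    ``scenario.seed``.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_subjects
    outcomes = scenario.outcomes
    K = len(outcomes)
    n_visits = len(scenario.visit_schedule)
    n_int = scenario.n_intervals

    cov = simulate_reserve_covariates(max(n, 2), config=scenario.covariates, rng=rng)
    cov = cov.iloc[:n].reset_index(drop=True)
    cov = _model_scale_columns(cov, scenario.covariates)

    # latent factor values: means + covariate effects + correlated deviations
    F = 2 * K
    mean = np.zeros((n, F))
    for i, o in enumerate(outcomes):
        mean[:, 2 * i] = scenario.factor_means[o][0]
        mean[:, 2 * i + 1] = scenario.factor_means[o][1]
        for j, role in enumerate(("intercept", "slope")):
            for c, coef in scenario.covariate_effects.get((o, role), {}).items():
                mean[:, 2 * i + j] += coef * cov[c].to_numpy()
    dev = rng.standard_normal((n, F)) @ _psd_sqrt(scenario.factor_cov).T
    eta = mean + dev

    # individually-varying observation times (baseline pinned at 0)
    times = np.zeros((n, n_visits))
    for k in range(1, n_visits):
        jitter = scenario.visit_jitter_sd * rng.standard_normal(n)
        proposed = scenario.visit_schedule[k] + jitter
        times[:, k] = np.maximum(times[:, k - 1] + 0.25, proposed)

    # outcomes at every planned visit (observation filtering comes later)
    resid_cov = np.diag([scenario.residual_sd[o] ** 2 for o in outcomes])
    if K == 2:
        resid_cov[0, 1] = resid_cov[1, 0] = scenario.residual_cross_cov
    resid_sqrt = _psd_sqrt(resid_cov)
    y = np.zeros((n, n_visits, K))
    for k in range(n_visits):
        eps = rng.standard_normal((n, K)) @ resid_sqrt.T
        for i, o in enumerate(outcomes):
            load = np.sqrt(k) if o == COL_MEMORY else 0.0
            y[:, k, i] = (
                eta[:, 2 * i]
                + eta[:, 2 * i + 1] * times[:, k]
                + load * scenario.practice_mean
                + eps[:, i]
            )

    # discrete-time death process on the memory factors, then absorbing
    # MAR dropout; death is resolved first within each interval
    mem_idx = outcomes.index(COL_MEMORY) if COL_MEMORY in outcomes else 0
    eta_h = eta[:, 2 * mem_idx : 2 * mem_idx + 2]
    g0, g1 = scenario.hazard_loadings
    last_visit = np.full(n, n_visits - 1, dtype=int)
    died_next = np.zeros(n, dtype=bool)
    alive = np.ones(n, dtype=bool)
    followed = np.ones(n, dtype=bool)
    for k in range(1, n_visits):
        linpred = scenario.hazard_thresholds[k - 1] + g0 * eta_h[:, 0] + g1 * eta_h[:, 1]
        dies = alive & followed & (rng.random(n) < expit(linpred))
        died_next[dies] = True
        last_visit[dies] = k - 1
        alive &= ~dies
        drops = alive & followed & (rng.random(n) < scenario.mar_dropout_prob)
        last_visit[drops & (last_visit == n_visits - 1)] = k - 1
        followed &= ~drops

    # assemble long rows for observed visits
    rows = []
    cov_cols = [c for c in cov.columns if c != COL_SUBJECT]
    for k in range(n_visits):
        keep = last_visit >= k
        if not keep.any():
            continue
        block = pd.DataFrame(
            {
                COL_SUBJECT: cov.loc[keep, COL_SUBJECT].to_numpy(),
                COL_VISIT: k,
                COL_TIME: times[keep, k],
                COL_DIED: died_next[keep] & (last_visit[keep] == k),
            }
        )
        for i, o in enumerate(outcomes):
            block[o] = y[keep, k, i]
        for c in cov_cols:
            block[c] = cov.loc[keep, c].to_numpy()
        rows.append(block)
    df = (
        pd.concat(rows, ignore_index=True)
        .sort_values([COL_SUBJECT, COL_VISIT])
        .reset_index(drop=True)
    )
    return df, ground_truth_parameters(scenario)
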