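"""Maximum-likelihood fitting: closed-form oracles, determinism,
cross-checks against an independent mixed-model implementation, and
multiple-group estimation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import growthsurv as gs
from growthsurv.model import GrowthModelSpec


def _no_noise_free_scenario(n, seed):
    """Balanced complete data: no jitter, no dropout, no deaths, no practice."""
    return dataclasses.replace(
        gs.informative_mortality_scenario(n_subjects=n, seed=seed),
        visit_jitter_sd=0.0,
        mar_dropout_prob=0.0,
        hazard_thresholds=(-30.0, -30.0),
        hazard_loadings=(0.0, 0.0),
        practice_mean=0.0,
    )


class TestFit:
    def test_gls_closed_form_on_balanced_complete_data(self):
        """With zero random effects the ML means equal pooled OLS of the
        outcome on time; on a balanced complete design this holds for the
        fitted model even though it estimates a random-effect covariance."""
        sc = dataclasses.replace(
            _no_noise_free_scenario(400, 3), factor_cov=np.zeros((2, 2))
        )
        df, _ = gs.simulate_cohort(sc)
        spec = GrowthModelSpec(outcomes=("memory",), practice_on=())
        f = gs.fit(df, spec, compute_vcov=False)
        X = np.column_stack([np.ones(len(df)), df["time_in_study"]])
        beta, *_ = np.linalg.lstsq(X, df["memory"], rcond=None)
        assert f.estimate("alpha.memory.intercept") == pytest.approx(beta[0], abs=1e-6)
        assert f.estimate("alpha.memory.slope") == pytest.approx(beta[1], abs=1e-6)

    def test_refit_is_deterministic(self, univariate_cohort):
        df, _ = univariate_cohort
        spec = GrowthModelSpec(outcomes=("memory",), include_survival=True)
        f1 = gs.fit(df, spec)
        f2 = gs.fit(df, spec)
        np.testing.assert_array_equal(f1.estimates, f2.estimates)
        np.testing.assert_array_equal(f1.vcov, f2.vcov)

    def test_converged_fit_has_small_gradient(self, univariate_cohort):
        df, _ = univariate_cohort
        spec = GrowthModelSpec(outcomes=("memory",))
        f = gs.fit(df, spec)
        assert f.converged
        assert f.gradient_norm < 1e-5

    def test_matches_independent_mixed_model_implementation(self):
        """Random-intercept/slope model with no practice factor: our marginal
        ML fit against statsmodels MixedLM (independent implementation)."""
        statsmodels = pytest.importorskip("statsmodels.api")
        sc = dataclasses.replace(
            gs.informative_mortality_scenario(n_subjects=300, seed=17),
            practice_mean=0.0,
            hazard_loadings=(0.0, 0.0),
            hazard_thresholds=(-30.0, -30.0),
        )
        df, _ = gs.simulate_cohort(sc)
        spec = GrowthModelSpec(outcomes=("memory",), practice_on=())
        f = gs.fit(df, spec, compute_vcov=False)

        exog = np.column_stack([np.ones(len(df)), df["time_in_study"]])
        model = statsmodels.MixedLM(
            df["memory"].to_numpy(), exog, groups=df["subject_id"].to_numpy(),
            exog_re=exog,
        )
        res = model.fit(reml=False, method="lbfgs")
        assert f.loglik == pytest.approx(res.llf, abs=1e-3)
        assert f.estimate("alpha.memory.intercept") == pytest.approx(
            res.fe_params[0], abs=2e-4
        )
        assert f.estimate("alpha.memory.slope") == pytest.approx(
            res.fe_params[1], abs=2e-4
        )
        # random-effect covariance (MixedLM scales cov_re by the residual)
        np.testing.assert_allclose(
            f.params.psi, np.asarray(res.cov_re), atol=5e-3
        )

    def test_unidentifiable_design_rejected(self):
        df = pd.DataFrame(
            {
                "subject_id": [1, 2, 3],
                "visit_order": [0, 0, 0],
                "time_in_study": [0.0, 0.0, 0.0],
                "memory": [0.1, -0.5, 0.7],
                "died_in_next_interval": [False] * 3,
            }
        )
        spec = GrowthModelSpec(outcomes=("memory",), practice_on=())
        with pytest.raises(ValueError, match="identifiable"):
            gs.fit(df, spec)

    def test_vcov_is_symmetric_psd_when_converged(self, univariate_cohort):
        df, _ = univariate_cohort
        spec = GrowthModelSpec(outcomes=("memory",))
        f = gs.fit(df, spec)
        assert f.converged
        np.testing.assert_allclose(f.vcov, f.vcov.T, atol=1e-12)
        assert np.linalg.eigvalsh(f.vcov).min() > -1e-10


class TestOccasionResiduals:
    def test_occasion_specific_variances_recover_homoscedastic_truth(self):
        """Freeing per-occasion residual variances on data generated with a
        common residual variance recovers roughly equal occasion variances
        and does not move the slope mean."""
        sc = _no_noise_free_scenario(800, 11)
        df, _ = gs.simulate_cohort(sc)
        spec_h = GrowthModelSpec(outcomes=("memory",), practice_on=())
        spec_o = GrowthModelSpec(
            outcomes=("memory",), practice_on=(), occasion_residuals=True
        )
        fh = gs.fit(df, spec_h, compute_vcov=False)
        fo = gs.fit(df, spec_o, compute_vcov=False)
        truth_var = 0.54**2
        thetas = [fo.estimate(f"theta.memory.v{j}") for j in range(3)]
        assert all(abs(t - truth_var) < 0.06 for t in thetas)
        assert fo.estimate("alpha.memory.slope") == pytest.approx(
            fh.estimate("alpha.memory.slope"), abs=2e-3
        )
        assert fo.loglik >= fh.loglik - 1e-6  # nested models

    def test_occasion_gradient_matches_finite_differences(self):
        from growthsurv.design import build_design
        from growthsurv.likelihood import marginal_ll_grad
        from growthsurv.model import ParameterLayout

        df, _ = gs.simulate_cohort(gs.default_scenario(n_subjects=80, seed=13))
        spec = GrowthModelSpec(outcomes=("memory",), occasion_residuals=True)
        design = build_design(df, spec)
        layout = ParameterLayout(spec)
        u = gs.fit(df, spec, compute_vcov=False).uvec + 0.05
        _, g = marginal_ll_grad(design, layout, u)
        for k in range(len(u)):
            h = 1e-6 * max(1.0, abs(u[k]))
            up, um = u.copy(), u.copy()
            up[k] += h
            um[k] -= h
            fd = (
                marginal_ll_grad(design, layout, up)[0]
                - marginal_ll_grad(design, layout, um)[0]
            ) / (2 * h)
            assert g[k] == pytest.approx(fd, rel=2e-5, abs=1e-7), layout.names[k]

    def test_bivariate_occasion_residuals_rejected(self):
        with pytest.raises(ValueError, match="single-outcome"):
            GrowthModelSpec(outcomes=("memory", "brain_bpf"), occasion_residuals=True)


class TestWaldLikelihoodRatioAgreement:
    def test_rank_one_wald_close_to_lr(self):
        """For a rank-1 constraint (reserve effect on the slope = 0) at
        n = 2,000, the Wald statistic and the likelihood-ratio statistic for
        the same constraint agree within 10%."""
        spec_full = GrowthModelSpec(
            outcomes=("memory",),
            intercept_covariates={"memory": ("dart_z",)},
            slope_covariates={"memory": ("dart_z",)},
        )
        spec_null = GrowthModelSpec(
            outcomes=("memory",),
            intercept_covariates={"memory": ("dart_z",)},
        )
        agree = 0
        for seed in (201, 202, 203):
            df, _ = gs.simulate_cohort(gs.default_scenario(n_subjects=2000, seed=seed))
            f_full = gs.fit(df, spec_full)
            f_null = gs.fit(df, spec_null, compute_vcov=False)
            lr = 2 * (f_full.loglik - f_null.loglik)
            est = f_full.estimate("beta.memory.slope.dart_z")
            se = f_full.se("beta.memory.slope.dart_z")
            wald = (est / se) ** 2
            agree += abs(wald - lr) < 0.10 * max(wald, lr)
        assert agree >= 2


@pytest.fixture(scope="module")
def grouped_cohort():
    df1, _ = gs.simulate_cohort(gs.default_scenario(n_subjects=150, seed=31))
    df2, _ = gs.simulate_cohort(gs.default_scenario(n_subjects=150, seed=32))
    df2 = df2.assign(subject_id=df2["subject_id"] + 10_000)
    df1["grp"], df2["grp"] = "a", "b"
    return pd.concat([df1, df2], ignore_index=True)


class TestMultipleGroup:
    def test_single_group_identical_to_fit(self, grouped_cohort):
        df = grouped_cohort[grouped_cohort["grp"] == "a"]
        spec = GrowthModelSpec(outcomes=("memory",))
        fits = gs.multiple_group_fit(df, spec, grouping="grp")
        single = gs.fit(df, spec)
        assert len(fits) == 1
        np.testing.assert_allclose(fits[0].estimates, single.estimates, rtol=1e-10)

    def test_label_permutation_equivariance(self, grouped_cohort):
        spec = GrowthModelSpec(outcomes=("memory",))
        fits = gs.multiple_group_fit(grouped_cohort, spec, grouping="grp",
                                     compute_vcov=False)
        relabeled = grouped_cohort.assign(
            grp=grouped_cohort["grp"].map({"a": "b", "b": "a"})
        )
        fits2 = gs.multiple_group_fit(relabeled, spec, grouping="grp",
                                      compute_vcov=False)
        by_label = {f.group_label: f for f in fits}
        by_label2 = {f.group_label: f for f in fits2}
        np.testing.assert_allclose(
            by_label["a"].estimates, by_label2["b"].estimates, rtol=1e-10
        )

    def test_small_group_rejected(self, grouped_cohort):
        spec = GrowthModelSpec(outcomes=("memory",))
        with pytest.raises(ValueError, match="fewer than"):
            gs.multiple_group_fit(grouped_cohort, spec, grouping="grp",
                                  min_group_size=500)
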