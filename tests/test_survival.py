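"""Discrete-time survival submodel and the joint likelihood."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import growthsurv as gs
from growthsurv.design import build_design, build_subject_designs
from growthsurv.likelihood import natural_arrays
from growthsurv.model import GrowthModelSpec, ParameterLayout, SurvivalBlock
from growthsurv.practice import practice_loading
from growthsurv.survival import (
    QuadratureRule,
    compute_centers,
    discrete_hazard,
    joint_core,
    joint_ll_grad,
    joint_loglik,
    survival_loglik,
    survival_loglik_given_eta,
)

from conftest import truth_without_survival


def _joint_spec():
    return GrowthModelSpec(
        outcomes=("memory", "brain_bpf"),
        intercept_covariates={"memory": ("dart_z",), "brain_bpf": ("age_c",)},
        slope_covariates={"memory": ("dart_z",)},
        include_survival=True,
    )


class TestHazard:
    def test_link_identity(self):
        block = SurvivalBlock(tau=(0.0, 0.0))
        assert discrete_hazard(np.zeros(2), 1, block) == pytest.approx(0.5)

    def test_monotone_limit(self):
        block = SurvivalBlock(tau=(-40.0, 0.0))
        assert discrete_hazard(np.zeros(2), 1, block) < 1e-15

    def test_steeper_decline_higher_hazard(self):
        """Negative slope loading: hazard increases monotonically as the
        latent slope becomes more negative, over a grid of slopes."""
        block = SurvivalBlock(tau=(-1.0, -1.0), gamma0=0.0, gamma1=-5.0)
        slopes = np.linspace(-0.3, 0.3, 41)
        eta = np.column_stack([np.zeros_like(slopes), slopes])
        h = discrete_hazard(eta, 1, block)
        assert np.all(np.diff(h) < 0)

    def test_probit_link(self):
        from scipy.stats import norm

        block = SurvivalBlock(tau=(-0.5, 0.2), gamma0=0.3, gamma1=-2.0, link="probit")
        eta = np.array([0.4, -0.1])
        lp = -0.5 + 0.3 * 0.4 + (-2.0) * (-0.1)
        assert discrete_hazard(eta, 1, block) == pytest.approx(norm.cdf(lp), abs=1e-12)
        ll = survival_loglik_given_eta((1, True), eta, block)
        lp2 = 0.2 + 0.3 * 0.4 + (-2.0) * (-0.1)
        assert ll == pytest.approx(
            np.log(norm.sf(lp)) + np.log(norm.cdf(lp2)), abs=1e-10
        )

    def test_invalid_interval_rejected(self):
        block = SurvivalBlock(tau=(0.0, 0.0))
        with pytest.raises(ValueError):
            discrete_hazard(np.zeros(2), 3, block)

    def test_probability_conservation(self):
        """Death-in-1, death-in-2, survive-both probabilities sum to one for
        any latent value."""
        block = SurvivalBlock(tau=(-0.8, 0.3), gamma0=0.5, gamma1=-4.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            eta = rng.normal(size=2)
            h1 = discrete_hazard(eta, 1, block)
            h2 = discrete_hazard(eta, 2, block)
            total = h1 + (1 - h1) * h2 + (1 - h1) * (1 - h2)
            assert total == pytest.approx(1.0, abs=1e-15)


class TestSurvivalLoglik:
    def test_survivor_closed_form(self):
        from scipy.special import logit

        block = SurvivalBlock(tau=(float(logit(0.1)), float(logit(0.2))))
        ll = survival_loglik_given_eta((2, False), np.zeros(2), block)
        assert ll == pytest.approx(np.log(0.9) + np.log(0.8), abs=1e-12)

    def test_death_first_interval(self):
        from scipy.special import logit

        block = SurvivalBlock(tau=(float(logit(0.3)), 0.0))
        ll = survival_loglik_given_eta((0, True), np.zeros(2), block)
        assert ll == pytest.approx(np.log(0.3), abs=1e-12)

    def test_inconsistent_record_rejected(self):
        block = SurvivalBlock(tau=(0.0, 0.0))
        with pytest.raises(ValueError, match="inconsistent"):
            survival_loglik_given_eta((2, True), np.zeros(2), block)

    def test_mle_of_threshold_equals_empirical_death_fraction(self):
        """With zero loadings, the survival likelihood is a product of
        binomials, so its threshold MLE is the empirical interval death
        fraction."""
        import dataclasses as dc

        from scipy.optimize import minimize_scalar

        sc = dc.replace(
            gs.informative_mortality_scenario(n_subjects=3000, seed=8),
            hazard_loadings=(0.0, 0.0),
            hazard_thresholds=(-1.2, -0.7),
        )
        df, _ = gs.simulate_cohort(sc)
        spec = GrowthModelSpec(outcomes=("memory",), include_survival=True)
        subs = build_subject_designs(df, spec)
        deaths1 = sum(s.died and s.n_survived == 0 for s in subs)
        atrisk1 = sum(s.n_survived >= 1 or (s.died and s.n_survived == 0) for s in subs)

        def nll(tau1):
            block = SurvivalBlock(tau=(tau1, 0.0))
            return -sum(
                survival_loglik_given_eta(
                    (min(s.n_survived, 1), s.died and s.n_survived == 0),
                    np.zeros(2),
                    block,
                )
                for s in subs
            )

        res = minimize_scalar(nll, bounds=(-4, 1), method="bounded")
        assert expit(res.x) == pytest.approx(deaths1 / atrisk1, abs=1e-5)


class TestJointLoglik:
    def test_separability_zero_loadings(self, small_cohort):
        """gamma = 0: joint likelihood = longitudinal + survival pieces."""
        df, truth = small_cohort
        spec = _joint_spec()
        params = dataclasses.replace(
            truth_without_survival(truth, spec.all_covariates),
            survival=SurvivalBlock(tau=truth.survival.tau, gamma0=0.0, gamma1=0.0),
        )
        jl = joint_loglik(df, spec, params)
        ml = gs.marginal_loglik(df, dataclasses.replace(spec, include_survival=False), params)
        sl = survival_loglik(df, spec, params)
        assert jl == pytest.approx(ml + sl, abs=1e-8)

    def test_quadrature_convergence_ladder(self, small_cohort):
        df, truth = small_cohort
        spec = _joint_spec()
        params = dataclasses.replace(
            truth_without_survival(truth, spec.all_covariates), survival=truth.survival
        )
        vals = [
            joint_loglik(df, spec, params, rule=QuadratureRule(n_points=n))
            for n in (7, 15, 31)
        ]
        assert abs(vals[1] - vals[0]) < 1e-6 * max(1.0, abs(vals[0]))
        assert abs(vals[2] - vals[1]) < 1e-8 * max(1.0, abs(vals[1]))

    def test_recentered_grid_matches_adaptive(self, small_cohort):
        df, truth = small_cohort
        spec = _joint_spec()
        params = dataclasses.replace(
            truth_without_survival(truth, spec.all_covariates), survival=truth.survival
        )
        design = build_design(df, spec)
        arr = natural_arrays(spec, design.covariates, params)
        centers = compute_centers(design, arr)
        ll_c, _ = joint_core(design, arr, QuadratureRule(n_points=9, adaptive=False), centers=centers)
        ll_a = joint_loglik(design, spec, params)
        assert ll_c == pytest.approx(ll_a, abs=1e-6)

    def test_monte_carlo_oracle_three_subjects(self, small_cohort):
        """Gauss-Hermite joint likelihood against brute-force Monte-Carlo
        integration over the latent factors, subject by subject."""
        df, truth = small_cohort
        spec = _joint_spec()
        params = dataclasses.replace(
            truth_without_survival(truth, spec.all_covariates), survival=truth.survival
        )
        ids = df["subject_id"].unique()[:3]
        arr = natural_arrays(spec, spec.all_covariates, params)
        rng = np.random.default_rng(5)
        N = 300_000
        L = np.linalg.cholesky(arr.psi + 1e-12 * np.eye(4))
        for sid in ids:
            one = df[df["subject_id"] == sid]
            s = build_subject_designs(one, spec)[0]
            entries = [
                (vi, oi)
                for vi in range(s.mask.shape[0])
                for oi in range(s.mask.shape[1])
                if s.mask[vi, oi]
            ]
            p = len(entries)
            Lam = np.zeros((p, 4))
            lam = np.zeros(p)
            R = np.zeros((p, p))
            for j, (vi, oi) in enumerate(entries):
                Lam[j, 2 * oi] = 1.0
                Lam[j, 2 * oi + 1] = s.times[vi]
                if spec.outcomes[oi] in spec.practice_on:
                    lam[j] = practice_loading(int(s.visit_orders[vi]))
                R[j, j] = arr.theta[oi, int(s.visit_orders[vi])]
            for j1, (v1, o1) in enumerate(entries):
                for j2, (v2, o2) in enumerate(entries):
                    if j1 != j2 and v1 == v2 and o1 != o2:
                        R[j1, j2] = arr.tcross
            b = arr.alpha + arr.G.T @ s.x
            eta = b[None, :] + rng.standard_normal((N, 4)) @ L.T
            m = eta @ Lam.T + lam * arr.mu_p
            resid = s.y[None, :] - m
            Rinv = np.linalg.inv(R)
            _, logdetR = np.linalg.slogdet(R)
            logf = -0.5 * (
                p * np.log(2 * np.pi) + logdetR
                + np.einsum("np,pq,nq->n", resid, Rinv, resid)
            )
            ls = survival_loglik_given_eta(
                (s.n_survived, s.died), eta[:, [0, 1]], params.survival
            )
            vals = np.exp(logf + ls)
            Lhat, se = vals.mean(), vals.std(ddof=1) / np.sqrt(N)
            llq = joint_loglik(one, spec, params)
            assert abs(np.exp(llq) - Lhat) < 3 * se

    def test_joint_gradient_matches_finite_differences(self, small_cohort):
        df, truth = small_cohort
        spec = _joint_spec()
        design = build_design(df, spec)
        layout = ParameterLayout(spec)
        params = dataclasses.replace(
            truth_without_survival(truth, spec.all_covariates), survival=truth.survival
        )
        uvec = layout.pack(params)
        rule = QuadratureRule(n_points=9, adaptive=False)
        arr = natural_arrays(spec, design.covariates, params)
        centers = compute_centers(design, arr)
        for ctr in (None, centers):
            _, g = joint_ll_grad(design, layout, uvec, rule, centers=ctr)
            for k in range(len(uvec)):
                h = 1e-6 * max(1.0, abs(uvec[k]))
                up, um = uvec.copy(), uvec.copy()
                up[k] += h
                um[k] -= h
                fd = (
                    joint_ll_grad(design, layout, up, rule, centers=ctr)[0]
                    - joint_ll_grad(design, layout, um, rule, centers=ctr)[0]
                ) / (2 * h)
                assert g[k] == pytest.approx(fd, rel=3e-5, abs=1e-7), layout.names[k]

    def test_spec_without_survival_rejected(self, small_cohort):
        df, truth = small_cohort
        spec = dataclasses.replace(_joint_spec(), include_survival=False)
        with pytest.raises(ValueError, match="survival"):
            joint_loglik(df, spec, truth_without_survival(truth, spec.all_covariates))


class TestQuadratureRule:
    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            QuadratureRule(n_points=2)

    def test_weights_normalized_nodes_symmetric(self):
        z, logw = QuadratureRule(n_points=15).nodes()
        assert np.exp(logw).sum() == pytest.approx(1.0, abs=1e-12)
        assert abs(z.sum()) < 1e-10
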