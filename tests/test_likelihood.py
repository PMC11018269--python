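"""Marginal growth curve likelihood: practice loadings, implied moments,
FIML, factorization, and oracle agreement."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal, norm

import growthsurv as gs
from growthsurv.design import build_design, build_subject_designs
from growthsurv.likelihood import (
    arrays_from_uvec,
    marginal_ll_grad,
    marginal_loglik,
    natural_arrays,
)
from growthsurv.model import GrowthModelSpec, GrowthParameters, ParameterLayout
from growthsurv.practice import practice_loading

from conftest import truth_without_survival


class TestPracticeLoading:
    @pytest.mark.parametrize(
        "order,mode,expected",
        [
            (0, "exact", 0.0),
            (1, "exact", 1.0),
            (2, "exact", np.sqrt(2.0)),
            (1, "one-decimal", 1.0),
            (2, "one-decimal", 1.4),
            (3, "one-decimal", 1.7),
        ],
    )
    def test_values(self, order, mode, expected):
        assert practice_loading(order, mode) == pytest.approx(expected, abs=1e-12)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            practice_loading(-1)

    @given(st.integers(min_value=0, max_value=50))
    def test_square_root_property(self, order):
        val = practice_loading(order)
        assert val * val == pytest.approx(order, rel=1e-12)


def _manual_moments(subject, spec, params):
    """Independent explicit-matrix construction of the implied moments."""
    arr = natural_arrays(spec, spec.all_covariates, params)
    entries = [
        (vi, oi)
        for vi in range(subject.mask.shape[0])
        for oi in range(subject.mask.shape[1])
        if subject.mask[vi, oi]
    ]
    p = len(entries)
    F = spec.n_factors
    Lam = np.zeros((p, F))
    lam = np.zeros(p)
    R = np.zeros((p, p))
    for j, (vi, oi) in enumerate(entries):
        Lam[j, 2 * oi] = 1.0
        Lam[j, 2 * oi + 1] = subject.times[vi]
        if spec.outcomes[oi] in spec.practice_on:
            lam[j] = practice_loading(int(subject.visit_orders[vi]), spec.practice_rounding)
        R[j, j] = arr.theta[oi, int(subject.visit_orders[vi])]
    for j1, (v1, o1) in enumerate(entries):
        for j2, (v2, o2) in enumerate(entries):
            if j1 != j2 and v1 == v2 and o1 != o2:
                R[j1, j2] = arr.tcross
    b = arr.alpha + arr.G.T @ subject.x
    mu = Lam @ b + lam * arr.mu_p
    Sigma = Lam @ arr.psi @ Lam.T + arr.psi_p * np.outer(lam, lam) + R
    return mu, Sigma


class TestImpliedMoments:
    def test_identity_when_no_random_effects(self):
        spec = GrowthModelSpec(outcomes=("memory",), practice_on=())
        df = pd.DataFrame(
            {
                "subject_id": [1, 1, 1],
                "visit_order": [0, 1, 2],
                "time_in_study": [0.0, 4.0, 12.0],
                "memory": [0.1, -0.2, 0.3],
                "died_in_next_interval": [False] * 3,
            }
        )
        params = GrowthParameters(
            alpha={"memory": (0.0, 0.0)}, gamma={}, psi=np.zeros((2, 2)),
            theta={"memory": 1.0},
        )
        subject = build_subject_designs(df, spec)[0]
        _, Sigma = gs.implied_moments(subject, spec, params)
        np.testing.assert_allclose(Sigma, np.eye(3), atol=1e-14)

    def test_single_baseline_visit_variance(self):
        spec = GrowthModelSpec(outcomes=("memory",), practice_on=())
        df = pd.DataFrame(
            {
                "subject_id": [1],
                "visit_order": [0],
                "time_in_study": [0.0],
                "memory": [0.5],
                "died_in_next_interval": [False],
            }
        )
        psi = np.array([[0.6, 0.01], [0.01, 0.002]])
        params = GrowthParameters(
            alpha={"memory": (0.0, 0.0)}, gamma={}, psi=psi, theta={"memory": 0.3},
        )
        subject = build_subject_designs(df, spec)[0]
        _, Sigma = gs.implied_moments(subject, spec, params)
        assert Sigma[0, 0] == pytest.approx(0.9, abs=1e-14)

    def test_matches_explicit_matrix_construction(self, small_cohort, bivariate_spec):
        df, truth = small_cohort
        params = truth_without_survival(truth)
        subjects = build_subject_designs(df, bivariate_spec)
        for s in subjects[:20]:
            mu, Sigma = gs.implied_moments(s, bivariate_spec, params)
            mu2, Sigma2 = _manual_moments(s, bivariate_spec, params)
            np.testing.assert_allclose(mu, mu2, atol=1e-12)
            np.testing.assert_allclose(Sigma, Sigma2, atol=1e-12)


class TestMarginalLoglik:
    def test_independence_limit(self):
        """Zero random effects, no practice, no covariates: likelihood is a
        sum of independent univariate normal log-densities."""
        spec = GrowthModelSpec(outcomes=("memory",), practice_on=())
        rng = np.random.default_rng(0)
        rows = []
        for sid in range(10):
            for k, t in enumerate([0.0, 4.1, 11.8]):
                rows.append(
                    dict(subject_id=sid, visit_order=k, time_in_study=t if k else 0.0,
                         memory=rng.normal(), died_in_next_interval=False)
                )
        df = pd.DataFrame(rows)
        params = GrowthParameters(
            alpha={"memory": (0.2, -0.1)}, gamma={}, psi=np.zeros((2, 2)),
            theta={"memory": 0.7},
        )
        ll = marginal_loglik(df, spec, params)
        mu = 0.2 - 0.1 * df["time_in_study"]
        expected = norm.logpdf(df["memory"], mu, np.sqrt(0.7)).sum()
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_duplication_doubles_loglik(self, small_cohort, bivariate_spec):
        df, truth = small_cohort
        params = truth_without_survival(truth)
        ll = marginal_loglik(df, bivariate_spec, params)
        dup = df.copy()
        dup["subject_id"] = dup["subject_id"] + 100_000
        ll2 = marginal_loglik(pd.concat([df, dup]), bivariate_spec, params)
        assert ll2 == pytest.approx(2 * ll, rel=1e-12)

    def test_row_order_invariance(self, small_cohort, bivariate_spec):
        df, truth = small_cohort
        params = truth_without_survival(truth)
        shuffled = df.sample(frac=1.0, random_state=3)
        assert marginal_loglik(shuffled, bivariate_spec, params) == pytest.approx(
            marginal_loglik(df, bivariate_spec, params), rel=1e-12
        )

    def test_fiml_missing_entry_equals_reduced_stack_oracle(self, small_cohort, bivariate_spec):
        df, truth = small_cohort
        params = truth_without_survival(truth)
        one = df[df["subject_id"] == df["subject_id"].iloc[0]].copy()
        one.loc[one.index[-1], "brain_bpf"] = np.nan
        ll = marginal_loglik(one, bivariate_spec, params)
        s = build_subject_designs(one, bivariate_spec)[0]
        mu, Sigma = _manual_moments(s, bivariate_spec, params)
        assert ll == pytest.approx(multivariate_normal.logpdf(s.y, mu, Sigma), abs=1e-10)

    def test_bivariate_factorizes_into_univariate_pieces(self, small_cohort):
        """Block-diagonal random effects and zero residual cross-covariance
        make the bivariate likelihood the product of the univariate ones."""
        df, truth = small_cohort
        psi = np.asarray(truth.psi).copy()
        psi[:2, 2:] = 0.0
        psi[2:, :2] = 0.0
        spec2 = GrowthModelSpec(outcomes=("memory", "brain_bpf"), residual_cross=True)
        params2 = GrowthParameters(
            alpha=truth.alpha, gamma={}, psi=psi, theta=truth.theta,
            theta_cross=0.0, mu_practice=truth.mu_practice,
        )
        ll_bi = marginal_loglik(df, spec2, params2)
        ll_sum = 0.0
        for i, o in enumerate(("memory", "brain_bpf")):
            spec1 = GrowthModelSpec(
                outcomes=(o,), practice_on=("memory",) if o == "memory" else (),
            )
            params1 = GrowthParameters(
                alpha={o: truth.alpha[o]}, gamma={},
                psi=psi[2 * i : 2 * i + 2, 2 * i : 2 * i + 2],
                theta={o: truth.theta[o]},
                mu_practice=truth.mu_practice if o == "memory" else 0.0,
            )
            ll_sum += marginal_loglik(df, spec1, params1)
        assert ll_bi == pytest.approx(ll_sum, abs=1e-10)

    def test_affine_covariate_recoding_invariance(self, small_cohort, bivariate_spec):
        """Shifting a centered covariate while moving the factor means by the
        compensating amount leaves the likelihood unchanged."""
        df, truth = small_cohort
        params = truth_without_survival(truth)
        ll = marginal_loglik(df, bivariate_spec, params)
        delta = 0.7
        shifted = df.copy()
        shifted["dart_z"] = shifted["dart_z"] + delta
        coef_int = params.gamma[("memory", "intercept")]["dart_z"]
        coef_slo = params.gamma[("memory", "slope")]["dart_z"]
        a0, a1 = params.alpha["memory"]
        params2 = dataclasses.replace(
            params,
            alpha={**params.alpha, "memory": (a0 - coef_int * delta, a1 - coef_slo * delta)},
        )
        assert marginal_loglik(shifted, bivariate_spec, params2) == pytest.approx(ll, rel=1e-12)

    def test_monte_carlo_oracle_small_toy(self, small_cohort, bivariate_spec):
        """3-subject toy: quadrature-free marginal density against brute-force
        Monte-Carlo integration over the latent factors."""
        df, truth = small_cohort
        params = truth_without_survival(truth)
        ids = df["subject_id"].unique()[:3]
        toy = df[df["subject_id"].isin(ids)]
        ll = marginal_loglik(toy, bivariate_spec, params)
        arr = natural_arrays(bivariate_spec, bivariate_spec.all_covariates, params)
        rng = np.random.default_rng(99)
        N = 200_000
        L = np.linalg.cholesky(arr.psi + 1e-12 * np.eye(4))
        total, var_acc = 0.0, 0.0
        for s in build_subject_designs(toy, bivariate_spec):
            mu, Sigma = _manual_moments(s, bivariate_spec, params)
            # conditional-on-eta residual density averaged over eta draws
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
                if bivariate_spec.outcomes[oi] in bivariate_spec.practice_on:
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
            vals = np.exp(logf)
            total += np.log(vals.mean())
            var_acc += (vals.std(ddof=1) / (np.sqrt(N) * vals.mean())) ** 2
        assert abs(total - ll) < 3 * np.sqrt(var_acc)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, small_cohort, bivariate_spec):
        df, truth = small_cohort
        spec = dataclasses.replace(bivariate_spec, practice_variance_free=True)
        design = build_design(df, spec)
        layout = ParameterLayout(spec)
        params = truth_without_survival(truth)
        params = dataclasses.replace(params, psi_practice=0.02)
        uvec = layout.pack(params)
        _, g = marginal_ll_grad(design, layout, uvec)
        for k in range(len(uvec)):
            h = 1e-6 * max(1.0, abs(uvec[k]))
            up, um = uvec.copy(), uvec.copy()
            up[k] += h
            um[k] -= h
            fd = (
                marginal_ll_grad(design, layout, up)[0]
                - marginal_ll_grad(design, layout, um)[0]
            ) / (2 * h)
            assert g[k] == pytest.approx(fd, rel=2e-5, abs=1e-7), layout.names[k]
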