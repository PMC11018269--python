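"""Maximum-likelihood fitting of growth curve and joint models.

Estimation maximizes the closed-form marginal likelihood (longitudinal
models) or the Gauss-Hermite joint likelihood (models with the survival
process) with L-BFGS on the unconstrained parameter scale, using analytic
gradients throughout.  Starting values come from per-subject least-squares
trajectories (factor means and covariate effects), the method of moments
(random-effect covariance, residual variances), and empirical interval
death fractions (hazard thresholds), which start the search inside the
feasible region and close to the optimum.  Standard errors are obtained
from the observed information (central finite differences of the analytic
gradient) and pushed to the natural scale by the delta method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logit

from .design import GroupedDesign, build_design
from .likelihood import arrays_from_uvec, marginal_ll_grad
from .model import (
    FitResult,
    GrowthModelSpec,
    GrowthParameters,
    ParameterLayout,
    SurvivalBlock,
)
from .survival import QuadratureRule, compute_centers, joint_ll_grad

#: quadrature used during optimization; the prior-centered layout carries
#: the analytic gradient
FIT_RULE = QuadratureRule(n_points=9, adaptive=False)


def _ols_factor_estimates(design: GroupedDesign):
    """Per-subject least-squares intercepts and slopes per outcome, plus a
    pooled residual-variance estimate.  Vectorized within pattern groups."""
    spec = design.spec
    K = spec.n_outcomes
    n = design.n_subjects
    est = np.full((n, 2 * K), np.nan)
    resid_ss = np.zeros(K)
    resid_df = np.zeros(K)
    X_rows = np.zeros((n, max(len(design.covariates), 1)))
    row = 0
    for group in design.groups:
        g = len(group.ids)
        sl = slice(row, row + g)
        if len(design.covariates):
            X_rows[sl] = group.X
        for oi in range(K):
            cols = [j for j, (vi, o) in enumerate(group.entries) if o == oi]
            if not cols:
                continue
            t = np.stack(
                [group.times[:, vi] for j, (vi, o) in enumerate(group.entries) if o == oi],
                axis=1,
            )
            y = group.Y[:, cols]
            m = t.shape[1]
            if m == 1:
                est[sl, 2 * oi] = y[:, 0]
                continue
            tbar = t.mean(axis=1, keepdims=True)
            ybar = y.mean(axis=1, keepdims=True)
            stt = ((t - tbar) ** 2).sum(axis=1)
            sty = ((t - tbar) * (y - ybar)).sum(axis=1)
            slope = sty / np.maximum(stt, 1e-12)
            intercept = (ybar - slope[:, None] * tbar)[:, 0]
            est[sl, 2 * oi] = intercept
            est[sl, 2 * oi + 1] = slope
            if m > 2:
                fitted = intercept[:, None] + slope[:, None] * t
                resid_ss[oi] += ((y - fitted) ** 2).sum()
                resid_df[oi] += g * (m - 2)
        row += g
    return est, X_rows, resid_ss, resid_df


def starting_values(design: GroupedDesign, layout: ParameterLayout) -> np.ndarray:
    spec = design.spec
    K = spec.n_outcomes
    F = spec.n_factors
    est, X, resid_ss, resid_df = _ols_factor_estimates(design)

    alpha = {}
    gamma = {}
    for oi, o in enumerate(spec.outcomes):
        ints = est[:, 2 * oi]
        slopes = est[:, 2 * oi + 1]
        a0 = float(np.nanmean(ints)) if np.isfinite(ints).any() else 0.0
        a1 = float(np.nanmean(slopes)) if np.isfinite(slopes).any() else 0.0
        alpha[o] = (a0, a1)
        for role, vals in (("intercept", ints), ("slope", slopes)):
            covs = spec.covariates_for(o, role)
            coefs = {c: 0.0 for c in covs}
            mask = np.isfinite(vals)
            if covs and mask.sum() > len(covs) + 1:
                idx = [design.covariates.index(c) for c in covs]
                Xi = np.column_stack([np.ones(mask.sum()), X[mask][:, idx]])
                beta, *_ = np.linalg.lstsq(Xi, vals[mask], rcond=None)
                coefs = {c: float(b) for c, b in zip(covs, beta[1:])}
            gamma[(o, role)] = coefs

    complete = np.isfinite(est).all(axis=1)
    if complete.sum() > F + 2:
        cov = np.cov(est[complete].T)
    else:
        cov = np.eye(F) * 0.5
    cov = 0.9 * cov + 0.1 * np.diag(np.diag(cov))
    vals, vecs = np.linalg.eigh(cov)
    floor = max(1e-4, 1e-3 * vals.max())
    psi0 = (vecs * np.clip(vals, floor, None)) @ vecs.T

    theta = {}
    for oi, o in enumerate(spec.outcomes):
        if resid_df[oi] > 10:
            theta[o] = float(max(resid_ss[oi] / resid_df[oi], 1e-3))
        else:
            base = est[:, 2 * oi]
            v = np.nanvar(base) if np.isfinite(base).any() else 1.0
            theta[o] = float(max(0.3 * v, 1e-2))

    survival = None
    if spec.include_survival:
        deaths = np.zeros(spec.n_intervals)
        at_risk = np.zeros(spec.n_intervals)
        for group in design.groups:
            g = len(group.ids)
            for k in range(1, spec.n_intervals + 1):
                if group.n_survived >= k:
                    at_risk[k - 1] += g
                elif group.died and group.n_survived + 1 == k:
                    at_risk[k - 1] += g
                    deaths[k - 1] += g
        frac = np.clip(deaths / np.maximum(at_risk, 1.0), 0.02, 0.8)
        survival = SurvivalBlock(tau=tuple(logit(frac)), link=spec.link)

    params = GrowthParameters(
        alpha=alpha,
        gamma=gamma,
        psi=psi0,
        theta=theta,
        theta_cross=0.0,
        mu_practice=0.05 if spec.has_practice else 0.0,
        psi_practice=0.01 if spec.practice_variance_free else 0.0,
        survival=survival,
    )
    return layout.pack(params)


def _precondition_scale(objective, u0: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Per-parameter scales 1/sqrt(diagonal curvature) at the start values,
    used to precondition the quasi-Newton search."""
    _, g0 = objective(u0)
    d = np.empty_like(u0)
    for k in range(len(u0)):
        h = step * max(1.0, abs(u0[k]))
        up = u0.copy()
        up[k] += h
        d[k] = (objective(up)[1][k] - g0[k]) / h
    med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    d = np.where(d > 1e-10, d, med)
    return 1.0 / np.sqrt(d)


def _observed_information(
    objective, uvec: np.ndarray, step: float = 1e-5
) -> np.ndarray:
    """Finite differences of the analytic gradient of the negative
    log-likelihood (forward differences; the gradient itself is exact, so
    the truncation error is negligible against sampling variability)."""
    d = len(uvec)
    H = np.zeros((d, d))
    _, g0 = objective(uvec)
    for k in range(d):
        h = step * max(1.0, abs(uvec[k]))
        up = uvec.copy()
        up[k] += h
        _, gp = objective(up)
        H[:, k] = (gp - g0) / h
    return 0.5 * (H + H.T)


def fit(
    data: pd.DataFrame | GroupedDesign,
    spec: GrowthModelSpec,
    rule: QuadratureRule | None = None,
    start: GrowthParameters | None = None,
    compute_vcov: bool = True,
    max_retries: int = 2,
    group_label: str | None = None,
    precondition: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood fit of a growth curve (or joint) model.

    Deterministic given the data and the starting rule; non-convergence is
    flagged in the result (never silently returned as valid).
    """
    design = data if isinstance(data, GroupedDesign) else build_design(data, spec)
    n_multi = sum(
        len(g.ids) for g in design.groups if len(np.unique(g.times[0])) >= 2
    )
    if n_multi == 0:
        raise ValueError(
            "model is not identifiable: no subject has two or more distinct "
            "observation times, so no slope information exists"
        )
    layout = ParameterLayout(spec)
    rule = rule or FIT_RULE
    u0 = layout.pack(start) if start is not None else starting_values(design, layout)

    def make_objective(ctrs):
        if spec.include_survival:
            def objective(u):
                ll, g = joint_ll_grad(design, layout, u, rule, centers=ctrs)
                return -ll, -g
        else:
            def objective(u):
                ll, g = marginal_ll_grad(design, layout, u)
                return -ll, -g
        return objective

    centers = (
        compute_centers(design, arrays_from_uvec(layout, u0))
        if spec.include_survival
        else None
    )
    objective = make_objective(centers)

    # diagonal preconditioning: the curvature of slope-scale parameters and
    # hazard loadings differs by many orders of magnitude, which stalls
    # quasi-Newton steps without it
    scale = precondition if precondition is not None else _precondition_scale(objective, u0)

    def scaled_obj_factory(obj):
        def sobj(v):
            f, g = obj(u0 + scale * v)
            return f, g * scale
        return sobj

    opts = {"maxiter": 1000, "ftol": 1e-12, "gtol": 2e-6, "maxcor": 25}
    best = None
    rng = np.random.default_rng(0)
    n_iter_total = 0
    for attempt in range(max_retries + 1):
        v_start = (
            np.zeros_like(u0)
            if attempt == 0
            else 0.05 * rng.standard_normal(len(u0)) / np.maximum(scale, 1e-8)
        )
        sobj = scaled_obj_factory(objective)
        res = minimize(sobj, v_start, jac=True, method="L-BFGS-B", options=opts)
        n_iter_total += res.nit
        if spec.include_survival:
            # refresh the posterior centering at the solution and re-polish
            # until the quadrature grid is self-consistent
            for _ in range(3):
                centers = compute_centers(
                    design, arrays_from_uvec(layout, u0 + scale * res.x)
                )
                objective = make_objective(centers)
                sobj = scaled_obj_factory(objective)
                f_new = sobj(res.x)[0]
                if abs(f_new - res.fun) <= 1e-7 * max(1.0, abs(res.fun)):
                    break
                res = minimize(sobj, res.x, jac=True, method="L-BFGS-B", options=opts)
                n_iter_total += res.nit
        gnorm = float(np.linalg.norm(res.jac))
        ok = bool(res.success) and gnorm < 1e-4 * max(1.0, abs(res.fun) ** 0.5)
        if best is None or res.fun < best[0].fun - 1e-8:
            best = (res, gnorm, ok, objective)
        if ok:
            best = (res, gnorm, ok, objective)
            break
    res, gnorm, converged, objective = best

    uhat = u0 + scale * np.asarray(res.x, dtype=float)
    params = layout.unpack(uhat)
    nat = layout.natural(uhat)
    vcov = np.full((layout.n_params, layout.n_params), np.nan)
    if compute_vcov:
        sobj = scaled_obj_factory(objective)
        Hv = _observed_information(sobj, np.asarray(res.x, dtype=float))
        try:
            cov_v = np.linalg.inv(Hv)
            if not np.all(np.isfinite(cov_v)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov_v = np.linalg.pinv(Hv)
        cov_u = cov_v * np.outer(scale, scale)
        J = layout.natural_jacobian(uhat)
        vcov = J @ cov_u @ J.T
        vcov = 0.5 * (vcov + vcov.T)

    return FitResult(
        names=layout.names,
        estimates=nat,
        vcov=vcov,
        loglik=float(-res.fun),
        n_subjects=design.n_subjects,
        converged=converged,
        n_iterations=int(n_iter_total),
        gradient_norm=gnorm,
        params=params,
        spec=spec,
        uvec=uhat,
        group_label=group_label,
    )


def multiple_group_fit(
    data: pd.DataFrame,
    spec: GrowthModelSpec,
    grouping: str | None = None,
    min_group_size: int = 30,
    rule: QuadratureRule | None = None,
    compute_vcov: bool = True,
) -> list[FitResult]:
    """Fit the model independently in every group of ``grouping`` (all
    parameters free across groups); the stacked covariance of the combined
    estimate vector is block-diagonal by construction (see
    :func:`growthsurv.wald.stack_fits`)."""
    grouping = grouping or spec.grouping
    if grouping is None:
        raise ValueError("no grouping column given")
    if grouping not in data.columns:
        raise ValueError(f"grouping column {grouping!r} not in the data")
    fits = []
    for label, grp in data.groupby(grouping, sort=True):
        n = grp["subject_id"].nunique()
        if n == 0:
            raise ValueError(f"group {label!r} is empty")
        if n < min_group_size:
            raise ValueError(
                f"group {label!r} has {n} subjects, fewer than the minimum "
                f"{min_group_size}"
            )
        fits.append(
            fit(grp, spec, rule=rule, compute_vcov=compute_vcov, group_label=str(label))
        )
    return fits
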