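"""Closed-form marginal likelihood of linear latent growth curve models.

For subject *i* with observed outcome stack :math:`y_i` (length
:math:`p_i`), loading matrix :math:`\\Lambda_i` built from the subject's
own observation times, practice loadings :math:`\\lambda_i`, and covariate
vector :math:`x_i`, the model implies

.. math::

    y_i \\sim N\\bigl(\\Lambda_i(\\alpha + \\Gamma' x_i)
        + \\lambda_i \\mu_p,\\;
        \\Lambda_i \\Psi \\Lambda_i' + \\psi_p \\lambda_i\\lambda_i'
        + R_i\\bigr),

where :math:`R_i` carries the per-outcome residual variances on its
diagonal and the within-occasion cross-outcome residual covariance on the
same-visit memory-brain entries.  Missing entries are simply dropped from
the stack (full-information maximum likelihood).  The marginal
log-likelihood is the sum of the resulting multivariate-normal
log-densities; analytic gradients with respect to every parameter block
are accumulated alongside for the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import GroupedDesign, PatternGroup, SubjectDesign, build_design
from .model import GrowthModelSpec, GrowthParameters, ParameterLayout
from .practice import practice_loading

__all__ = ["practice_loading", "implied_moments", "marginal_loglik"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class NaturalArrays:
    """Dense array view of a parameter value for fast evaluation."""

    alpha: np.ndarray      # (F,)
    G: np.ndarray          # (C, F) dense coefficients with structural zeros
    psi: np.ndarray        # (F, F)
    theta: np.ndarray      # (K, n_visits) residual variances per occasion
    tcross: float
    mu_p: float
    psi_p: float
    tau: np.ndarray | None = None
    g0: float = 0.0
    g1: float = 0.0


def natural_arrays(
    spec: GrowthModelSpec, covariates: tuple[str, ...], params: GrowthParameters
) -> NaturalArrays:
    params.validate()
    theta_rows = []
    for o in spec.outcomes:
        th = params.theta[o]
        theta_rows.append([th] * spec.n_visits if np.isscalar(th) else list(th))
    arr = NaturalArrays(
        alpha=params.alpha_vector(spec.outcomes),
        G=params.gamma_matrix(covariates, spec.factor_names),
        psi=np.asarray(params.psi, dtype=float),
        theta=np.asarray(theta_rows, dtype=float),
        tcross=float(params.theta_cross) if spec.has_residual_cross else 0.0,
        mu_p=float(params.mu_practice),
        psi_p=float(params.psi_practice),
    )
    if params.survival is not None:
        arr.tau = np.asarray(params.survival.tau, dtype=float)
        arr.g0 = float(params.survival.gamma0)
        arr.g1 = float(params.survival.gamma1)
    return arr


def arrays_from_uvec(layout: ParameterLayout, uvec: np.ndarray) -> NaturalArrays:
    """Natural arrays straight from the unconstrained vector (no dict
    round-trip, exact Cholesky consistency with the transform)."""
    spec = layout.spec
    uvec = np.asarray(uvec, dtype=float)
    alpha = uvec[layout.sl_alpha].copy()
    G = np.zeros(layout.free_gamma.shape)
    for val, (ci, j) in zip(uvec[layout.sl_beta], layout._beta_idx):
        G[ci, j] = val
    L = layout.psi_chol(uvec)
    K = len(spec.outcomes)
    theta_flat = np.exp(uvec[layout.sl_theta])
    if spec.occasion_residuals:
        theta = theta_flat.reshape(K, spec.n_visits)
    else:
        theta = np.repeat(theta_flat[:, None], spec.n_visits, axis=1)
    tcross = 0.0
    if layout.i_tcross is not None:
        tcross = float(np.tanh(uvec[layout.i_tcross]) * np.sqrt(theta_flat.prod()))
    mu_p = float(uvec[layout.i_mup]) if layout.i_mup is not None else 0.0
    psi_p = float(np.exp(uvec[layout.i_psip])) if layout.i_psip is not None else 0.0
    arr = NaturalArrays(
        alpha=alpha, G=G, psi=L @ L.T, theta=theta, tcross=tcross,
        mu_p=mu_p, psi_p=psi_p,
    )
    if spec.include_survival:
        arr.tau = uvec[layout.sl_tau].copy()
        arr.g0 = float(uvec[layout.i_gamma0])
        arr.g1 = float(uvec[layout.i_gamma1])
    return arr


def _residual_matrix(group: PatternGroup, arr: NaturalArrays) -> np.ndarray:
    p = len(group.entries)
    R = np.zeros((p, p))
    R[np.arange(p), np.arange(p)] = arr.theta[group.diag_outcome, group.diag_visit]
    for j1, j2 in group.cross_pairs:
        R[j1, j2] = R[j2, j1] = arr.tcross
    if arr.psi_p > 0:
        R += arr.psi_p * np.outer(group.lam, group.lam)
    return R


def _group_mean(group: PatternGroup, arr: NaturalArrays) -> np.ndarray:
    b = arr.alpha[None, :] + group.X @ arr.G  # (g, F) factor means per subject
    return np.einsum("gpf,gf->gp", group.Lam, b) + group.lam[None, :] * arr.mu_p


def _group_cov(group: PatternGroup, arr: NaturalArrays) -> np.ndarray:
    LamPsi = group.Lam @ arr.psi
    return LamPsi @ group.Lam.transpose(0, 2, 1) + _residual_matrix(group, arr)


def _safe_cholesky(Sigma: np.ndarray, group: PatternGroup) -> np.ndarray:
    try:
        return np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        for i in range(Sigma.shape[0]):
            try:
                np.linalg.cholesky(Sigma[i])
            except np.linalg.LinAlgError:
                raise ValueError(
                    "implied outcome covariance is not positive definite for "
                    f"subject {group.ids[i]!r}"
                ) from None
        raise


def marginal_core(
    design: GroupedDesign, arr: NaturalArrays, want_grad: bool = False
) -> tuple[float, dict | None]:
    """Log-likelihood (and optional natural-block gradients) of the
    longitudinal part over all pattern groups."""
    F = design.spec.n_factors
    K = design.spec.n_outcomes
    C = len(design.covariates)
    ll = 0.0
    blocks = None
    if want_grad:
        blocks = {
            "alpha": np.zeros(F),
            "gamma": np.zeros((C, F)),
            "psi_full": np.zeros((F, F)),
            "theta": np.zeros((K, design.spec.n_visits)),
            "theta_cross": 0.0,
            "mu_practice": 0.0,
            "psi_practice": 0.0,
        }
    for group in design.groups:
        p = len(group.entries)
        mu = _group_mean(group, arr)
        Sigma = _group_cov(group, arr)
        chol = _safe_cholesky(Sigma, group)
        logdet = 2.0 * np.log(np.einsum("gpp->gp", chol)).sum(axis=1)
        Sinv = np.linalg.inv(Sigma)
        r = group.Y - mu
        u = (Sinv @ r[..., None])[..., 0]
        quad = np.einsum("gp,gp->g", r, u)
        ll += float(-0.5 * (p * _LOG2PI * len(group.ids) + logdet.sum() + quad.sum()))
        if not want_grad:
            continue
        W = 0.5 * (u[:, :, None] * u[:, None, :] - Sinv)
        A = (group.Lam.transpose(0, 2, 1) @ u[..., None])[..., 0]
        blocks["alpha"] += A.sum(axis=0)
        if C:
            blocks["gamma"] += group.X.T @ A
        blocks["mu_practice"] += float(group.lam @ u.sum(axis=0))
        WL = W @ group.Lam
        blocks["psi_full"] += np.einsum("gpf,gph->fh", group.Lam, WL)
        Wdiag = np.einsum("gpp->gp", W).sum(axis=0)
        np.add.at(blocks["theta"], (group.diag_outcome, group.diag_visit), Wdiag)
        for j1, j2 in group.cross_pairs:
            blocks["theta_cross"] += 2.0 * W[:, j1, j2].sum()
        blocks["psi_practice"] += float(group.lam @ (W.sum(axis=0) @ group.lam))
    return ll, blocks


def marginal_ll_grad(
    design: GroupedDesign, layout: ParameterLayout, uvec: np.ndarray
) -> tuple[float, np.ndarray]:
    """Objective for the optimizer: log-likelihood and its gradient on the
    unconstrained scale."""
    arr = arrays_from_uvec(layout, uvec)
    ll, blocks = marginal_core(design, arr, want_grad=True)
    return ll, layout.assemble_grad(uvec, blocks)


def implied_moments(
    subject: SubjectDesign, spec: GrowthModelSpec, params: GrowthParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix of one subject's
    observed outcome stack (visit-major order, missing entries dropped)."""
    if subject.n_obs == 0:
        raise ValueError(f"subject {subject.subject_id!r} has no observed outcomes")
    design = GroupedDesign([subject], spec, spec.all_covariates)
    arr = natural_arrays(spec, spec.all_covariates, params)
    group = design.groups[0]
    return _group_mean(group, arr)[0], _group_cov(group, arr)[0]


def marginal_loglik(
    data: pd.DataFrame | GroupedDesign,
    spec: GrowthModelSpec,
    params: GrowthParameters,
) -> float:
    """Marginal (longitudinal-only) log-likelihood of a cohort.

    The survival-augmented likelihood lives in
    :func:`growthsurv.survival.joint_loglik`; this function requires a
    spec without the survival process.
    """
    if spec.include_survival:
        raise ValueError(
            "spec includes the survival process; use joint_loglik instead"
        )
    design = data if isinstance(data, GroupedDesign) else build_design(data, spec)
    arr = natural_arrays(spec, design.covariates, params)
    ll, _ = marginal_core(design, arr, want_grad=False)
    return ll
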