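"""Discrete-time survival submodel and the joint longitudinal-survival
likelihood.

Death is modeled as a per-interval conditional probability (hazard) given
survival to the interval: with three planned visits there are two risk
intervals.  The latent hazard in interval *k* is

.. math:: h_k(\\eta) = g^{-1}(\\tau_k + \\gamma_0\\eta_0 + \\gamma_1\\eta_1),

where :math:`(\\eta_0, \\eta_1)` are the growth intercept and slope of the
hazard-carrying outcome (memory by default) and :math:`g` is the logit
link (probit available).  The joint likelihood integrates, per subject,
the product of the Gaussian outcome density and the survival probability
over the latent factors with Gauss-Hermite quadrature.

Two integration layouts are provided.  The *posterior-centered* layout
(default for evaluation) factors the integrand as the exact marginal
Gaussian density times the posterior expectation of the survival factor;
it is exactly separable when the hazard loadings vanish.  The
*prior-centered* layout expands the outcome density conditional on the
hazard-factor deviations and carries analytic gradients for every
parameter; it is the objective the optimizer uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit, log_ndtr
from scipy.stats import norm

from .design import GroupedDesign, build_design
from .likelihood import (
    NaturalArrays,
    _group_cov,
    _group_mean,
    _residual_matrix,
    _safe_cholesky,
    arrays_from_uvec,
    marginal_core,
    natural_arrays,
)
from .model import GrowthModelSpec, GrowthParameters, ParameterLayout, SurvivalBlock

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# hazard primitives
# ---------------------------------------------------------------------------

def _check_link(link: str) -> None:
    if link not in ("logit", "probit"):
        raise ValueError(f"unknown link {link!r}")


def _log_h_and_log_1mh(lp: np.ndarray, link: str):
    if link == "logit":
        return -np.logaddexp(0.0, -lp), -np.logaddexp(0.0, lp)
    return log_ndtr(lp), log_ndtr(-lp)


def _hazard_derivs(lp: np.ndarray, link: str):
    """d log h / d lp and d log(1-h) / d lp."""
    if link == "logit":
        h = expit(lp)
        return 1.0 - h, -h
    pdf = norm.pdf(lp)
    return pdf / np.maximum(norm.cdf(lp), 1e-300), -pdf / np.maximum(
        norm.sf(lp), 1e-300
    )


def discrete_hazard(eta, interval: int, block: SurvivalBlock) -> np.ndarray:
    """Conditional probability of death in risk interval ``interval``
    (1-based) given survival so far, at latent factor values ``eta``
    (..., 2) = (intercept, slope)."""
    if not 1 <= interval <= block.n_intervals:
        raise ValueError(
            f"interval must be in 1..{block.n_intervals}, got {interval}"
        )
    eta = np.asarray(eta, dtype=float)
    lp = block.tau[interval - 1] + block.gamma0 * eta[..., 0] + block.gamma1 * eta[..., 1]
    return expit(lp) if block.link == "logit" else norm.cdf(lp)


def survival_loglik_given_eta(record, eta, block: SurvivalBlock) -> float:
    """Discrete-time survival log-likelihood of one subject's record at
    fixed latent factor values.

    ``record`` is ``(n_survived, died)`` or any object with those
    attributes: the subject survived risk intervals ``1..n_survived`` and,
    if ``died``, died in interval ``n_survived + 1``.
    """
    if hasattr(record, "n_survived"):
        n_survived, died = record.n_survived, record.died
    else:
        n_survived, died = record
    if n_survived < 0 or (died and n_survived + 1 > block.n_intervals):
        raise ValueError(
            f"inconsistent survival record (n_survived={n_survived}, died={died})"
        )
    eta = np.asarray(eta, dtype=float)
    total = 0.0
    for k in range(1, n_survived + 1):
        lp = block.tau[k - 1] + block.gamma0 * eta[..., 0] + block.gamma1 * eta[..., 1]
        total = total + _log_h_and_log_1mh(lp, block.link)[1]
    if died:
        k = n_survived + 1
        lp = block.tau[k - 1] + block.gamma0 * eta[..., 0] + block.gamma1 * eta[..., 1]
        total = total + _log_h_and_log_1mh(lp, block.link)[0]
    return total


def survival_loglik(
    data: pd.DataFrame | GroupedDesign,
    spec: GrowthModelSpec,
    params: GrowthParameters,
) -> float:
    """Stand-alone survival log-likelihood evaluated at each subject's
    *factor means* (no integration over the random effects).  With zero
    hazard loadings this is the exact survival likelihood, and the joint
    likelihood separates into this plus the longitudinal likelihood."""
    design = data if isinstance(data, GroupedDesign) else build_design(data, spec)
    arr = natural_arrays(spec, design.covariates, params)
    if arr.tau is None:
        raise ValueError("params carry no survival block")
    h0, h1 = spec.hazard_factor_indices
    block = params.survival
    total = 0.0
    for group in design.groups:
        b = arr.alpha[None, :] + group.X @ arr.G
        eta = b[:, [h0, h1]]
        total += float(
            np.sum(survival_loglik_given_eta((group.n_survived, group.died), eta, block))
        )
    return total


# ---------------------------------------------------------------------------
# quadrature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadratureRule:
    """Gauss-Hermite rule over the latent hazard factors.

    ``n_points`` nodes per latent dimension (two dimensions: intercept and
    slope deviations).  ``adaptive=True`` centers the integration at each
    subject's posterior distribution of the deviations given their
    outcomes, which makes the evaluation exactly separable when the hazard
    loadings are zero; ``adaptive=False`` centers at the prior (the factor
    means).
    """

    n_points: int = 15
    dimension: int = 2
    adaptive: bool = True

    def __post_init__(self):
        if self.n_points < 3:
            raise ValueError("n_points must be at least 3")
        if self.dimension != 2:
            raise ValueError("the joint model integrates over 2 latent dimensions")

    def nodes(self) -> tuple[np.ndarray, np.ndarray]:
        """Nodes ``z`` (Q, 2) and log-weights for an N(0, I_2) measure."""
        x, w = hermgauss(self.n_points)
        z1 = np.sqrt(2.0) * x
        logw1 = np.log(w) - 0.5 * np.log(np.pi)
        z = np.array([(a, b) for a in z1 for b in z1])
        logw = np.add.outer(logw1, logw1).ravel()
        return z, logw


DEFAULT_RULE = QuadratureRule()


# ---------------------------------------------------------------------------
# survival factor over quadrature nodes
# ---------------------------------------------------------------------------

def _group_logS_and_coefs(
    eta_q: np.ndarray,  # (g, Q, 2) latent factor values at the nodes
    n_survived: int,
    died: bool,
    tau: np.ndarray,
    g0: float,
    g1: float,
    link: str,
    want_grad: bool,
):
    """log survival factor (g, Q) and, optionally, the per-interval
    coefficients c_k = d logS / d linpred_k (g, Q, K_used)."""
    g, Q = eta_q.shape[:2]
    logS = np.zeros((g, Q))
    used = list(range(1, n_survived + 1)) + ([n_survived + 1] if died else [])
    coefs = np.zeros((g, Q, len(used))) if want_grad else None
    base = g0 * eta_q[..., 0] + g1 * eta_q[..., 1]
    for idx, k in enumerate(used):
        lp = tau[k - 1] + base
        logh, log1mh = _log_h_and_log_1mh(lp, link)
        is_death = died and k == n_survived + 1
        logS += logh if is_death else log1mh
        if want_grad:
            dlogh, dlog1mh = _hazard_derivs(lp, link)
            coefs[..., idx] = dlogh if is_death else dlog1mh
    return logS, used, coefs


# ---------------------------------------------------------------------------
# joint likelihood: prior-centered engine (value + analytic gradient)
# ---------------------------------------------------------------------------

def _chol_grad_to_psi_grad(L: np.ndarray, gL: np.ndarray) -> np.ndarray:
    """Map a gradient w.r.t. the Cholesky factor to the full-matrix
    derivative w.r.t. Psi = L L'."""
    S = L.T @ np.tril(gL)
    P = np.tril(S) + np.tril(S, -1).T
    Linv = np.linalg.inv(L)
    G = 0.5 * Linv.T @ P @ Linv
    return 0.5 * (G + G.T)


def compute_centers(
    design: GroupedDesign, arr: NaturalArrays
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-group posterior centering of the quadrature grid.

    For every subject, the Gaussian posterior of the standardized
    hazard-factor coordinates given the outcomes (survival factor ignored)
    is N((I+B)^{-1} a, (I+B)^{-1}); the returned (mean, Cholesky-scale)
    pairs re-center and re-scale the Gauss-Hermite nodes there, which keeps
    the quadrature accurate even when the residual variances make the
    posterior much narrower than the prior.  The centers are treated as
    fixed constants of the objective, so the analytic gradient stays exact.
    """
    spec = design.spec
    F = spec.n_factors
    h0, h1 = spec.hazard_factor_indices
    perm = [h0, h1] + [f for f in range(F) if f not in (h0, h1)]
    psi_p = arr.psi[np.ix_(perm, perm)]
    scale = max(np.trace(psi_p) / F, 1e-12)
    Lp = np.linalg.cholesky(psi_p + 1e-12 * scale * np.eye(F))
    centers = []
    for group in design.groups:
        Lamp = group.Lam[:, :, perm]
        mu = _group_mean(group, arr)
        M = Lamp @ Lp[:, :2]
        Kmat = Lamp @ Lp[:, 2:]
        Sigma_c = np.einsum("gpf,gqf->gpq", Kmat, Kmat) + _residual_matrix(group, arr)
        Sinv = np.linalg.inv(Sigma_c)
        r = group.Y - mu
        u0 = np.einsum("gpq,gq->gp", Sinv, r)
        a = np.einsum("gpi,gp->gi", M, u0)
        N = np.einsum("gpq,gqi->gpi", Sinv, M)
        B = np.einsum("gpi,gpj->gij", M, N)
        prec = np.eye(2)[None] + B
        Vz = np.linalg.inv(prec)
        Vz = 0.5 * (Vz + np.swapaxes(Vz, 1, 2))
        mz = np.einsum("gij,gj->gi", Vz, a)
        A = np.linalg.cholesky(Vz + 1e-12 * np.eye(2)[None])
        centers.append((mz, A))
    return centers


def joint_core(
    design: GroupedDesign,
    arr: NaturalArrays,
    rule: QuadratureRule,
    want_grad: bool = False,
    centers: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[float, dict | None]:
    """Gauss-Hermite joint log-likelihood over the hazard-factor deviations.

    Conditional on the hazard-factor deviations the outcome stack stays
    Gaussian with a node-independent covariance, so the node dependence
    reduces to a quadratic form in the two-dimensional node coordinates;
    everything else is batched per pattern group.  Optional ``centers``
    (see :func:`compute_centers`) re-center the node grid per subject; the
    grid is held fixed, so the integral approximation remains a smooth
    deterministic function of the parameters with an exact analytic
    gradient.
    """
    spec = design.spec
    if arr.tau is None:
        raise ValueError("parameters carry no survival block")
    F = spec.n_factors
    K = spec.n_outcomes
    C = len(design.covariates)
    h0, h1 = spec.hazard_factor_indices
    perm = [h0, h1] + [f for f in range(F) if f not in (h0, h1)]
    inv_perm = np.argsort(perm)
    psi_p = arr.psi[np.ix_(perm, perm)]
    scale = max(np.trace(psi_p) / F, 1e-12)
    Lp = np.linalg.cholesky(psi_p + 1e-12 * scale * np.eye(F))
    gamma_vec = np.array([arr.g0, arr.g1])
    z, logw = rule.nodes()
    Q = z.shape[0]

    ll = 0.0
    gL = np.zeros((F, F))
    blocks = None
    if want_grad:
        blocks = {
            "alpha": np.zeros(F),
            "gamma": np.zeros((C, F)),
            "theta": np.zeros((K, spec.n_visits)),
            "theta_cross": 0.0,
            "mu_practice": 0.0,
            "psi_practice": 0.0,
            "tau": np.zeros(spec.n_intervals),
            "gamma0": 0.0,
            "gamma1": 0.0,
        }

    for gi, group in enumerate(design.groups):
        g = len(group.ids)
        p = len(group.entries)
        Lamp = group.Lam[:, :, perm]
        mu = _group_mean(group, arr)
        M = Lamp @ Lp[:, :2]                      # (g, p, 2) mean shift per unit node
        Kmat = Lamp @ Lp[:, 2:]                   # (g, p, F-2)
        Sigma_c = Kmat @ Kmat.transpose(0, 2, 1) + _residual_matrix(group, arr)
        chol = _safe_cholesky(Sigma_c, group)
        logdet = 2.0 * np.log(np.einsum("gpp->gp", chol)).sum(axis=1)
        Sinv = np.linalg.inv(Sigma_c)
        r = group.Y - mu
        u0 = (Sinv @ r[..., None])[..., 0]
        quad0 = np.einsum("gp,gp->g", r, u0)
        a = (M.transpose(0, 2, 1) @ u0[..., None])[..., 0]   # (g, 2)
        N = Sinv @ M                              # (g, p, 2)
        B = M.transpose(0, 2, 1) @ N              # (g, 2, 2)

        if centers is not None:
            mz, A = centers[gi]
            zt = mz[:, None, :] + z @ A.transpose(0, 2, 1)         # (g, Q, 2)
            logjac = np.log(np.einsum("gii->gi", A)).sum(axis=1)   # (g,)
            logextra = (
                logjac[:, None]
                + 0.5 * (z**2).sum(axis=1)[None, :]
                - 0.5 * (zt**2).sum(axis=2)
            )
        else:
            zt = np.broadcast_to(z[None, :, :], (g, Q, 2))
            logextra = 0.0

        za = (zt @ a[..., None])[..., 0]
        zBz = ((zt @ B) * zt).sum(axis=2)
        logF = -0.5 * (
            (p * _LOG2PI + logdet + quad0)[:, None] - 2.0 * za + zBz
        )

        b_means = arr.alpha[None, :] + group.X @ arr.G
        gmean = b_means[:, [h0, h1]]              # (g, 2)
        eta_q = gmean[:, None, :] + np.einsum("ij,gqj->gqi", Lp[:2, :2], zt)
        logS, used, coefs = _group_logS_and_coefs(
            eta_q, group.n_survived, group.died, arr.tau, arr.g0, arr.g1,
            spec.link, want_grad,
        )

        joint = logw[None, :] + logextra + logF + logS
        m = joint.max(axis=1)
        if not np.all(np.isfinite(m)):
            raise ValueError(
                "quadrature underflow in the joint likelihood; increase "
                "n_points or use the adaptive rule"
            )
        lse = m + np.log(np.exp(joint - m[:, None]).sum(axis=1))
        ll += float(lse.sum())
        if not want_grad:
            continue

        omega = np.exp(joint - lse[:, None])      # (g, Q) posterior node weights
        zbar = (omega[:, None, :] @ zt)[:, 0, :]
        Z2 = zt.transpose(0, 2, 1) @ (omega[..., None] * zt)
        Nzbar = (N @ zbar[..., None])[..., 0]
        ubar = u0 - Nzbar
        uu = (
            u0[:, :, None] * u0[:, None, :]
            - u0[:, :, None] * Nzbar[:, None, :]
            - Nzbar[:, :, None] * u0[:, None, :]
            + N @ Z2 @ N.transpose(0, 2, 1)
        )
        W = 0.5 * (uu - Sinv)

        # mean parameters through the Gaussian factor
        A = (group.Lam.transpose(0, 2, 1) @ ubar[..., None])[..., 0]
        blocks["alpha"] += A.sum(axis=0)
        if C:
            blocks["gamma"] += group.X.T @ A
        blocks["mu_practice"] += float(group.lam @ ubar.sum(axis=0))

        # survival coefficients
        a_q = coefs.sum(axis=2)                   # (g, Q)
        s1 = (omega * a_q).sum(axis=1)            # (g,)
        gm_contrib = s1[:, None] * gamma_vec[None, :]
        blocks["alpha"][[h0, h1]] += gm_contrib.sum(axis=0)
        if C:
            blocks["gamma"][:, [h0, h1]] += group.X.T @ gm_contrib
        for idx, k in enumerate(used):
            blocks["tau"][k - 1] += float((omega * coefs[..., idx]).sum())
        blocks["gamma0"] += float((omega * a_q * eta_q[..., 0]).sum())
        blocks["gamma1"] += float((omega * a_q * eta_q[..., 1]).sum())

        # residual structure through the conditional covariance
        Wdiag = np.einsum("gpp->gp", W).sum(axis=0)
        np.add.at(blocks["theta"], (group.diag_outcome, group.diag_visit), Wdiag)
        for j1, j2 in group.cross_pairs:
            blocks["theta_cross"] += 2.0 * W[:, j1, j2].sum()
        blocks["psi_practice"] += float(group.lam @ (W.sum(axis=0) @ group.lam))

        # Cholesky factor of the (permuted) random-effect covariance
        WL = W @ Lamp                             # (g, p, F)
        T = np.einsum("gpf,gph->fh", Lamp, WL)
        gL[:, 2:] += 2.0 * (T @ Lp)[:, 2:]
        UZ = u0[:, :, None] * zbar[:, None, :] - N @ Z2
        gL[:, :2] += np.einsum("gpf,gpb->fb", Lamp, UZ)
        az = ((omega * a_q)[:, None, :] @ zt)[:, 0, :]
        gL[:2, :2] += np.outer(gamma_vec, az.sum(axis=0))

    if want_grad:
        gL = np.tril(gL)
        Gpsi_perm = _chol_grad_to_psi_grad(Lp, gL)
        blocks["psi_full"] = Gpsi_perm[np.ix_(inv_perm, inv_perm)]
    return ll, blocks


def joint_ll_grad(
    design: GroupedDesign, layout: ParameterLayout, uvec: np.ndarray,
    rule: QuadratureRule, centers=None,
) -> tuple[float, np.ndarray]:
    """Optimizer objective: joint log-likelihood and unconstrained gradient."""
    arr = arrays_from_uvec(layout, uvec)
    ll, blocks = joint_core(design, arr, rule, want_grad=True, centers=centers)
    return ll, layout.assemble_grad(uvec, blocks)


# ---------------------------------------------------------------------------
# posterior-centered evaluation
# ---------------------------------------------------------------------------

def _joint_loglik_adaptive(
    design: GroupedDesign, arr: NaturalArrays, spec: GrowthModelSpec,
    rule: QuadratureRule,
) -> float:
    """Exact marginal Gaussian term plus the posterior expectation of the
    survival factor, the latter integrated with Gauss-Hermite nodes
    re-centered at each subject's posterior of the hazard-factor
    deviations given their observed outcomes."""
    h0, h1 = spec.hazard_factor_indices
    hidx = [h0, h1]
    z, logw = rule.nodes()
    ll = 0.0
    for group in design.groups:
        mu = _group_mean(group, arr)
        Sigma = _group_cov(group, arr)
        chol = _safe_cholesky(Sigma, group)
        logdet = 2.0 * np.log(np.einsum("gpp->gp", chol)).sum(axis=1)
        Sinv = np.linalg.inv(Sigma)
        r = group.Y - mu
        u = np.einsum("gpq,gq->gp", Sinv, r)
        p = len(group.entries)
        ll += float(
            -0.5
            * (p * _LOG2PI * len(group.ids) + logdet.sum() + np.einsum("gp,gp->", r, u))
        )

        # posterior of the hazard-factor deviations given the outcomes
        Cmat = np.einsum("hf,gpf->ghp", arr.psi[hidx, :], group.Lam)  # (g, 2, p)
        m_post = np.einsum("ghp,gp->gh", Cmat, u)
        CSin = np.einsum("ghp,gpq->ghq", Cmat, Sinv)
        V = arr.psi[np.ix_(hidx, hidx)][None] - np.einsum("ghp,gip->ghi", CSin, Cmat)
        V = 0.5 * (V + np.swapaxes(V, 1, 2))
        tr = np.einsum("ghh->g", V).max()
        Lv = np.linalg.cholesky(V + 1e-14 * max(tr, 1e-12) * np.eye(2)[None])

        b_means = arr.alpha[None, :] + group.X @ arr.G
        gmean = b_means[:, hidx]
        eta_q = (gmean + m_post)[:, None, :] + np.einsum(
            "ghi,qi->gqh", Lv, z
        )
        logS, _, _ = _group_logS_and_coefs(
            eta_q, group.n_survived, group.died, arr.tau, arr.g0, arr.g1,
            spec.link, want_grad=False,
        )
        joint = logw[None, :] + logS
        m = joint.max(axis=1)
        if not np.all(np.isfinite(m)):
            raise ValueError(
                "quadrature underflow in the joint likelihood; increase "
                "n_points or use the adaptive rule"
            )
        ll += float((m + np.log(np.exp(joint - m[:, None]).sum(axis=1))).sum())
    return ll


def joint_loglik(
    data: pd.DataFrame | GroupedDesign,
    spec: GrowthModelSpec,
    params: GrowthParameters,
    rule: QuadratureRule | None = None,
) -> float:
    """Joint longitudinal-survival log-likelihood of a cohort.

    With zero hazard loadings the result equals
    ``marginal_loglik + survival_loglik`` (exactly, under the default
    posterior-centered rule).
    """
    if not spec.include_survival:
        raise ValueError("spec does not include the survival process")
    rule = rule or DEFAULT_RULE
    design = data if isinstance(data, GroupedDesign) else build_design(data, spec)
    arr = natural_arrays(spec, design.covariates, params)
    if rule.adaptive:
        return _joint_loglik_adaptive(design, arr, spec, rule)
    ll, _ = joint_core(design, arr, rule, want_grad=False)
    return ll
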