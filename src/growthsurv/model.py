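"""Model specifications, parameter containers, and the unconstrained
parametrization used by the optimizer.

A :class:`GrowthModelSpec` declares *which* model to fit (outcomes,
covariates on intercepts and slopes, practice factor, survival inclusion);
a :class:`GrowthParameters` holds one full parameter value on its natural
scale; a :class:`ParameterLayout` maps between the two and an unconstrained
real vector (log variances, log-Cholesky random-effect covariance,
Fisher-z residual correlation) so that quasi-Newton optimization stays
inside the feasible region by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

ROLES = ("intercept", "slope")


@dataclass(frozen=True)
class SurvivalBlock:
    """Discrete-time survival parameters.

    ``tau`` holds the per-interval hazard intercepts on the link scale
    (one per risk interval); ``gamma0`` and ``gamma1`` regress the latent
    hazard on the growth intercept and slope of the hazard-carrying
    outcome.  The logit link is the conventional discrete-time choice;
    probit is available.
    """

    tau: tuple[float, ...]
    gamma0: float = 0.0
    gamma1: float = 0.0
    link: str = "logit"

    def __post_init__(self):
        if self.link not in ("logit", "probit"):
            raise ValueError(f"unknown link {self.link!r}; use 'logit' or 'probit'")
        vals = np.asarray(self.tau, dtype=float)
        if not np.all(np.isfinite(vals)) or not np.isfinite([self.gamma0, self.gamma1]).all():
            raise ValueError("survival parameters must be finite")

    @property
    def n_intervals(self) -> int:
        return len(self.tau)


@dataclass(frozen=True)
class GrowthModelSpec:
    """Declarative description of one growth curve model."""

    outcomes: tuple[str, ...] = ("memory",)
    intercept_covariates: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    slope_covariates: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    practice_on: tuple[str, ...] = ("memory",)
    practice_variance_free: bool = False
    residual_cross: bool = True
    occasion_residuals: bool = False
    include_survival: bool = False
    n_intervals: int = 2
    link: str = "logit"
    hazard_on: str = "memory"
    practice_rounding: str = "exact"
    grouping: str | None = None

    def __post_init__(self):
        if len(self.outcomes) not in (1, 2):
            raise ValueError("outcomes must name one or two processes")
        if len(set(self.outcomes)) != len(self.outcomes):
            raise ValueError("outcomes must be distinct")
        for o in self.practice_on:
            if o not in self.outcomes:
                raise ValueError(f"practice_on names unknown outcome {o!r}")
        if self.include_survival and self.hazard_on not in self.outcomes:
            raise ValueError(f"hazard_on names unknown outcome {self.hazard_on!r}")
        if self.practice_rounding not in ("exact", "one-decimal"):
            raise ValueError("practice_rounding must be 'exact' or 'one-decimal'")
        if self.occasion_residuals and len(self.outcomes) == 2:
            raise ValueError(
                "occasion-specific residual variances are supported for "
                "single-outcome models only"
            )

    # -- derived structure -------------------------------------------------
    @property
    def n_outcomes(self) -> int:
        return len(self.outcomes)

    @property
    def factor_names(self) -> tuple[tuple[str, str], ...]:
        """Latent factors in canonical order: (outcome, role) pairs."""
        return tuple((o, r) for o in self.outcomes for r in ROLES)

    @property
    def n_factors(self) -> int:
        return 2 * self.n_outcomes

    def covariates_for(self, outcome: str, role: str) -> tuple[str, ...]:
        src = self.intercept_covariates if role == "intercept" else self.slope_covariates
        return tuple(src.get(outcome, ()))

    @property
    def all_covariates(self) -> tuple[str, ...]:
        seen: list[str] = []
        for o, r in self.factor_names:
            for c in self.covariates_for(o, r):
                if c not in seen:
                    seen.append(c)
        return tuple(seen)

    @property
    def n_visits(self) -> int:
        return self.n_intervals + 1

    @property
    def has_practice(self) -> bool:
        return len(self.practice_on) > 0

    @property
    def has_residual_cross(self) -> bool:
        return self.n_outcomes == 2 and self.residual_cross

    @property
    def hazard_factor_indices(self) -> tuple[int, int]:
        i = self.outcomes.index(self.hazard_on)
        return (2 * i, 2 * i + 1)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "outcomes": list(self.outcomes),
            "intercept_covariates": {k: list(v) for k, v in self.intercept_covariates.items()},
            "slope_covariates": {k: list(v) for k, v in self.slope_covariates.items()},
            "practice_on": list(self.practice_on),
            "practice_variance_free": self.practice_variance_free,
            "residual_cross": self.residual_cross,
            "occasion_residuals": self.occasion_residuals,
            "include_survival": self.include_survival,
            "n_intervals": self.n_intervals,
            "link": self.link,
            "hazard_on": self.hazard_on,
            "practice_rounding": self.practice_rounding,
            "grouping": self.grouping,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GrowthModelSpec":
        d = dict(d)
        for key in ("outcomes", "practice_on"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("intercept_covariates", "slope_covariates"):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GrowthModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GrowthParameters:
    """One full parameter value on the natural scale.

    ``alpha`` maps each outcome to its (intercept mean, slope mean);
    ``gamma`` maps (outcome, role) to covariate coefficients; ``psi`` is
    the random-effect covariance over the factors in canonical order;
    ``theta`` holds residual variances, ``theta_cross`` the within-occasion
    cross-outcome residual covariance; ``mu_practice``/``psi_practice`` the
    practice-factor mean and variance; ``survival`` the hazard block.
    """

    alpha: dict
    gamma: dict
    psi: np.ndarray
    theta: dict
    theta_cross: float = 0.0
    mu_practice: float = 0.0
    psi_practice: float = 0.0
    survival: SurvivalBlock | None = None

    def validate(self) -> None:
        psi = np.asarray(self.psi, dtype=float)
        if not np.allclose(psi, psi.T):
            raise ValueError("psi is not symmetric")
        eig = np.linalg.eigvalsh(psi)
        if eig.min() < -1e-10 * max(1.0, abs(eig).max()):
            raise ValueError(
                f"psi is not positive semi-definite (min eigenvalue {eig.min():.3g})"
            )
        for o, th in self.theta.items():
            if np.any(np.atleast_1d(th) <= 0):
                raise ValueError(f"theta[{o!r}] must be positive")
        if len(self.theta) == 2 and all(np.isscalar(t) for t in self.theta.values()):
            bound = float(np.sqrt(np.prod(list(self.theta.values()))))
            if abs(self.theta_cross) > bound + 1e-12:
                raise ValueError("theta_cross exceeds the Cauchy-Schwarz bound")
        if self.psi_practice < 0:
            raise ValueError("psi_practice must be non-negative")

    def alpha_vector(self, outcomes: Sequence[str]) -> np.ndarray:
        return np.array([v for o in outcomes for v in self.alpha[o]], dtype=float)

    def gamma_matrix(
        self, covariates: Sequence[str], factor_names: Sequence[tuple[str, str]]
    ) -> np.ndarray:
        """Dense (n_covariates, n_factors) coefficient matrix with structural
        zeros where a covariate does not load on a factor."""
        G = np.zeros((len(covariates), len(factor_names)))
        for j, (o, r) in enumerate(factor_names):
            for c, val in self.gamma.get((o, r), {}).items():
                G[list(covariates).index(c), j] = val
        return G

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "alpha": {o: list(v) for o, v in self.alpha.items()},
            "gamma": {f"{o}.{r}": dict(v) for (o, r), v in self.gamma.items()},
            "psi": np.asarray(self.psi).tolist(),
            "theta": dict(self.theta),
            "theta_cross": self.theta_cross,
            "mu_practice": self.mu_practice,
            "psi_practice": self.psi_practice,
            "survival": None
            if self.survival is None
            else {
                "tau": list(self.survival.tau),
                "gamma0": self.survival.gamma0,
                "gamma1": self.survival.gamma1,
                "link": self.survival.link,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GrowthParameters":
        surv = d.get("survival")
        return cls(
            alpha={o: tuple(v) for o, v in d["alpha"].items()},
            gamma={tuple(k.split(".")): dict(v) for k, v in d["gamma"].items()},
            psi=np.asarray(d["psi"], dtype=float),
            theta=dict(d["theta"]),
            theta_cross=float(d.get("theta_cross", 0.0)),
            mu_practice=float(d.get("mu_practice", 0.0)),
            psi_practice=float(d.get("psi_practice", 0.0)),
            survival=None
            if surv is None
            else SurvivalBlock(
                tau=tuple(surv["tau"]),
                gamma0=float(surv["gamma0"]),
                gamma1=float(surv["gamma1"]),
                link=surv.get("link", "logit"),
            ),
        )

    @classmethod
    def from_json(cls, path) -> "GrowthParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class ParameterLayout:
    """Bijection between :class:`GrowthParameters` and an unconstrained
    real vector, with named natural-scale coordinates.

    Natural and unconstrained vectors have the same length; variances are
    optimized on the log scale, the random-effect covariance through its
    Cholesky factor with logged diagonal, and the residual cross-covariance
    through the Fisher z of its correlation.
    """

    def __init__(self, spec: GrowthModelSpec):
        self.spec = spec
        self.outcomes = spec.outcomes
        self.factor_names = spec.factor_names
        self.covariates = spec.all_covariates
        F = spec.n_factors
        C = len(self.covariates)
        self.n_factors = F

        # free-coefficient mask over the dense (C, F) coefficient matrix,
        # plus the explicit (covariate, factor) index of every free entry in
        # the order the parameter names are emitted
        self.free_gamma = np.zeros((C, F), dtype=bool)
        self._beta_idx: list[tuple[int, int]] = []
        for j, (o, r) in enumerate(self.factor_names):
            for c in spec.covariates_for(o, r):
                ci = self.covariates.index(c)
                self.free_gamma[ci, j] = True
                self._beta_idx.append((ci, j))

        def fname(j):
            o, r = self.factor_names[j]
            return f"{o}_{r}"

        names: list[str] = []
        for o, r in self.factor_names:
            names.append(f"alpha.{o}.{r}")
        for j, (o, r) in enumerate(self.factor_names):
            for c in spec.covariates_for(o, r):
                names.append(f"beta.{o}.{r}.{c}")
        self._tril = [(i, j) for i in range(F) for j in range(i + 1)]
        for i, j in self._tril:
            names.append(f"psi.{fname(i)}.{fname(j)}")
        if spec.occasion_residuals:
            for o in self.outcomes:
                names.extend(f"theta.{o}.v{j}" for j in range(spec.n_visits))
        else:
            names.extend(f"theta.{o}" for o in self.outcomes)
        if spec.has_residual_cross:
            names.append("theta_cross")
        if spec.has_practice:
            names.append("mu_practice")
        if spec.practice_variance_free:
            names.append("psi_practice")
        if spec.include_survival:
            names.extend(f"tau.{k}" for k in range(1, spec.n_intervals + 1))
            names.extend(["gamma0", "gamma1"])
        self.names: tuple[str, ...] = tuple(names)
        self.n_params = len(names)

        # slice bookkeeping
        i = 0
        self.sl_alpha = slice(i, i + F); i += F
        n_beta = int(self.free_gamma.sum())
        self.sl_beta = slice(i, i + n_beta); i += n_beta
        n_psi = len(self._tril)
        self.sl_psi = slice(i, i + n_psi); i += n_psi
        K = len(self.outcomes)
        n_theta = K * spec.n_visits if spec.occasion_residuals else K
        self.sl_theta = slice(i, i + n_theta); i += n_theta
        self.i_tcross = i if spec.has_residual_cross else None
        i += spec.has_residual_cross
        self.i_mup = i if spec.has_practice else None
        i += spec.has_practice
        self.i_psip = i if spec.practice_variance_free else None
        i += spec.practice_variance_free
        if spec.include_survival:
            self.sl_tau = slice(i, i + spec.n_intervals); i += spec.n_intervals
            self.i_gamma0, self.i_gamma1 = i, i + 1; i += 2
        assert i == self.n_params

    # -- packing -----------------------------------------------------------
    def pack(self, params: GrowthParameters) -> np.ndarray:
        spec = self.spec
        v = np.zeros(self.n_params)
        v[self.sl_alpha] = params.alpha_vector(self.outcomes)
        G = params.gamma_matrix(self.covariates, self.factor_names)
        v[self.sl_beta] = [G[ci, j] for ci, j in self._beta_idx]
        psi = np.asarray(params.psi, dtype=float)
        L = np.linalg.cholesky(psi + 1e-10 * np.eye(len(psi)))
        chol_vals = np.array([L[i, j] for i, j in self._tril])
        for idx, (i, j) in enumerate(self._tril):
            if i == j:
                chol_vals[idx] = np.log(max(L[i, j], 1e-8))
        v[self.sl_psi] = chol_vals
        if spec.occasion_residuals:
            vals = []
            for o in self.outcomes:
                th = params.theta[o]
                th = [th] * spec.n_visits if np.isscalar(th) else list(th)
                if len(th) != spec.n_visits:
                    raise ValueError(
                        f"theta[{o!r}] needs {spec.n_visits} occasion variances"
                    )
                vals.extend(np.log(th))
            v[self.sl_theta] = vals
        else:
            v[self.sl_theta] = np.log([params.theta[o] for o in self.outcomes])
        if self.i_tcross is not None:
            th = [params.theta[o] for o in self.outcomes]
            rho = params.theta_cross / np.sqrt(th[0] * th[1])
            v[self.i_tcross] = np.arctanh(np.clip(rho, -0.999, 0.999))
        if self.i_mup is not None:
            v[self.i_mup] = params.mu_practice
        if self.i_psip is not None:
            v[self.i_psip] = np.log(max(params.psi_practice, 1e-8))
        if spec.include_survival:
            sb = params.survival
            if sb is None:
                raise ValueError("spec includes survival but params carry no survival block")
            v[self.sl_tau] = np.asarray(sb.tau, dtype=float)
            v[self.i_gamma0] = sb.gamma0
            v[self.i_gamma1] = sb.gamma1
        return v

    def psi_chol(self, v: np.ndarray) -> np.ndarray:
        F = self.n_factors
        L = np.zeros((F, F))
        for val, (i, j) in zip(v[self.sl_psi], self._tril):
            L[i, j] = np.exp(val) if i == j else val
        return L

    def unpack(self, v: np.ndarray) -> GrowthParameters:
        spec = self.spec
        v = np.asarray(v, dtype=float)
        alpha_vec = v[self.sl_alpha]
        alpha = {
            o: (alpha_vec[2 * i], alpha_vec[2 * i + 1]) for i, o in enumerate(self.outcomes)
        }
        G = np.zeros(self.free_gamma.shape, dtype=float)
        for val, (ci, j) in zip(v[self.sl_beta], self._beta_idx):
            G[ci, j] = val
        gamma = {}
        for j, (o, r) in enumerate(self.factor_names):
            covs = spec.covariates_for(o, r)
            gamma[(o, r)] = {c: G[self.covariates.index(c), j] for c in covs}
        L = self.psi_chol(v)
        psi = L @ L.T
        if spec.occasion_residuals:
            tv = np.exp(v[self.sl_theta]).reshape(len(self.outcomes), spec.n_visits)
            theta = {o: [float(x) for x in tv[i]] for i, o in enumerate(self.outcomes)}
        else:
            theta = {
                o: float(np.exp(t)) for o, t in zip(self.outcomes, v[self.sl_theta])
            }
        tcross = 0.0
        if self.i_tcross is not None:
            th = [theta[o] for o in self.outcomes]
            tcross = float(np.tanh(v[self.i_tcross]) * np.sqrt(th[0] * th[1]))
        mu_p = float(v[self.i_mup]) if self.i_mup is not None else 0.0
        psi_p = float(np.exp(v[self.i_psip])) if self.i_psip is not None else 0.0
        survival = None
        if spec.include_survival:
            survival = SurvivalBlock(
                tau=tuple(v[self.sl_tau]),
                gamma0=float(v[self.i_gamma0]),
                gamma1=float(v[self.i_gamma1]),
                link=spec.link,
            )
        return GrowthParameters(
            alpha=alpha,
            gamma=gamma,
            psi=psi,
            theta=theta,
            theta_cross=tcross,
            mu_practice=mu_p,
            psi_practice=psi_p,
            survival=survival,
        )

    # -- natural-scale view --------------------------------------------------
    def natural(self, v: np.ndarray) -> np.ndarray:
        """Natural-scale values in the order of :attr:`names`."""
        p = self.unpack(v)
        out = list(p.alpha_vector(self.outcomes))
        for o, r in self.factor_names:
            out.extend(p.gamma[(o, r)][c] for c in self.spec.covariates_for(o, r))
        out.extend(p.psi[i, j] for i, j in self._tril)
        for o in self.outcomes:
            th = p.theta[o]
            out.extend(th if isinstance(th, (list, tuple)) else [th])
        if self.i_tcross is not None:
            out.append(p.theta_cross)
        if self.i_mup is not None:
            out.append(p.mu_practice)
        if self.i_psip is not None:
            out.append(p.psi_practice)
        if self.spec.include_survival:
            out.extend(p.survival.tau)
            out.extend([p.survival.gamma0, p.survival.gamma1])
        return np.array(out, dtype=float)

    def natural_jacobian(self, v: np.ndarray, step: float = 1e-6) -> np.ndarray:
        """Finite-difference Jacobian of the natural map, used to push the
        covariance of unconstrained estimates to the natural scale."""
        v = np.asarray(v, dtype=float)
        base = self.natural(v)
        J = np.zeros((len(base), len(v)))
        for k in range(len(v)):
            h = step * max(1.0, abs(v[k]))
            vp, vm = v.copy(), v.copy()
            vp[k] += h
            vm[k] -= h
            J[:, k] = (self.natural(vp) - self.natural(vm)) / (2 * h)
        return J

    # -- gradient assembly ---------------------------------------------------
    def assemble_grad(self, v: np.ndarray, blocks: dict) -> np.ndarray:
        """Map natural-block gradients to the unconstrained vector.

        ``blocks`` may contain: ``alpha`` (F,), ``gamma`` dense (C, F),
        ``psi_full`` (F, F) full-matrix derivative, ``psi_chol`` (F, F)
        derivative w.r.t. the Cholesky factor, ``theta`` (K,) on the
        variance scale, ``theta_cross``, ``mu_practice``, ``psi_practice``
        (natural), ``tau`` (n_intervals,), ``gamma0``, ``gamma1``.
        """
        g = np.zeros(self.n_params)
        if "alpha" in blocks:
            g[self.sl_alpha] = blocks["alpha"]
        if "gamma" in blocks:
            Gg = np.asarray(blocks["gamma"])
            g[self.sl_beta] = [Gg[ci, j] for ci, j in self._beta_idx]
        L = self.psi_chol(v)
        gL = np.zeros_like(L)
        if "psi_full" in blocks:
            gL += 2.0 * (np.asarray(blocks["psi_full"]) @ L)
        if "psi_chol" in blocks:
            gL += np.asarray(blocks["psi_chol"])
        vals = []
        for i, j in self._tril:
            vals.append(gL[i, j] * (L[i, i] if i == j else 1.0))
        g[self.sl_psi] = vals

        theta = np.exp(np.asarray(v[self.sl_theta], dtype=float))
        K = len(self.outcomes)
        n_visits = self.spec.n_visits
        g_th = np.asarray(
            blocks.get("theta", np.zeros((K, n_visits))), dtype=float
        )  # (K, n_visits) accumulated per outcome and occasion
        g_tc = float(blocks.get("theta_cross", 0.0))
        if self.spec.occasion_residuals:
            g[self.sl_theta] = theta * g_th.ravel()
        else:
            g[self.sl_theta] = theta * g_th.sum(axis=1)
        if self.i_tcross is not None:
            z = v[self.i_tcross]
            rho = np.tanh(z)
            root = np.sqrt(theta[0] * theta[1])
            tcross = rho * root
            # theta_cross moves with the log-variances at fixed correlation
            g[self.sl_theta] += 0.5 * tcross * g_tc
            g[self.i_tcross] = g_tc * root * (1.0 - rho**2)
        if self.i_mup is not None:
            g[self.i_mup] = float(blocks.get("mu_practice", 0.0))
        if self.i_psip is not None:
            g[self.i_psip] = float(blocks.get("psi_practice", 0.0)) * np.exp(v[self.i_psip])
        if self.spec.include_survival:
            g[self.sl_tau] = blocks.get("tau", np.zeros(self.spec.n_intervals))
            g[self.i_gamma0] = float(blocks.get("gamma0", 0.0))
            g[self.i_gamma1] = float(blocks.get("gamma1", 0.0))
        return g


@dataclass
class FitResult:
    """Maximum-likelihood estimates with their sampling covariance.

    ``estimates``/``vcov`` are on the natural scale in the order of
    ``names``; ``uvec`` retains the unconstrained optimum so that fits can
    be resumed or re-evaluated.
    """

    names: tuple[str, ...]
    estimates: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_subjects: int
    converged: bool
    n_iterations: int
    gradient_norm: float
    params: GrowthParameters
    spec: GrowthModelSpec
    uvec: np.ndarray
    group_label: str | None = None

    def estimate(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def se(self, name: str) -> float:
        i = self.names.index(name)
        return float(np.sqrt(max(self.vcov[i, i], 0.0)))

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        e, s = self.estimate(name), self.se(name)
        return (e - z * s, e + z * s)

    def summary(self) -> "pd.DataFrame":  # noqa: F821 (lazy import)
        import pandas as pd
        from scipy.stats import norm

        se = np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))
        z = np.divide(self.estimates, se, out=np.full_like(se, np.nan), where=se > 0)
        return pd.DataFrame(
            {
                "parameter": list(self.names),
                "estimate": self.estimates,
                "se": se,
                "ci_low": self.estimates - 1.959963984540054 * se,
                "ci_high": self.estimates + 1.959963984540054 * se,
                "p_value": 2 * norm.sf(np.abs(z)),
            }
        )

    def to_json(self, path) -> None:
        payload = {
            "names": list(self.names),
            "estimates": self.estimates.tolist(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "gradient_norm": self.gradient_norm,
            "group_label": self.group_label,
            "spec": self.spec.to_dict(),
            "params": self.params.to_dict(),
            "uvec": self.uvec.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            names=tuple(d["names"]),
            estimates=np.asarray(d["estimates"], dtype=float),
            vcov=np.asarray(d["vcov"], dtype=float),
            loglik=float(d["loglik"]),
            n_subjects=int(d["n_subjects"]),
            converged=bool(d["converged"]),
            n_iterations=int(d["n_iterations"]),
            gradient_norm=float(d["gradient_norm"]),
            params=GrowthParameters.from_dict(d["params"]),
            spec=GrowthModelSpec.from_dict(d["spec"]),
            uvec=np.asarray(d["uvec"], dtype=float),
            group_label=d.get("group_label"),
        )
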