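"""Wald tests for equality of parameters, within and across groups.

A contrast is a linear map ``L`` over a (possibly group-stacked) estimate
vector; the Wald statistic is ``(L b)' (L V L')^{-1} (L b)`` with
chi-square reference on ``rank(L)`` degrees of freedom.  Rank-one
contrasts additionally report the signed estimate with a delta-method 95%
confidence interval -- the "difference [CI]" presentation used for the
memory-versus-brain rate difference (delta-B) and its group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import block_diag
from scipy.stats import chi2, norm

from .model import FitResult


@dataclass
class WaldResult:
    contrast: np.ndarray
    estimate: float | None    # signed value of the contrast (rank-1 only)
    statistic: float
    df: int
    p_value: float
    ci_95: tuple[float, float] | None
    se: float | None = None

    def __repr__(self):
        est = "" if self.estimate is None else f" estimate={self.estimate:.4g}"
        return (
            f"WaldResult(statistic={self.statistic:.4g}, df={self.df}, "
            f"p={self.p_value:.4g}{est})"
        )


def stack_fits(fits: list[FitResult]) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    """Stack group fits into one named estimate vector with block-diagonal
    covariance (groups are independent samples)."""
    names: list[str] = []
    for f in fits:
        prefix = f"{f.group_label}:" if f.group_label is not None else ""
        names.extend(prefix + n for n in f.names)
    est = np.concatenate([f.estimates for f in fits])
    vcov = block_diag(*[f.vcov for f in fits])
    return tuple(names), est, vcov


def _as_matrix(contrast, names: tuple[str, ...]) -> np.ndarray:
    """Accept a dict {name: weight}, a list of dicts, or a raw matrix."""
    if isinstance(contrast, dict):
        contrast = [contrast]
    if isinstance(contrast, (list, tuple)) and contrast and isinstance(contrast[0], dict):
        L = np.zeros((len(contrast), len(names)))
        for i, row in enumerate(contrast):
            for name, w in row.items():
                if name not in names:
                    raise KeyError(f"unknown parameter {name!r} in contrast")
                L[i, names.index(name)] = w
        return L
    L = np.atleast_2d(np.asarray(contrast, dtype=float))
    if L.shape[1] != len(names):
        raise ValueError(
            f"contrast has {L.shape[1]} columns but the estimate vector has "
            f"{len(names)} entries"
        )
    return L


def wald_test(fits, contrast) -> WaldResult:
    """Wald test of ``L theta = 0``.

    ``fits`` is a single :class:`FitResult` or a list of group fits (then
    contrast names are prefixed ``"<group>:"``); ``contrast`` is a dict
    mapping parameter names to weights, a list of such dicts (one per
    row), or a raw matrix.
    """
    if isinstance(fits, FitResult):
        fits = [fits]
    names, est, vcov = stack_fits(fits)
    L = _as_matrix(contrast, names)
    if not np.any(L):
        # e.g. a parameter contrasted with itself: L theta is identically 0
        return WaldResult(
            contrast=L, estimate=0.0 if L.shape[0] == 1 else None,
            statistic=0.0, df=0, p_value=1.0, ci_95=None, se=None,
        )
    Lb = L @ est
    LVL = L @ vcov @ L.T
    df = int(np.linalg.matrix_rank(LVL, tol=1e-12 * max(np.abs(LVL).max(), 1e-300)))
    if df < L.shape[0]:
        raise ValueError(
            "singular contrast covariance: rows "
            f"{list(range(L.shape[0]))} of the contrast are redundant "
            f"(rank {df} < {L.shape[0]})"
        )
    stat = float(Lb @ np.linalg.solve(LVL, Lb))
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    estimate = se = ci = None
    if L.shape[0] == 1:
        estimate = float(Lb[0])
        se = float(np.sqrt(max(LVL[0, 0], 0.0)))
        zcrit = norm.ppf(0.975)
        ci = (estimate - zcrit * se, estimate + zcrit * se)
    return WaldResult(
        contrast=L, estimate=estimate, statistic=stat, df=df, p_value=p,
        ci_95=ci, se=se,
    )


def _slope_name(outcome: str) -> str:
    return f"alpha.{outcome}.slope"


def _slope_cov_name(outcomes) -> str:
    return f"psi.{outcomes[1]}_slope.{outcomes[0]}_slope"


def standard_contrasts(fits) -> dict[str, dict[str, float]]:
    """The standard comparison set for fitted growth models.

    For a single bivariate fit: the memory-minus-brain rate difference
    (``delta_b``).  For multiple-group bivariate fits with groups low/mid/
    high: ``delta_b`` within each group, and pairwise group differences in
    the memory slope, the brain slope, ``delta_b``, and the slope
    covariance.  Univariate fits only get slope and intercept contrasts.
    """
    single = isinstance(fits, FitResult)
    flist = [fits] if single else list(fits)
    outcomes = flist[0].spec.outcomes
    bivariate = len(outcomes) == 2
    out: dict[str, dict[str, float]] = {}

    def pref(f):
        # must mirror the naming rule of stack_fits
        return f"{f.group_label}:" if f.group_label is not None else ""

    for f in flist:
        p = pref(f)
        label = f.group_label if f.group_label is not None else "overall"
        if bivariate:
            out[f"delta_b[{label}]"] = {
                p + _slope_name(outcomes[0]): 1.0,
                p + _slope_name(outcomes[1]): -1.0,
            }
        else:
            o = outcomes[0]
            out[f"{o}_intercept[{label}]"] = {p + f"alpha.{o}.intercept": 1.0}
            out[f"{o}_slope[{label}]"] = {p + _slope_name(o): 1.0}
    if len(flist) > 1:
        pairs = [
            (a, b) for i, a in enumerate(flist) for b in flist[i + 1 :]
        ]
        for fa, fb in pairs:
            la, lb = fa.group_label, fb.group_label
            for o in outcomes:
                out[f"{o}_slope[{la} vs {lb}]"] = {
                    pref(fa) + _slope_name(o): 1.0,
                    pref(fb) + _slope_name(o): -1.0,
                }
            if bivariate:
                out[f"delta_b[{la} vs {lb}]"] = {
                    pref(fa) + _slope_name(outcomes[0]): 1.0,
                    pref(fa) + _slope_name(outcomes[1]): -1.0,
                    pref(fb) + _slope_name(outcomes[0]): -1.0,
                    pref(fb) + _slope_name(outcomes[1]): 1.0,
                }
                cov_name = _slope_cov_name(outcomes)
                out[f"slope_cov[{la} vs {lb}]"] = {
                    pref(fa) + cov_name: 1.0,
                    pref(fb) + cov_name: -1.0,
                }
    return out


def run_standard_contrasts(fits) -> dict[str, WaldResult]:
    """Evaluate :func:`standard_contrasts` on the fits."""
    contrasts = standard_contrasts(fits)
    flist = [fits] if isinstance(fits, FitResult) else list(fits)
    return {name: wald_test(flist, c) for name, c in contrasts.items()}
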