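"""Derived-variable construction: memory composite, brain parenchymal
fraction, baseline standardization, age grouping, tertiles, education
categories, and covariate centering.

All standardizations are *baseline-referenced*: means and SDs are computed
once from the baseline rows of the analysis sample, frozen in a
:class:`StandardizationReference`, and applied unchanged to every later
wave.  SDs are population SDs (``ddof=0``).  ICV is standardized
separately within men and within women because of the systematic sex
difference in head size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import COL_VISIT

#: the three memory tests entering the composite
MEMORY_TESTS = ("wlt_total_recall", "wlt_delayed_recall", "rey_delayed_recall")

#: fixed tertile boundaries for the reserve proxies, written as
#: (lower, upper] intervals except the first bin, which includes its lower
#: edge.  DART is on the raw score scale; ICV and BPF on the baseline
#: z-score scale.
FIXED_TERTILES: dict[str, tuple[tuple[float, float], ...]] = {
    "dart": ((35.0, 75.0), (75.0, 89.0), (89.0, 100.0)),
    "icv": ((-2.66, -0.46), (-0.46, 0.40), (0.40, 3.29)),
    "bpf": ((-3.65, -0.37), (-0.37, 0.51), (0.51, 2.91)),
}

TERTILE_LABELS = ("low", "mid", "high")

#: 7-level Dutch education scale collapsed to three categories
EDUCATION_CATEGORIES = {
    1: "less than high school",
    2: "less than high school",
    3: "high school",
    4: "high school",
    5: "high school",
    6: "college/university",
    7: "college/university",
}


@dataclass
class StandardizationReference:
    """Frozen baseline means/SDs used for every standardization.

    ``means``/``sds`` hold per-variable baseline moments (including the
    moments of the averaged memory z-scores under the key
    ``memory_composite_raw``); ``icv_by_sex`` holds sex-specific ICV
    moments keyed by the sex code.
    """

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    icv_by_sex: dict = field(default_factory=dict)

    def add(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        sd = float(values.std(ddof=0))
        if sd <= 0:
            raise ValueError(f"zero baseline SD for {name!r}; cannot standardize")
        self.means[name] = float(values.mean())
        self.sds[name] = sd

    def zscore(self, name: str, values) -> np.ndarray:
        if name not in self.means:
            raise KeyError(f"no baseline reference for {name!r}")
        return (np.asarray(values, dtype=float) - self.means[name]) / self.sds[name]

    def unstandardize(self, name: str, z) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sds[name] + self.means[name]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "means": self.means,
                    "sds": self.sds,
                    "icv_by_sex": {str(k): list(v) for k, v in self.icv_by_sex.items()},
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "StandardizationReference":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            means=d["means"],
            sds=d["sds"],
            icv_by_sex={int(k): tuple(v) for k, v in d["icv_by_sex"].items()},
        )


def _baseline_rows(df: pd.DataFrame) -> pd.DataFrame:
    if COL_VISIT not in df.columns:
        raise ValueError(f"table needs a {COL_VISIT!r} column to locate baseline rows")
    base = df[df[COL_VISIT] == 0]
    if base.empty:
        raise ValueError("no baseline rows (visit_order == 0) to compute references")
    return base


def memory_composite(
    raw: pd.DataFrame,
    ref: StandardizationReference | None = None,
    tests: tuple[str, ...] = MEMORY_TESTS,
    min_components: int = 2,
) -> tuple[pd.Series, StandardizationReference]:
    """Standardized memory composite per visit row.

    Each test is z-scored against the baseline mean/SD of the analysis
    sample, the available z-scores are averaged (a row needs at least
    ``min_components`` observed tests, otherwise its composite is missing),
    and the average is re-standardized against the baseline mean/SD of the
    averaged score, so the baseline composite has mean 0 and SD 1 by
    construction.
    """
    if ref is None:
        ref = StandardizationReference()
    if "memory_composite_raw" not in ref.means:
        base = _baseline_rows(raw)
        for t in tests:
            ref.add(t, base[t].to_numpy())
        zs = np.column_stack([ref.zscore(t, base[t]) for t in tests])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            avg = np.nanmean(np.where(np.isfinite(zs), zs, np.nan), axis=1)
        n_obs = np.isfinite(zs).sum(axis=1)
        avg = np.where(n_obs >= min_components, avg, np.nan)
        ref.add("memory_composite_raw", avg)

    zs = np.column_stack([ref.zscore(t, raw[t]) for t in tests])
    n_obs = np.isfinite(zs).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(np.where(np.isfinite(zs), zs, np.nan), axis=1)
    avg = np.where(n_obs >= min_components, avg, np.nan)
    composite = ref.zscore("memory_composite_raw", avg)
    return pd.Series(composite, index=raw.index, name="memory"), ref


def compute_bpf(brain_volume_ml, icv_ml) -> np.ndarray:
    """Brain parenchymal fraction: total brain volume / intracranial volume."""
    brain = np.asarray(brain_volume_ml, dtype=float)
    icv = np.asarray(icv_ml, dtype=float)
    if np.any(brain <= 0) or np.any(icv <= 0):
        raise ValueError("brain and intracranial volumes must be positive")
    if np.any(icv < brain):
        raise ValueError("intracranial volume must be at least the brain volume")
    return brain / icv


def standardize_bpf(
    bpf: pd.Series | np.ndarray,
    ref: StandardizationReference | None = None,
    baseline_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, StandardizationReference]:
    """Standardize BPF (fraction scale) against its baseline mean/SD.

    If no reference is supplied, ``baseline_mask`` selects the rows whose
    moments define it.
    """
    values = np.asarray(bpf, dtype=float)
    if ref is None:
        ref = StandardizationReference()
    if "bpf" not in ref.means:
        if baseline_mask is None:
            raise ValueError("need a reference or a baseline_mask to build one")
        ref.add("bpf", values[np.asarray(baseline_mask, dtype=bool)])
    return ref.zscore("bpf", values), ref


def standardize_icv_by_sex(
    icv_ml, sex, ref: StandardizationReference | None = None
) -> tuple[np.ndarray, StandardizationReference]:
    """Sex-stratified ICV z-scores: each subject is standardized against the
    mean/SD of their own sex in the reference sample."""
    icv = np.asarray(icv_ml, dtype=float)
    sex = np.asarray(sex)
    if ref is None or not ref.icv_by_sex:
        ref = ref or StandardizationReference()
        for s in np.unique(sex):
            vals = icv[sex == s]
            if len(vals) < 2:
                raise ValueError(
                    f"sex stratum {s!r} has fewer than 2 subjects; SD undefined"
                )
            sd = float(vals.std(ddof=0))
            if sd <= 0:
                raise ValueError(f"zero ICV SD within sex stratum {s!r}")
            ref.icv_by_sex[s] = (float(vals.mean()), sd)
    z = np.empty_like(icv)
    for s, (m, sd) in ref.icv_by_sex.items():
        z[sex == s] = (icv[sex == s] - m) / sd
    return z, ref


def assign_age_group(baseline_age, time_in_study) -> np.ndarray:
    """Mid-life vs late-life by the age at the middle of a subject's time in
    the study; a midpoint age of exactly 60 counts as late-life."""
    age = np.asarray(baseline_age, dtype=float)
    t = np.asarray(time_in_study, dtype=float)
    if np.any(age <= 0):
        raise ValueError("baseline_age must be positive")
    if np.any(t < 0):
        raise ValueError("time_in_study must be non-negative")
    midpoint = age + t / 2.0
    return np.where(midpoint >= 60.0, "late-life", "mid-life")


def assign_tertile(
    value, measure: str, boundaries: tuple[tuple[float, float], ...] | None = None
) -> np.ndarray | str:
    """Low/mid/high tertile of a reserve proxy.

    With no explicit ``boundaries``, the fixed boundaries for the measure
    (``dart``, ``icv``, ``bpf``) are used; bins are (lower, upper] except
    the first, which includes its lower edge.  Values outside every bin
    are rejected.
    """
    if boundaries is None:
        if measure not in FIXED_TERTILES:
            raise ValueError(
                f"no fixed boundaries for measure {measure!r}; supply boundaries"
            )
        boundaries = FIXED_TERTILES[measure]
    scalar = np.isscalar(value)
    vals = np.atleast_1d(np.asarray(value, dtype=float))
    out = np.empty(vals.shape, dtype=object)
    out[:] = None
    for label, (lo, hi) in zip(TERTILE_LABELS, boundaries):
        first = label == TERTILE_LABELS[0]
        inside = (vals > lo) & (vals <= hi) | (first & (vals == lo))
        out[inside] = label
    if any(v is None for v in out.ravel()):
        bad = vals[np.array([v is None for v in out.ravel()]).reshape(vals.shape)]
        raise ValueError(
            f"value(s) {bad.tolist()} outside the {measure!r} tertile bins {boundaries}"
        )
    out = out.astype(str)
    return out.item() if scalar else out


def data_driven_tertiles(values) -> tuple[tuple[float, float], ...]:
    """Empirical tertile boundaries (lower-open/upper-closed) from data."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    q1, q2 = np.quantile(vals, [1 / 3, 2 / 3])
    return ((vals.min(), q1), (q1, q2), (q2, vals.max()))


def categorize_education(level) -> np.ndarray | str:
    """Collapse the seven ordered education levels to three categories:
    levels 1-2 'less than high school', 3-5 'high school', 6-7
    'college/university'."""
    scalar = np.isscalar(level)
    levels = np.atleast_1d(np.asarray(level))
    out = []
    for lv in levels.ravel():
        lv = int(lv)
        if lv not in EDUCATION_CATEGORIES:
            raise ValueError(f"education level {lv} outside 1..7")
        out.append(EDUCATION_CATEGORIES[lv])
    res = np.array(out, dtype=object).reshape(levels.shape).astype(str)
    return res.item() if scalar else res


def derive_long_table(
    raw: pd.DataFrame, ref: StandardizationReference | None = None
) -> tuple[pd.DataFrame, StandardizationReference]:
    """Derive analysis variables from a raw visit table.

    Expects the raw memory test scores, ``brain_volume_ml``/``icv_ml``, and
    ``sex``.  Produces the standardized memory composite, standardized BPF,
    and sex-standardized ICV, using (or building) a baseline
    :class:`StandardizationReference` so that fitted references can be
    re-applied to new data.
    """
    out = raw.copy()
    if ref is None:
        ref = StandardizationReference()
    composite, ref = memory_composite(out, ref=ref)
    out["memory"] = composite
    if "brain_volume_ml" in out.columns and "icv_ml" in out.columns:
        bpf = compute_bpf(out["brain_volume_ml"], out["icv_ml"])
        base_mask = (out[COL_VISIT] == 0).to_numpy()
        z, ref = standardize_bpf(bpf, ref=ref, baseline_mask=base_mask)
        out["brain_bpf"] = z
        if not ref.icv_by_sex:
            base = _baseline_rows(out)
            _, ref = standardize_icv_by_sex(
                base["icv_ml"].to_numpy(), base["sex"].to_numpy(), ref
            )
        icv_z, _ = standardize_icv_by_sex(out["icv_ml"], out["sex"], ref)
        out["icv_z"] = icv_z
    return out, ref


def center_covariates(
    table: pd.DataFrame, covariates: list[str] | tuple[str, ...]
) -> pd.DataFrame:
    """Center the listed covariates on the analysis sample (mean 0).

    Constant covariates trigger a warning and end up identically 0.
    Centering an already-centered column is a no-op.
    """
    out = table.copy()
    for c in covariates:
        col = out[c].astype(float)
        if col.std(ddof=0) == 0:
            warnings.warn(f"covariate {c!r} is constant; centered to 0", stacklevel=2)
        out[c] = col - col.mean()
    return out
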