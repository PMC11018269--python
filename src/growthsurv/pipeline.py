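"""End-to-end analysis pipeline on any conforming long-format cohort.

The full design is: preprocess the cohort (standardized reserve
determinants, centered adjustment covariates, age groups, tertiles), fit
univariate memory growth models per reserve proxy and age stratum with the
reserve measure as a determinant of the intercept and slope, fit the
bivariate memory-brain model, fit multiple-group bivariate models over
reserve tertiles, and run the standard Wald comparison set.  Age
stratification applies only to the univariate models; the multiple-group
tertile models run on the whole sample, reflecting the sample-size
constraint of splitting by both age and reserve group.

Every stage persists its outputs (CSV/JSON; figures as SVG and PNG) under
the configured output directory together with a manifest recording the
seed, a hash of the configuration, and the package version, so a run can
be resumed from its completed stages and every reported number is
traceable to a stored fit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _pkg_version
from .cohort import COL_BRAIN, COL_MEMORY, COL_SUBJECT, COL_TIME, COL_VISIT, read_cohort, write_cohort
from .fitting import fit, multiple_group_fit
from .model import FitResult, GrowthModelSpec
from .preprocess import (
    FIXED_TERTILES,
    assign_age_group,
    assign_tertile,
    categorize_education,
    data_driven_tertiles,
)
from .scenario import SimulationScenario, default_scenario, scenario_from_dict, scenario_to_dict
from .simulate import simulate_cohort
from .survival import QuadratureRule
from .wald import run_standard_contrasts

PROXIES = ("dart", "education", "icv", "bpf")


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run."""

    scenario: SimulationScenario | None = None
    input_path: str | None = None
    proxies: tuple[str, ...] = PROXIES
    strata: tuple[str, ...] = ("overall", "mid-life", "late-life")
    tertile_mode: str = "fixed"        # or "data"
    include_survival: bool = True
    n_quadrature: int = 9
    link: str = "logit"
    min_group_size: int = 30
    run_univariate: bool = True
    run_bivariate: bool = True
    run_multigroup: bool = True
    make_figures: bool = True
    seed: int = 0
    outdir: str | None = None
    resume: bool = False

    def __post_init__(self):
        if self.scenario is None and self.input_path is None:
            self.scenario = default_scenario(seed=self.seed)
        if not self.proxies or not self.strata:
            raise ValueError("select at least one reserve proxy and one stratum")
        unknown = set(self.proxies) - set(PROXIES)
        if unknown:
            raise ValueError(f"unknown proxies {sorted(unknown)}; choose from {PROXIES}")

    def to_dict(self) -> dict:
        d = {
            "scenario": None if self.scenario is None else scenario_to_dict(self.scenario),
            "input_path": self.input_path,
            "proxies": list(self.proxies),
            "strata": list(self.strata),
            "tertile_mode": self.tertile_mode,
            "include_survival": self.include_survival,
            "n_quadrature": self.n_quadrature,
            "link": self.link,
            "min_group_size": self.min_group_size,
            "run_univariate": self.run_univariate,
            "run_bivariate": self.run_bivariate,
            "run_multigroup": self.run_multigroup,
            "make_figures": self.make_figures,
            "seed": self.seed,
        }
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        scenario = d.pop("scenario", None)
        if scenario is not None:
            scenario = scenario_from_dict(scenario)
        for key in ("proxies", "strata"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(scenario=scenario, **d)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _zscore_sample(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=0)
    if sd == 0:
        raise ValueError(f"column {s.name!r} is constant; cannot standardize")
    return (s - s.mean()) / sd


def preprocess_cohort(df: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Attach analysis columns: per-subject age group, standardized reserve
    determinants, centered adjustment covariates, and tertile groups."""
    out = df.copy()
    base = out[out[COL_VISIT] == 0].set_index(COL_SUBJECT)
    last_time = out.groupby(COL_SUBJECT)[COL_TIME].max()
    age_group = pd.Series(
        assign_age_group(base["baseline_age"].to_numpy(), last_time.reindex(base.index).to_numpy()),
        index=base.index,
        name="age_group",
    )
    out = out.merge(age_group, left_on=COL_SUBJECT, right_index=True)

    # centered adjustment covariates (analysis-sample means)
    for col, centered in (
        ("baseline_age", "age_cs"),
        ("sex", "sex_cs"),
        ("stroke_history", "stroke_cs"),
    ):
        means = base[col].mean()
        out[centered] = out[col] - means

    # continuous standardized reserve determinants (baseline-subject sample)
    det = {}
    if "dart" in config.proxies:
        det["dart_std"] = _zscore_sample(base["dart"])
    if "education" in config.proxies:
        det["education_std"] = _zscore_sample(base["education_level"].astype(float))
    if "icv" in config.proxies:
        icv_col = "icv_z" if "icv_z" in base.columns else "icv"
        det["icv_std"] = _zscore_sample(base[icv_col].astype(float))
    if "bpf" in config.proxies:
        det["bpf_std"] = _zscore_sample(base[COL_BRAIN].astype(float))
    for name, series in det.items():
        out = out.merge(series.rename(name), left_on=COL_SUBJECT, right_index=True)

    # tertile groups
    def fixed_or_data(values, measure):
        if config.tertile_mode == "fixed":
            lo = min(values.min(), FIXED_TERTILES[measure][0][0])
            hi = max(values.max(), FIXED_TERTILES[measure][-1][1])
            bounds = FIXED_TERTILES[measure]
            widened = ((lo, bounds[0][1]), bounds[1], (bounds[2][0], hi))
            return assign_tertile(values.to_numpy(), measure, boundaries=widened)
        return assign_tertile(
            values.to_numpy(), measure, boundaries=data_driven_tertiles(values)
        )

    if "dart" in config.proxies:
        grp = pd.Series(fixed_or_data(base["dart"], "dart"), index=base.index, name="dart_group")
        out = out.merge(grp, left_on=COL_SUBJECT, right_index=True)
    if "education" in config.proxies:
        cats = categorize_education(base["education_level"].to_numpy())
        order = {"less than high school": "low", "high school": "mid", "college/university": "high"}
        grp = pd.Series([order[c] for c in cats], index=base.index, name="education_group")
        out = out.merge(grp, left_on=COL_SUBJECT, right_index=True)
    if "icv" in config.proxies:
        icv_col = "icv_z" if "icv_z" in base.columns else "icv_std"
        vals = base[icv_col] if icv_col in base.columns else det["icv_std"]
        grp = pd.Series(fixed_or_data(vals, "icv"), index=base.index, name="icv_group")
        out = out.merge(grp, left_on=COL_SUBJECT, right_index=True)
    if "bpf" in config.proxies:
        grp = pd.Series(fixed_or_data(base[COL_BRAIN], "bpf"), index=base.index, name="bpf_group")
        out = out.merge(grp, left_on=COL_SUBJECT, right_index=True)
    return out


def _univariate_spec(proxy: str, config: AnalysisConfig) -> GrowthModelSpec:
    det = f"{proxy}_std"
    return GrowthModelSpec(
        outcomes=(COL_MEMORY,),
        intercept_covariates={COL_MEMORY: (det, "age_cs", "sex_cs", "stroke_cs")},
        slope_covariates={COL_MEMORY: (det,)},
        include_survival=config.include_survival,
        link=config.link,
    )


def _bivariate_spec(config: AnalysisConfig) -> GrowthModelSpec:
    adj = ("age_cs", "sex_cs", "stroke_cs")
    return GrowthModelSpec(
        outcomes=(COL_MEMORY, COL_BRAIN),
        intercept_covariates={COL_MEMORY: adj, COL_BRAIN: adj},
        slope_covariates={},
        include_survival=config.include_survival,
        link=config.link,
    )


def _stratum_data(df: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "overall":
        return df
    return df[df["age_group"] == stratum]


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis design; returns the report bundle and, when an
    output directory is configured, persists every artifact there."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "package_version": _pkg_version,
        "config": config.to_dict(),
        "stages": {},
    }
    rule = QuadratureRule(n_points=config.n_quadrature, adaptive=False)
    bundle: dict = {"manifest": manifest}

    # stage: data ------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        cohort_path = outdir / "cohort.csv" if outdir else None
        truth = None
        if (
            config.resume
            and cohort_path is not None
            and cohort_path.exists()
            and (outdir / "manifest.json").exists()
            and json.loads((outdir / "manifest.json").read_text()).get("config_hash")
            == manifest["config_hash"]
        ):
            df = read_cohort(cohort_path)
        elif config.input_path is not None:
            df = read_cohort(config.input_path)
        else:
            scenario = config.scenario
            if scenario.seed is None:
                from dataclasses import replace

                scenario = replace(scenario, seed=config.seed)
            df, truth = simulate_cohort(scenario)
            if outdir:
                write_cohort(df, cohort_path)
                truth.to_json(outdir / "ground_truth.json")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("data", e) from e
    manifest["stages"]["data"] = {"seconds": time.perf_counter() - t0, "n_rows": len(df)}
    bundle["cohort"] = df
    bundle["ground_truth"] = truth

    # stage: preprocess -------------------------------------------------------
    t0 = time.perf_counter()
    try:
        data = preprocess_cohort(df, config)
        if outdir:
            data.to_csv(outdir / "analysis_table.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("preprocess", e) from e
    manifest["stages"]["preprocess"] = {"seconds": time.perf_counter() - t0}
    bundle["analysis_table"] = data

    # stage: univariate reserve models ---------------------------------------
    if config.run_univariate:
        t0 = time.perf_counter()
        rows = []
        uni_fits: dict[tuple[str, str], FitResult] = {}
        try:
            for proxy in config.proxies:
                spec = _univariate_spec(proxy, config)
                for stratum in config.strata:
                    sub = _stratum_data(data, stratum)
                    if sub[COL_SUBJECT].nunique() < config.min_group_size:
                        continue
                    f = fit(sub, spec, rule=rule, group_label=f"{proxy}/{stratum}")
                    uni_fits[(proxy, stratum)] = f
                    det = f"{proxy}_std"
                    for role in ("intercept", "slope"):
                        name = f"beta.{COL_MEMORY}.{role}.{det}"
                        lo, hi = f.ci(name)
                        est, se = f.estimate(name), f.se(name)
                        from scipy.stats import norm as _norm

                        rows.append(
                            {
                                "proxy": proxy,
                                "stratum": stratum,
                                "factor": role,
                                "estimate": est,
                                "se": se,
                                "ci_low": lo,
                                "ci_high": hi,
                                "p_value": float(2 * _norm.sf(abs(est / se)))
                                if se > 0
                                else float("nan"),
                                "converged": f.converged,
                                "n_subjects": f.n_subjects,
                            }
                        )
                    if outdir:
                        f.to_json(outdir / f"fit_univariate_{proxy}_{stratum}.json")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("univariate", e) from e
        table2 = pd.DataFrame(rows)
        if outdir:
            table2.to_csv(outdir / "univariate_effects.csv", index=False)
        manifest["stages"]["univariate"] = {
            "seconds": time.perf_counter() - t0,
            "n_models": len(uni_fits),
        }
        bundle["univariate"] = table2
        bundle["univariate_fits"] = uni_fits

    # stage: bivariate joint model --------------------------------------------
    if config.run_bivariate:
        t0 = time.perf_counter()
        try:
            spec = _bivariate_spec(config)
            f = fit(data, spec, rule=rule, group_label="overall")
            wald = run_standard_contrasts(f)
            bundle["bivariate_fit"] = f
            bundle["bivariate_wald"] = wald
            if outdir:
                f.to_json(outdir / "fit_bivariate_overall.json")
                _wald_to_csv(wald, outdir / "bivariate_contrasts.csv")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("bivariate", e) from e
        manifest["stages"]["bivariate"] = {"seconds": time.perf_counter() - t0}

    # stage: multiple-group tertile models -------------------------------------
    if config.run_multigroup:
        t0 = time.perf_counter()
        multi = {}
        try:
            spec = _bivariate_spec(config)
            for proxy in config.proxies:
                col = f"{proxy}_group"
                fits = multiple_group_fit(
                    data, spec, grouping=col, min_group_size=config.min_group_size,
                    rule=rule,
                )
                wald = run_standard_contrasts(fits)
                multi[proxy] = {"fits": fits, "wald": wald}
                if outdir:
                    for f in fits:
                        f.to_json(outdir / f"fit_multigroup_{proxy}_{f.group_label}.json")
                    _wald_to_csv(wald, outdir / f"multigroup_contrasts_{proxy}.csv")
                    _slope_table(fits).to_csv(
                        outdir / f"multigroup_slopes_{proxy}.csv", index=False
                    )
        except Exception as e:  # noqa: BLE001
            raise PipelineError("multigroup", e) from e
        manifest["stages"]["multigroup"] = {"seconds": time.perf_counter() - t0}
        bundle["multigroup"] = multi

    # stage: figures -----------------------------------------------------------
    if config.make_figures and outdir and config.run_univariate:
        t0 = time.perf_counter()
        try:
            _trajectory_figures(bundle.get("univariate_fits", {}), config, outdir)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("figures", e) from e
        manifest["stages"]["figures"] = {"seconds": time.perf_counter() - t0}

    if outdir:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return bundle


def _wald_to_csv(wald: dict, path) -> None:
    rows = []
    for name, w in wald.items():
        rows.append(
            {
                "contrast": name,
                "estimate": w.estimate,
                "se": w.se,
                "ci_low": None if w.ci_95 is None else w.ci_95[0],
                "ci_high": None if w.ci_95 is None else w.ci_95[1],
                "statistic": w.statistic,
                "df": w.df,
                "p_value": w.p_value,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def _slope_table(fits: list[FitResult]) -> pd.DataFrame:
    rows = []
    for f in fits:
        for o in f.spec.outcomes:
            name = f"alpha.{o}.slope"
            lo, hi = f.ci(name)
            rows.append(
                {
                    "group": f.group_label,
                    "outcome": o,
                    "slope": f.estimate(name),
                    "ci_low": lo,
                    "ci_high": hi,
                    "n_subjects": f.n_subjects,
                }
            )
    return pd.DataFrame(rows)


def _trajectory_figures(uni_fits: dict, config: AnalysisConfig, outdir: Path) -> None:
    """Model-implied memory trajectories at +/-1 SD of each reserve proxy
    (high vs low reserve), from the overall univariate fits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for proxy in config.proxies:
        f = uni_fits.get((proxy, "overall"))
        if f is None:
            continue
        det = f"{proxy}_std"
        a0 = f.estimate(f"alpha.{COL_MEMORY}.intercept")
        a1 = f.estimate(f"alpha.{COL_MEMORY}.slope")
        b0 = f.estimate(f"beta.{COL_MEMORY}.intercept.{det}")
        b1 = f.estimate(f"beta.{COL_MEMORY}.slope.{det}")
        t = np.linspace(0, 12, 50)
        figure, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(t, (a0 + b0) + (a1 + b1) * t, label=f"high {proxy} (+1 SD)")
        ax.plot(t, (a0 - b0) + (a1 - b1) * t, label=f"low {proxy} (-1 SD)", linestyle="--")
        ax.set_xlabel("time in study (years)")
        ax.set_ylabel("memory (standardized)")
        ax.set_title(f"Memory trajectory by {proxy}")
        ax.legend(frameon=False)
        figure.tight_layout()
        figure.savefig(outdir / f"trajectory_{proxy}.svg")
        figure.savefig(outdir / f"trajectory_{proxy}.png", dpi=150)
        plt.close(figure)
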