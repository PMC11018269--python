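"""Computational design: per-subject observation structure and
pattern-grouped arrays for vectorized likelihood evaluation.

A subject's observed outcome entries are stacked visit-major (all outcomes
of the first observed visit, then the next visit, ...).  Subjects sharing
the same visit pattern, missingness mask, and survival record form a
*pattern group* whose likelihood contributions are evaluated with batched
linear algebra; observation times still vary freely within a group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import COL_DIED, COL_SUBJECT, COL_TIME, COL_VISIT, validate_cohort
from .practice import practice_loading_value
from .model import GrowthModelSpec


@dataclass
class SubjectDesign:
    """Observation structure of one subject under a model spec."""

    subject_id: object
    times: np.ndarray          # observed visit times (n_v,)
    visit_orders: np.ndarray   # 0-based visit indices (n_v,)
    mask: np.ndarray           # (n_v, n_outcomes) observed-entry mask
    y: np.ndarray              # stacked observed values (p,)
    x: np.ndarray              # covariate vector (C,)
    n_survived: int            # risk intervals known to be survived
    died: bool                 # death in interval n_survived + 1

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())


@dataclass
class PatternGroup:
    """All subjects sharing one observation/survival pattern."""

    entries: list            # [(visit_idx, outcome_idx)] stack order, length p
    visit_orders: np.ndarray
    n_survived: int
    died: bool
    ids: np.ndarray          # (g,)
    times: np.ndarray        # (g, n_v)
    Y: np.ndarray            # (g, p)
    X: np.ndarray            # (g, C)
    Lam: np.ndarray          # (g, p, F) factor loadings
    lam: np.ndarray          # (p,) practice loadings
    diag_outcome: np.ndarray  # (p,) outcome index of each stacked entry
    diag_visit: np.ndarray   # (p,) visit order of each stacked entry
    cross_pairs: list        # [(j1, j2)] same-visit memory-brain entry pairs


class GroupedDesign:
    """Pattern-grouped computational design for one cohort and spec."""

    def __init__(self, subjects: list[SubjectDesign], spec: GrowthModelSpec,
                 covariates: tuple[str, ...]):
        self.spec = spec
        self.covariates = covariates
        self.subjects = subjects
        self.n_subjects = len(subjects)
        F = spec.n_factors
        groups: dict[tuple, list[SubjectDesign]] = {}
        for s in subjects:
            key = (
                tuple(s.visit_orders),
                s.mask.tobytes(),
                s.n_survived,
                s.died,
            )
            groups.setdefault(key, []).append(s)

        self.groups: list[PatternGroup] = []
        for key, members in groups.items():
            proto = members[0]
            mask = proto.mask
            entries = [
                (vi, oi)
                for vi in range(mask.shape[0])
                for oi in range(mask.shape[1])
                if mask[vi, oi]
            ]
            times = np.stack([m.times for m in members])
            Y = np.stack([m.y for m in members])
            X = np.stack([m.x for m in members])
            g, p = len(members), len(entries)
            Lam = np.zeros((g, p, F))
            lam = np.zeros(p)
            diag_outcome = np.zeros(p, dtype=int)
            diag_visit = np.zeros(p, dtype=int)
            for j, (vi, oi) in enumerate(entries):
                Lam[:, j, 2 * oi] = 1.0
                Lam[:, j, 2 * oi + 1] = times[:, vi]
                diag_outcome[j] = oi
                diag_visit[j] = int(proto.visit_orders[vi])
                outcome = spec.outcomes[oi]
                if outcome in spec.practice_on:
                    lam[j] = practice_loading_value(
                        int(proto.visit_orders[vi]), spec.practice_rounding
                    )
            cross_pairs = []
            if spec.n_outcomes == 2:
                for j1, (v1, o1) in enumerate(entries):
                    for j2, (v2, o2) in enumerate(entries):
                        if j1 < j2 and v1 == v2 and o1 != o2:
                            cross_pairs.append((j1, j2))
            self.groups.append(
                PatternGroup(
                    entries=entries,
                    visit_orders=proto.visit_orders,
                    n_survived=proto.n_survived,
                    died=proto.died,
                    ids=np.array([m.subject_id for m in members]),
                    times=times,
                    Y=Y,
                    X=X,
                    Lam=Lam,
                    lam=lam,
                    diag_outcome=diag_outcome,
                    diag_visit=diag_visit,
                    cross_pairs=cross_pairs,
                )
            )


def build_subject_designs(
    df: pd.DataFrame, spec: GrowthModelSpec, validate: bool = True
) -> list[SubjectDesign]:
    """Per-subject designs from a long cohort table.

    Survival bookkeeping follows the cohort convention: a subject flagged
    as dying did so in the interval right after their last visit and
    survived all earlier intervals; an unflagged subject survived through
    the interval following their last visit (capped at the number of risk
    intervals), with later intervals censored.
    """
    if validate:
        validate_cohort(df, n_intervals=spec.n_intervals)
    for o in spec.outcomes:
        if o not in df.columns:
            raise ValueError(f"outcome column {o!r} not in the data")
    covs = spec.all_covariates
    for c in covs:
        if c not in df.columns:
            raise ValueError(f"covariate column {c!r} not in the data")

    sid_col = df[COL_SUBJECT].to_numpy()
    order = np.lexsort((df[COL_VISIT].to_numpy(), sid_col.astype(object)))
    sid = sid_col[order]
    orders_all = df[COL_VISIT].to_numpy(dtype=int)[order]
    times_all = df[COL_TIME].to_numpy(dtype=float)[order]
    died_all = df[COL_DIED].to_numpy(dtype=bool)[order]
    ymat_all = df[list(spec.outcomes)].to_numpy(dtype=float)[order]
    xmat_all = df[list(covs)].to_numpy(dtype=float)[order] if covs else None
    first = np.r_[True, sid[1:] != sid[:-1]]
    starts = np.flatnonzero(first)
    bounds = np.r_[starts, len(sid)]

    subjects = []
    for i in range(len(starts)):
        sl = slice(bounds[i], bounds[i + 1])
        orders = orders_all[sl]
        ymat = ymat_all[sl]
        mask = np.isfinite(ymat)
        died = bool(died_all[sl][-1])
        last = int(orders[-1])
        n_survived = last if died else min(last + 1, spec.n_intervals)
        subjects.append(
            SubjectDesign(
                subject_id=sid[starts[i]],
                times=times_all[sl],
                visit_orders=orders,
                mask=mask,
                y=ymat[mask],
                x=xmat_all[starts[i]] if covs else np.zeros(0),
                n_survived=n_survived,
                died=died,
            )
        )
    return subjects


def build_design(df: pd.DataFrame, spec: GrowthModelSpec, validate: bool = True) -> GroupedDesign:
    subjects = build_subject_designs(df, spec, validate=validate)
    return GroupedDesign(subjects, spec, spec.all_covariates)
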