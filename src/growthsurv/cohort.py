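"""Long-format cohort table: column conventions, validation, and IO.

A cohort is a plain :class:`pandas.DataFrame` with one row per subject-visit.
The columns below are the exchange format between every stage of the
package (simulation, preprocessing, model fitting, reporting).

Survival convention
-------------------
With three planned visits there are two risk intervals (between visits
one and two, and between visits two and three).  ``died_in_next_interval``
is ``True`` on a subject's *last* observed row when the subject died in the
interval immediately following that visit.  A subject without the flag is
treated as having survived through the interval following their last visit
(attrition for reasons other than death censors the survival process at
that point); this is the missing-at-random reading of non-death dropout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COL_SUBJECT = "subject_id"
COL_VISIT = "visit_order"
COL_TIME = "time_in_study"
COL_MEMORY = "memory"
COL_BRAIN = "brain_bpf"
COL_DIED = "died_in_next_interval"

#: columns every cohort table must carry
REQUIRED_COLUMNS = (COL_SUBJECT, COL_VISIT, COL_TIME, COL_DIED)


def validate_cohort(df: pd.DataFrame, n_intervals: int = 2) -> None:
    """Check the structural invariants of a long-format cohort table.

    Raises ``ValueError`` naming the first violated invariant:

    * required columns present;
    * visit order 0 exists for every subject and has ``time_in_study`` 0;
    * observation times strictly increase within subject;
    * each subject has between 1 and ``n_intervals + 1`` visits;
    * the death flag appears only on a subject's last row, and only when a
      risk interval remains (no outcome rows after a death interval).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    if df.empty:
        raise ValueError("cohort table is empty")

    order = np.lexsort(
        (df[COL_VISIT].to_numpy(), df[COL_SUBJECT].to_numpy(dtype=object))
    )
    sid = df[COL_SUBJECT].to_numpy()[order]
    orders = df[COL_VISIT].to_numpy(dtype=int)[order]
    times = df[COL_TIME].to_numpy(dtype=float)[order]
    died = df[COL_DIED].to_numpy(dtype=bool)[order]
    first = np.r_[True, sid[1:] != sid[:-1]]
    last = np.r_[first[1:], True]

    def offender(mask):
        return sid[np.argmax(mask)]

    if np.any(bad := first & (orders != 0)):
        raise ValueError(
            f"subject {offender(bad)!r} has no baseline visit (visit_order 0)"
        )
    if np.any(bad := first & (times != 0.0)):
        raise ValueError(
            f"subject {offender(bad)!r} has nonzero time_in_study at baseline"
        )
    same = ~first
    if np.any(bad := same & (np.r_[0, np.diff(orders)] <= 0)):
        raise ValueError(f"subject {offender(bad)!r} has duplicated visit orders")
    if np.any(bad := same & (np.r_[1.0, np.diff(times)] <= 0)):
        raise ValueError(
            f"subject {offender(bad)!r} has non-increasing observation times"
        )
    if np.any(bad := times < 0):
        raise ValueError(f"subject {offender(bad)!r} has negative observation times")
    if np.any(bad := orders > n_intervals):
        raise ValueError(
            f"subject {offender(bad)!r} has more than {n_intervals + 1} visits "
            f"with {n_intervals} risk intervals"
        )
    if np.any(bad := died & ~last):
        raise ValueError(
            f"subject {offender(bad)!r} has outcome rows after a death interval"
        )
    if np.any(bad := died & last & (orders + 1 > n_intervals)):
        raise ValueError(
            f"subject {offender(bad)!r} is flagged as dying after the last "
            "planned visit"
        )


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV (one row per subject-visit)."""
    df.to_csv(path, index=False)


def read_cohort(path, validate: bool = True) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    df[COL_DIED] = df[COL_DIED].astype(bool)
    if validate:
        validate_cohort(df)
    return df
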