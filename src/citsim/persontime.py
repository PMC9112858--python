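"""Time-at-risk computation and person-year expansion.

For each outcome, a child is at risk from birth to the earliest of the
fifth birthday, loss to follow-up, the study end date, or the first
diagnosis of the outcome; the event indicator is 1 iff the diagnosis date
attains that minimum.  Follow-up is then split into one analysis row per
year of life (ages 0..4), the final partial year carrying the fractional
time, which is the one-observation-per-year-of-life layout the Poisson
models expect.

Conventions (documented, since the day-level bookkeeping is not dictated by
the design): years are measured as days/365.25; censoring at the study end
or at loss to follow-up includes the censoring day (the child was observed
through it), whereas time to a diagnosis runs to the start of the diagnosis
day; the fifth birthday contributes exactly 5.0 years.  Age intervals are
half-open [a, a+1), so an event exactly on a birthday belongs to the later
year of life.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import MAX_AGE_YEARS
from .synthetic_cohort import DAYS_PER_YEAR, MotherBabyRecord

_EPS = 1e-12


class DataError(ValueError):
    """Raised for impossible record dates (e.g. diagnosis before birth)."""


@dataclass
class PersonYearRow:
    child_id: str
    birth_year: int
    age_year: int  # 0..4
    delivery_type: str
    exposure_value: float
    time_at_risk: float  # years in (0, 1]
    event: int


def fifth_birthday(birth: date) -> date:
    """Calendar fifth birthday; 29 February birthdays map to 28 February."""
    try:
        return birth.replace(year=birth.year + 5)
    except ValueError:
        return birth.replace(year=birth.year + 5, day=28)


def follow_up_end(child: MotherBabyRecord, outcome: str,
                  study_end: date) -> tuple[date, int]:
    """Earliest of fifth birthday, LTFU, study end, diagnosis; event flag.

    The event flag is 1 iff the diagnosis date is the (possibly tied)
    earliest candidate.
    """
    birth = child.birth_date
    diag = child.outcome_dates.get(outcome)
    if diag is not None and diag < birth:
        raise DataError(
            f"diagnosis of {outcome!r} before birth for {child.child_id}")
    if child.ltfu_date is not None and child.ltfu_date < birth:
        raise DataError(f"LTFU before birth for {child.child_id}")
    candidates = [fifth_birthday(birth), study_end]
    if child.ltfu_date is not None:
        candidates.append(child.ltfu_date)
    end = min(candidates)
    event = 0
    if diag is not None and diag <= end:
        end, event = diag, 1
    return end, event


def follow_up_years(child: MotherBabyRecord, outcome: str,
                    study_end: date) -> tuple[float, int]:
    """Length of follow-up in years under the documented day conventions."""
    end, event = follow_up_end(child, outcome, study_end)
    birth = child.birth_date
    days = (end - birth).days
    if event:
        years = days / DAYS_PER_YEAR
    elif end == fifth_birthday(birth) and end <= study_end:
        years = float(MAX_AGE_YEARS)
    else:
        years = (days + 1) / DAYS_PER_YEAR  # censoring day observed
    return min(years, float(MAX_AGE_YEARS)), event


def expand_person_years(child: MotherBabyRecord, years: float, event: int,
                        exposure_value: float = 0.0) -> list[PersonYearRow]:
    """Split follow-up into one row per year of life; event on the last row."""
    if years <= 0:
        import warnings
        warnings.warn(f"zero follow-up for {child.child_id}", stacklevel=2)
        return []
    years = min(years, float(MAX_AGE_YEARS))
    n_rows = int(np.ceil(years - _EPS))
    rows = []
    for a in range(n_rows):
        t = min(1.0, years - a)
        rows.append(PersonYearRow(
            child_id=child.child_id,
            birth_year=child.birth_date.year,
            age_year=a,
            delivery_type=child.delivery_type,
            exposure_value=exposure_value,
            time_at_risk=t,
            event=event if a == n_rows - 1 else 0,
        ))
    return rows


def total_person_years(rows) -> tuple[int, float]:
    """Exact (event count, person-years) sums over analysis rows."""
    if isinstance(rows, pd.DataFrame):
        if len(rows) == 0:
            raise ValueError("rows must be nonempty")
        return int(rows["event"].sum()), float(rows["time_at_risk"].sum())
    rows = list(rows)
    if not rows:
        raise ValueError("rows must be nonempty")
    return (sum(r.event for r in rows),
            float(sum(r.time_at_risk for r in rows)))


# ---------------------------------------------------------------------------
# vectorised table builder


def build_person_year_table(cohort: pd.DataFrame, outcome: str,
                            study_end: date) -> pd.DataFrame:
    """Expand an exposure-assigned cohort frame into person-year rows.

    Requires ``exposure_value``/``exposure_status`` columns (see the
    exposure module); rows for excluded children are dropped.  Returns a
    frame with columns child_id, birth_year, age_year, delivery_type,
    caesarean_type, exposure_value, time_at_risk, event.
    """
    if "exposure_value" not in cohort.columns:
        raise ValueError("cohort frame lacks exposure assignment columns")
    inc = cohort[cohort["exposure_status"] == "included"]

    birth = inc["birth_date"].to_numpy(dtype="datetime64[D]")
    end_study = np.datetime64(study_end, "D")
    fifth = (pd.DatetimeIndex(inc["birth_date"])
             + pd.DateOffset(years=MAX_AGE_YEARS)).to_numpy(
                 dtype="datetime64[D]")
    ltfu = inc["ltfu_date"].to_numpy(dtype="datetime64[D]")
    diag_col = f"outcome_{outcome}_date"
    if diag_col not in inc.columns:
        raise KeyError(f"cohort has no column {diag_col!r}")
    diag = inc[diag_col].to_numpy(dtype="datetime64[D]")

    if np.any(diag[~np.isnat(diag)] < birth[~np.isnat(diag)]):
        raise DataError(f"diagnosis of {outcome!r} before birth")

    censor = np.minimum(fifth, end_study)
    has_ltfu = ~np.isnat(ltfu)
    censor[has_ltfu] = np.minimum(censor[has_ltfu], ltfu[has_ltfu])
    has_diag = ~np.isnat(diag)
    event = has_diag & (diag <= censor)
    end = np.where(event, diag, censor)

    days = (end - birth).astype("timedelta64[D]").astype(float)
    at_fifth = (~event) & (end == fifth)
    years = np.where(event, days / DAYS_PER_YEAR,
                     np.where(at_fifth, float(MAX_AGE_YEARS),
                              (days + 1) / DAYS_PER_YEAR))
    years = np.clip(years, 0.0, float(MAX_AGE_YEARS))

    pos = years > 0
    inc = inc[pos]
    years = years[pos]
    event = event[pos]

    n_rows = np.ceil(years - _EPS).astype(int)
    idx = np.repeat(np.arange(len(inc)), n_rows)
    # within-child age counter: 0..n_rows[i]-1 for each child i
    starts = np.cumsum(n_rows) - n_rows
    age = np.arange(idx.size) - starts[idx]
    time = np.minimum(1.0, years[idx] - age)
    last = age == (n_rows[idx] - 1)

    out = pd.DataFrame({
        "child_id": inc["child_id"].to_numpy()[idx],
        "birth_year": inc["birth_year"].to_numpy()[idx],
        "age_year": age,
        "delivery_type": inc["delivery_type"].to_numpy()[idx],
        "caesarean_type": inc["caesarean_type"].to_numpy()[idx],
        "exposure_value": inc["exposure_value"].to_numpy()[idx],
        "time_at_risk": time,
        "event": (event[idx] & last).astype(int),
    })
    return out
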