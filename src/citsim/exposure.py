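"""Policy-uptake estimation and exposure assignment.

Two exposure regimes are supported, mirroring how the policy change is
observed in different data sources:

* **national** — the child-level exposure is unknown, so each caesarean
  birth receives the national probability that a caesarean in its birth
  year occurred under a pre-incision policy (the uptake curve estimated
  from the hospital survey).
* **hospital** — the hospital's policy-change year is known, so caesarean
  births receive a 0/1 indicator (born strictly after the change year);
  births in the change year itself are excluded, as are births at
  hospitals whose policy is unknown.

Vaginal births are always unexposed (value 0, included): the policy change
only applies to caesarean section, which is what makes vaginal deliveries
the control series of the interrupted time series design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import UNKNOWN
from .synthetic_cohort import Hospital, MotherBabyRecord

INCLUDED = "included"
EXCLUDED_CHANGE_YEAR = "excluded_change_year"
EXCLUDED_UNKNOWN_POLICY = "excluded_unknown_policy"


class UptakeUndefinedError(KeyError):
    """Uptake probability requested for a year with no informative births."""


@dataclass
class UptakeCurve:
    """Yearly probability that a caesarean birth was under a pre-incision
    policy, weighted by caesarean birth counts at known-policy hospitals."""

    probabilities: dict = field(default_factory=dict)  # year -> p
    n_denominator: dict = field(default_factory=dict)  # year -> births
    undefined_years: set = field(default_factory=set)

    def probability(self, year: int) -> float:
        year = int(year)
        if year in self.undefined_years or year not in self.probabilities:
            raise UptakeUndefinedError(
                f"uptake probability undefined for year {year}")
        return self.probabilities[year]

    def to_frame(self) -> pd.DataFrame:
        years = sorted(set(self.probabilities) | self.undefined_years)
        return pd.DataFrame({
            "year": years,
            "p_preincision": [
                np.nan if y in self.undefined_years
                else self.probabilities[y] for y in years],
            "n_denominator": [self.n_denominator.get(y, 0) for y in years],
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "UptakeCurve":
        curve = cls()
        for row in frame.itertuples(index=False):
            y = int(row.year)
            curve.n_denominator[y] = int(row.n_denominator)
            if pd.isna(row.p_preincision):
                curve.undefined_years.add(y)
            else:
                curve.probabilities[y] = float(row.p_preincision)
        return curve


def caesarean_births_by_hospital_year(cohort: pd.DataFrame) -> pd.DataFrame:
    """Count caesarean births per hospital and calendar year."""
    cs = cohort[cohort["delivery_type"] == "caesarean"]
    counts = (cs.groupby(["hospital_id", "birth_year"], as_index=False)
              .size().rename(columns={"size": "n_caesarean",
                                      "birth_year": "year"}))
    return counts


def estimate_uptake(hospitals: Sequence[Hospital],
                    births_by_hospital_year: pd.DataFrame) -> UptakeCurve:
    """Estimate the national uptake curve from the hospital survey.

    For each calendar year ``y``::

        p(y) = caesarean births at hospitals with change year < y
               -----------------------------------------------------
               caesarean births at hospitals with known policy

    Hospitals with an unknown policy are excluded from numerator and
    denominator.  A year whose denominator is zero is flagged undefined
    rather than silently set to zero.
    """
    known = {h.hospital_id: h for h in hospitals if h.policy_known}
    if not known:
        # every year will be undefined; still return a curve so callers can
        # surface the per-year errors explicitly
        pass
    if (births_by_hospital_year["n_caesarean"] < 0).any():
        raise ValueError("birth counts must be non-negative")

    curve = UptakeCurve()
    for year, grp in births_by_hospital_year.groupby("year"):
        year = int(year)
        num = 0
        denom = 0
        for row in grp.itertuples(index=False):
            h = known.get(row.hospital_id)
            if h is None:
                continue
            denom += int(row.n_caesarean)
            cy = h.policy_change_year
            if cy is not None and int(cy) < year:
                num += int(row.n_caesarean)
        curve.n_denominator[year] = denom
        if denom == 0:
            curve.undefined_years.add(year)
        else:
            curve.probabilities[year] = num / denom
    return curve


@dataclass(frozen=True)
class ExposureAssignment:
    child_id: str
    regime: str  # "national" | "hospital"
    value: float  # probability in [0, 1] or indicator
    status: str


# ---------------------------------------------------------------------------
# national regime


def assign_exposure_national(child: MotherBabyRecord,
                             curve: UptakeCurve) -> ExposureAssignment:
    """Probability-of-exposure assignment from the national uptake curve."""
    if child.delivery_type == "vaginal":
        return ExposureAssignment(child.child_id, "national", 0.0, INCLUDED)
    value = curve.probability(child.birth_date.year)
    return ExposureAssignment(child.child_id, "national", value, INCLUDED)


def assign_exposure_national_frame(cohort: pd.DataFrame,
                                   curve: UptakeCurve) -> pd.DataFrame:
    """Vectorised national assignment; adds ``exposure_value`` and
    ``exposure_status`` columns to a copy of the cohort frame."""
    out = cohort.copy()
    cs = out["delivery_type"] == "caesarean"
    years = out.loc[cs, "birth_year"].unique()
    lookup = {int(y): curve.probability(int(y)) for y in years}
    out["exposure_value"] = 0.0
    out.loc[cs, "exposure_value"] = (
        out.loc[cs, "birth_year"].map(lookup).to_numpy())
    out["exposure_status"] = INCLUDED
    return out


# ---------------------------------------------------------------------------
# hospital regime


def assign_exposure_hospital(child: MotherBabyRecord,
                             hospitals: Sequence[Hospital] | dict,
                             exclude_vaginal_in_change_year: bool = False
                             ) -> ExposureAssignment:
    """Indicator assignment from the child's hospital policy-change year."""
    if not isinstance(hospitals, dict):
        hospitals = {h.hospital_id: h for h in hospitals}
    h = hospitals.get(child.hospital_id)
    if h is None:
        raise KeyError(f"unknown hospital_id {child.hospital_id!r}")
    year = child.birth_date.year
    change = h.policy_change_year

    if child.delivery_type == "vaginal":
        if (exclude_vaginal_in_change_year and h.policy_known
                and change is not None and int(change) == year):
            return ExposureAssignment(child.child_id, "hospital", 0.0,
                                      EXCLUDED_CHANGE_YEAR)
        return ExposureAssignment(child.child_id, "hospital", 0.0, INCLUDED)

    if change == UNKNOWN:
        return ExposureAssignment(child.child_id, "hospital", 0.0,
                                  EXCLUDED_UNKNOWN_POLICY)
    if change is None:  # never adopted: always unexposed
        return ExposureAssignment(child.child_id, "hospital", 0.0, INCLUDED)
    change = int(change)
    if year == change:
        return ExposureAssignment(child.child_id, "hospital", 0.0,
                                  EXCLUDED_CHANGE_YEAR)
    value = 1.0 if year > change else 0.0
    return ExposureAssignment(child.child_id, "hospital", value, INCLUDED)


def assign_exposure_hospital_frame(cohort: pd.DataFrame,
                                   hospitals: Sequence[Hospital],
                                   exclude_vaginal_in_change_year: bool = False
                                   ) -> pd.DataFrame:
    """Vectorised hospital-regime assignment."""
    by_id = {h.hospital_id: h for h in hospitals}
    missing = set(cohort["hospital_id"].unique()) - set(by_id)
    if missing:
        raise KeyError(f"unknown hospital_id(s): {sorted(missing)}")

    change = cohort["hospital_id"].map(
        lambda hid: by_id[hid].policy_change_year
        if by_id[hid].policy_change_year not in (None, UNKNOWN) else np.nan
    ).astype(float).to_numpy()
    unknown = cohort["hospital_id"].map(
        lambda hid: by_id[hid].policy_change_year == UNKNOWN
    ).to_numpy(dtype=bool)
    year = cohort["birth_year"].to_numpy()
    cs = (cohort["delivery_type"] == "caesarean").to_numpy()

    in_change_year = ~np.isnan(change) & (year == change)
    out = cohort.copy()
    out["exposure_value"] = np.where(
        cs & ~np.isnan(change) & (year > change), 1.0, 0.0)
    status = np.full(len(out), INCLUDED, dtype=object)
    status[cs & unknown] = EXCLUDED_UNKNOWN_POLICY
    status[cs & in_change_year] = EXCLUDED_CHANGE_YEAR
    if exclude_vaginal_in_change_year:
        status[~cs & in_change_year] = EXCLUDED_CHANGE_YEAR
    out["exposure_status"] = status
    out.loc[out["exposure_status"] != INCLUDED, "exposure_value"] = 0.0
    return out
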