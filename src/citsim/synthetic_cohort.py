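"""Synthetic hospitals, policy surveys, mother-baby cohorts and maternal outcomes.

The generator emulates the data structure of UK routine maternity records on
which the pre-incision antibiotic policy change was evaluated: a hospital
survey reporting the year each hospital moved prophylactic antibiotics from
post-cord-clamping to pre-incision, a mother-baby cohort with delivery type
and first-diagnosis dates for childhood outcomes, and maternal six-week
postpartum outcomes.  All randomness is driven by the configuration seed, so
identical configurations yield identical outputs.

Ground-truth columns (``true_exposure``, ``latent_change_year``) are carried
alongside the observable fields so that parameter-recovery experiments can
compare estimates against the simulated truth; real records have no such
columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import (MAX_AGE_YEARS, NEVER, UNKNOWN, ConfigurationError,
                     SimConfig)

DAYS_PER_YEAR = 365.25

# Fixed sub-stream keys so each generator draws from an independent stream
# of the configuration seed regardless of call order.
_STREAM_HOSPITALS = 1
_STREAM_COHORT = 2
_STREAM_MATERNAL = 3


@dataclass(frozen=True)
class Hospital:
    """One surveyed maternity unit.

    ``policy_change_year`` is the survey response: a calendar year, ``None``
    for a hospital that never adopted pre-incision prophylaxis, or the string
    ``"unknown"`` when the survey response is missing.  ``latent_change_year``
    is the simulation ground truth (equal to the reported year when the
    response is known); analyses never see it.
    """

    hospital_id: str
    policy_change_year: int | None | str
    latent_change_year: int | None

    @property
    def policy_known(self) -> bool:
        return self.policy_change_year != UNKNOWN


@dataclass
class MotherBabyRecord:
    child_id: str
    mother_id: str
    hospital_id: str
    birth_date: date
    delivery_type: str  # "caesarean" | "vaginal"
    caesarean_type: str | None  # "elective" | "emergency" | None
    ltfu_date: date | None
    outcome_dates: dict  # outcome -> first diagnosis date or None
    multiple_birth_group: str | None
    true_exposure: bool


@dataclass
class MaternalDelivery:
    mother_id: str
    delivery_year: int
    delivery_type: str
    outcome_flags: dict  # outcome -> 0/1 within 42 days of delivery
    length_of_stay: float
    true_exposure: bool


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), stream]))


# ---------------------------------------------------------------------------
# hospitals


def generate_hospitals(config: SimConfig) -> list[Hospital]:
    """Draw hospitals with policy-change years i.i.d. from the survey mix.

    Hospitals whose survey response is unknown still have a latent change
    year, drawn from the known part of the distribution renormalised; this
    is what makes probability-based exposure assignment a genuine
    misclassification problem rather than a bookkeeping identity.
    """
    dist = config.change_year_distribution
    if not dist:
        raise ConfigurationError("change_year_distribution is empty")
    rng = _rng(config, _STREAM_HOSPITALS)
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    draws = rng.choice(len(keys), size=config.n_hospitals, p=probs)

    known_keys = [k for k in keys if k != UNKNOWN]
    known_probs = np.array([dist[k] for k in known_keys], dtype=float)
    if known_probs.sum() > 0:
        known_probs = known_probs / known_probs.sum()

    hospitals = []
    for i, ki in enumerate(draws):
        key = keys[ki]
        if key == UNKNOWN:
            if known_keys:
                latent_key = known_keys[
                    rng.choice(len(known_keys), p=known_probs)]
            else:
                latent_key = NEVER
            latent = None if latent_key == NEVER else int(latent_key)
            reported: int | None | str = UNKNOWN
        elif key == NEVER:
            reported, latent = None, None
        else:
            reported, latent = int(key), int(key)
        hospitals.append(Hospital(f"H{i + 1:03d}", reported, latent))
    return hospitals


def hospitals_to_frame(hospitals: Sequence[Hospital]) -> pd.DataFrame:
    rows = []
    for h in hospitals:
        if h.policy_change_year == UNKNOWN:
            status, year = UNKNOWN, np.nan
        elif h.policy_change_year is None:
            status, year = NEVER, np.nan
        else:
            status, year = "changed", h.policy_change_year
        rows.append({
            "hospital_id": h.hospital_id,
            "policy_status": status,
            "policy_change_year": year,
            "latent_change_year":
                np.nan if h.latent_change_year is None
                else h.latent_change_year,
        })
    return pd.DataFrame(rows)


def frame_to_hospitals(frame: pd.DataFrame) -> list[Hospital]:
    out = []
    for row in frame.itertuples(index=False):
        if row.policy_status == UNKNOWN:
            reported: int | None | str = UNKNOWN
        elif row.policy_status == NEVER:
            reported = None
        else:
            reported = int(row.policy_change_year)
        latent = (None if pd.isna(row.latent_change_year)
                  else int(row.latent_change_year))
        out.append(Hospital(str(row.hospital_id), reported, latent))
    return out


# ---------------------------------------------------------------------------
# cohort


def _event_ages(rng: np.random.Generator, config: SimConfig, outcome: str,
                birth_year: np.ndarray, caesarean: np.ndarray,
                exposed: np.ndarray, elective: np.ndarray) -> np.ndarray:
    """First-event age (years, float) per child, NaN if no event before 5.

    Piecewise-constant hazard over years of life: within year of life ``a``
    an exponential waiting time is drawn; the first year whose waiting time
    falls inside the year yields the event.
    """
    base = config.baseline_rate[outcome] / 1000.0
    n = birth_year.shape[0]
    first_year = config.birth_year_range[0]
    # per-child IRR: the configured effect, scaled for elective caesareans
    # when a subgroup contrast is being simulated
    irr = config.true_irr * config.elective_irr_ratio ** elective.astype(float)
    mult = (config.delivery_rr ** caesarean.astype(float)
            * irr ** exposed.astype(float))
    age = np.full(n, np.nan)
    done = np.zeros(n, dtype=bool)
    for a in range(MAX_AGE_YEARS):
        lam = (base * config.age_rate_multipliers[a]
               * config.year_trend ** (birth_year + a - first_year) * mult)
        if np.any(lam <= 0):
            raise ConfigurationError("hazard parameters must be positive")
        wait = rng.exponential(1.0, size=n) / lam
        hit = (~done) & (wait < 1.0)
        age[hit] = a + wait[hit]
        done |= hit
    return age


def generate_cohort_frame(config: SimConfig,
                          hospitals: Sequence[Hospital],
                          outcomes: Iterable[str] | None = None
                          ) -> pd.DataFrame:
    """Vectorised cohort generator returning one row per retained child.

    ``config.n_children`` deliveries are simulated; multiple-birth deliveries
    produce twin pairs of which exactly one child is retained at random, so
    the returned frame has ``n_children`` rows, each a distinct delivery.
    """
    if not hospitals:
        raise ConfigurationError("hospitals must be nonempty")
    if outcomes is None:
        outcomes = list(config.baseline_rate)
    else:
        outcomes = list(outcomes)
        missing = [o for o in outcomes if o not in config.baseline_rate]
        if missing:
            raise ConfigurationError(f"no baseline rate for {missing}")

    rng = _rng(config, _STREAM_COHORT)
    n = config.n_children
    first, last = config.birth_year_range

    hosp_idx = rng.integers(0, len(hospitals), size=n)
    latent = np.array([
        -1 if h.latent_change_year is None else h.latent_change_year
        for h in hospitals])
    hosp_ids = np.array([h.hospital_id for h in hospitals])

    birth_year = rng.integers(first, last + 1, size=n)
    day_of_year = rng.integers(0, 365, size=n)
    birth_date = ((birth_year - 1970).astype("datetime64[Y]")
                  .astype("datetime64[D]") + day_of_year)

    caesarean = rng.random(n) < config.caesarean_fraction
    elective = caesarean & (rng.random(n) < config.elective_fraction_of_cs)

    # True exposure: caesarean birth strictly after the hospital's (latent)
    # change year, thinned by compliance.
    change = latent[hosp_idx]
    post_change = (change >= 0) & (birth_year > change)
    exposed = caesarean & post_change
    if config.compliance < 1.0:
        exposed &= rng.random(n) < config.compliance

    # Multiple births: a twin pair shares mother, hospital and birth date;
    # one of the two children is retained at random, mirroring the analysis
    # rule of randomly choosing one child from each multiple birth.  Outcome
    # draws are independent between twins, so retaining either leaves the
    # marginal distribution of the kept child unchanged; the retained row is
    # simply tagged with its group id.
    is_multi = rng.random(n) < config.multiple_birth_prob
    # rng draw consumed for the discarded twin's outcomes is not needed:
    # independence means we may draw the retained child's outcomes directly.
    keep_first_twin = rng.random(n) < 0.5  # which twin of the pair is kept

    outcome_age = {
        o: _event_ages(rng, config, o, birth_year, caesarean, exposed,
                       elective)
        for o in outcomes
    }

    if config.ltfu_annual_prob > 0:
        g = rng.geometric(config.ltfu_annual_prob, size=n)
    else:
        g = np.full(n, np.iinfo(np.int64).max)
    ltfu_years = np.where(g <= MAX_AGE_YEARS + 1,
                          (g - 1) + rng.random(n), np.nan)

    frame = pd.DataFrame({
        "child_id": [f"C{i + 1:07d}" for i in range(n)],
        "mother_id": [f"M{i + 1:07d}" for i in range(n)],
        "hospital_id": hosp_ids[hosp_idx],
        "birth_date": pd.to_datetime(birth_date),
        "birth_year": birth_year,
        "delivery_type": np.where(caesarean, "caesarean", "vaginal"),
        "caesarean_type": np.select(
            [caesarean & elective, caesarean & ~elective],
            ["elective", "emergency"], default=None),
        "multiple_birth_group": [
            f"G{i + 1:07d}" if m else None for i, m in enumerate(is_multi)],
        "retained_twin": np.where(is_multi,
                                  np.where(keep_first_twin, 1, 2), 0),
        "true_exposure": exposed,
    })
    frame["ltfu_date"] = frame["birth_date"] + pd.to_timedelta(
        np.round(ltfu_years * DAYS_PER_YEAR), unit="D")
    for o in outcomes:
        frame[f"outcome_{o}_date"] = frame["birth_date"] + pd.to_timedelta(
            np.round(outcome_age[o] * DAYS_PER_YEAR), unit="D")
    return frame


def generate_cohort(config: SimConfig, hospitals: Sequence[Hospital],
                    outcomes: Iterable[str] | None = None
                    ) -> list[MotherBabyRecord]:
    """Record-level view of :func:`generate_cohort_frame`."""
    frame = generate_cohort_frame(config, hospitals, outcomes)
    return frame_to_records(frame)


def frame_to_records(frame: pd.DataFrame) -> list[MotherBabyRecord]:
    outcome_cols = [c for c in frame.columns
                    if c.startswith("outcome_") and c.endswith("_date")]
    names = [c[len("outcome_"):-len("_date")] for c in outcome_cols]
    records = []
    for row in frame.itertuples(index=False):
        dates = {}
        for name, col in zip(names, outcome_cols):
            v = getattr(row, col)
            dates[name] = None if pd.isna(v) else v.date()
        records.append(MotherBabyRecord(
            child_id=row.child_id,
            mother_id=row.mother_id,
            hospital_id=row.hospital_id,
            birth_date=row.birth_date.date(),
            delivery_type=row.delivery_type,
            caesarean_type=(None if row.caesarean_type is None
                            or (isinstance(row.caesarean_type, float)
                                and np.isnan(row.caesarean_type))
                            else row.caesarean_type),
            ltfu_date=None if pd.isna(row.ltfu_date) else row.ltfu_date.date(),
            outcome_dates=dates,
            multiple_birth_group=(None if row.multiple_birth_group is None
                                  else row.multiple_birth_group),
            true_exposure=bool(row.true_exposure),
        ))
    return records


def select_one_per_multiple_birth(frame: pd.DataFrame,
                                  rng: np.random.Generator) -> pd.DataFrame:
    """Retain exactly one child per multiple-birth group.

    Provided for cohorts where twin siblings appear as separate rows (e.g.
    external data).  Singleton rows (group ``None``/NaN) pass through.
    """
    if frame["multiple_birth_group"].notna().sum() == 0:
        return frame.copy()
    shuffled = frame.iloc[rng.permutation(len(frame))]
    in_group = shuffled["multiple_birth_group"].notna()
    dup = shuffled["multiple_birth_group"].duplicated() & in_group
    return shuffled[~dup].sort_index().reset_index(drop=True)


# ---------------------------------------------------------------------------
# maternal outcomes


def generate_maternal_frame(config: SimConfig,
                            cohort: pd.DataFrame) -> pd.DataFrame:
    """One delivery per mother with Bernoulli six-week postpartum outcomes.

    The caesarean risk is multiplied by the outcome's ``exposure_rr`` when
    the delivery was truly under a pre-incision policy; vaginal deliveries
    are unaffected by the policy.  Length of stay is a truncated normal with
    delivery-type mean, shifted by ``los_exposure_shift`` under exposure.
    """
    if len(cohort) == 0:
        raise ConfigurationError("cohort must be nonempty")
    rng = _rng(config, _STREAM_MATERNAL)
    cs = (cohort["delivery_type"] == "caesarean").to_numpy()
    exposed = cohort["true_exposure"].to_numpy(dtype=bool)
    n = len(cohort)

    out = pd.DataFrame({
        "mother_id": cohort["mother_id"].to_numpy(),
        "delivery_year": cohort["birth_year"].to_numpy(),
        "delivery_type": cohort["delivery_type"].to_numpy(),
        "true_exposure": exposed,
    })
    for name, risk in config.maternal_risk.items():
        p = np.where(cs, risk.risk_caesarean, risk.risk_vaginal)
        p = np.where(cs & exposed, p * risk.exposure_rr, p)
        if np.any((p < 0) | (p > 1)):
            raise ConfigurationError(
                f"maternal risk for {name!r} outside [0, 1]")
        out[f"flag_{name}"] = (rng.random(n) < p).astype(int)
    mean = np.where(cs, config.los_mean_caesarean, config.los_mean_vaginal)
    mean = mean + config.los_exposure_shift * (cs & exposed)
    out["length_of_stay"] = np.clip(
        rng.normal(mean, config.los_sd), 0.0, None)
    return out


def generate_maternal(config: SimConfig,
                      cohort: pd.DataFrame | Sequence[MotherBabyRecord]
                      ) -> list[MaternalDelivery]:
    if not isinstance(cohort, pd.DataFrame):
        cohort = records_to_frame(list(cohort))
    frame = generate_maternal_frame(config, cohort)
    flags = [c for c in frame.columns if c.startswith("flag_")]
    return [
        MaternalDelivery(
            mother_id=row.mother_id,
            delivery_year=int(row.delivery_year),
            delivery_type=row.delivery_type,
            outcome_flags={c[len("flag_"):]: int(getattr(row, c))
                           for c in flags},
            length_of_stay=float(row.length_of_stay),
            true_exposure=bool(row.true_exposure),
        )
        for row in frame.itertuples(index=False)
    ]


def records_to_frame(records: Sequence[MotherBabyRecord]) -> pd.DataFrame:
    outcomes = sorted({o for r in records for o in r.outcome_dates})
    data = {
        "child_id": [r.child_id for r in records],
        "mother_id": [r.mother_id for r in records],
        "hospital_id": [r.hospital_id for r in records],
        "birth_date": pd.to_datetime([r.birth_date for r in records]),
        "birth_year": [r.birth_date.year for r in records],
        "delivery_type": [r.delivery_type for r in records],
        "caesarean_type": [r.caesarean_type for r in records],
        "multiple_birth_group": [r.multiple_birth_group for r in records],
        "true_exposure": [r.true_exposure for r in records],
        "ltfu_date": pd.to_datetime([r.ltfu_date for r in records]),
    }
    frame = pd.DataFrame(data)
    for o in outcomes:
        frame[f"outcome_{o}_date"] = pd.to_datetime(
            [r.outcome_dates.get(o) for r in records])
    return frame


# ---------------------------------------------------------------------------
# CSV round-trip


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in frame.columns:
        if col == "birth_date" or col == "ltfu_date" or (
                col.startswith("outcome_") and col.endswith("_date")):
            frame[col] = pd.to_datetime(frame[col])
    if "caesarean_type" in frame:
        frame["caesarean_type"] = frame["caesarean_type"].where(
            frame["caesarean_type"].notna(), None)
    if "multiple_birth_group" in frame:
        frame["multiple_birth_group"] = frame["multiple_birth_group"].where(
            frame["multiple_birth_group"].notna(), None)
    return frame
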