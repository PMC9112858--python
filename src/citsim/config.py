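"""Simulation configuration for the synthetic mother-baby cohort generator.

The configuration pins down the statistical structure the controlled
interrupted time series (CITS) analysis assumes: secular trends in outcome
incidence, age-dependent first-event hazards over years of life 0-4, the
caesarean fraction, hospital-level policy-change years, a configurable true
exposure incidence rate ratio (IRR), loss to follow-up, multiple births, and
delivery-type-dependent maternal infection risks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

import yaml

#: Sentinel survey responses for a hospital's policy-change year.
NEVER = "never"
UNKNOWN = "unknown"

#: Follow-up stops at the fifth birthday: years of life 0..4.
MAX_AGE_YEARS = 5

#: Calendar bounds the generator accepts for birth years.
STUDY_PERIOD = (2005, 2018)


class ConfigurationError(ValueError):
    """Raised when simulation parameters are outside their valid domain."""


@dataclass(frozen=True)
class MaternalRisk:
    """Six-week postpartum outcome risk by delivery type.

    ``exposure_rr`` multiplies the caesarean risk when the mother delivered
    under a pre-incision antibiotic policy (the generator's ground truth).
    """

    risk_caesarean: float
    risk_vaginal: float
    exposure_rr: float = 1.0

    def validate(self, name: str) -> None:
        for label, v in (("risk_caesarean", self.risk_caesarean),
                         ("risk_vaginal", self.risk_vaginal)):
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(
                    f"maternal_risk[{name!r}].{label}={v} outside [0, 1]")
        if self.exposure_rr <= 0:
            raise ConfigurationError(
                f"maternal_risk[{name!r}].exposure_rr must be positive")
        if self.risk_caesarean * self.exposure_rr > 1.0:
            raise ConfigurationError(
                f"maternal_risk[{name!r}]: risk_caesarean x exposure_rr "
                f"exceeds 1")


def _default_change_year_distribution() -> dict:
    # Staggered policy adoption over the study period.  The mass on known
    # change years (0.55) mirrors the share of births at hospitals able to
    # report a change year in the national survey; "never" hospitals kept a
    # post-cord-clamping policy throughout, "unknown" hospitals did not
    # report a year.
    return {
        UNKNOWN: 0.40,
        NEVER: 0.05,
        2008: 0.05,
        2009: 0.07,
        2010: 0.08,
        2011: 0.09,
        2012: 0.09,
        2013: 0.08,
        2014: 0.09,
    }


def _default_baseline_rate() -> dict:
    # Events per 1000 person-years at the reference age/year, on the scale
    # of asthma and eczema incidence in UK primary care records.
    return {"asthma": 9.9, "eczema": 71.9}


def _default_maternal_risk() -> dict:
    # Composite infectious morbidity and wound infection at the observed
    # caesarean/vaginal percentages, with protective pre-incision effects.
    return {
        "composite_infectious_morbidity": MaternalRisk(0.0861, 0.0143, 0.70),
        "wound_infection": MaternalRisk(0.0809, 0.0102, 0.62),
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    The first-event hazard for a child in year of life ``a`` is

        lambda(a) = baseline/1000 * age_mult[a] * year_trend**(year - y0)
                    * delivery_rr**[caesarean] * true_irr**[truly exposed]

    where ``year = birth_year + a`` (year resolution) and "truly exposed"
    means a caesarean birth in a year strictly after the hospital's policy
    change, thinned by ``compliance``.
    """

    n_children: int = 100_000
    birth_year_range: tuple[int, int] = (2006, 2018)
    caesarean_fraction: float = 0.281
    elective_fraction_of_cs: float = 0.4
    n_hospitals: int = 120
    change_year_distribution: dict = field(
        default_factory=_default_change_year_distribution)
    baseline_rate: dict = field(default_factory=_default_baseline_rate)
    age_rate_multipliers: tuple[float, ...] = (0.7, 1.3, 1.2, 1.0, 0.8)
    year_trend: float = 0.99
    delivery_rr: float = 1.1
    true_irr: float = 1.0
    elective_irr_ratio: float = 1.0
    compliance: float = 1.0
    ltfu_annual_prob: float = 0.03
    multiple_birth_prob: float = 0.03
    maternal_risk: dict = field(default_factory=_default_maternal_risk)
    los_mean_caesarean: float = 3.0
    los_mean_vaginal: float = 1.5
    los_sd: float = 1.0
    los_exposure_shift: float = -0.23
    study_end: date = date(2018, 12, 31)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.study_end, str):
            self.study_end = date.fromisoformat(self.study_end)
        self.birth_year_range = tuple(self.birth_year_range)  # type: ignore
        self.age_rate_multipliers = tuple(self.age_rate_multipliers)
        self.maternal_risk = {
            k: (v if isinstance(v, MaternalRisk) else MaternalRisk(**v))
            for k, v in self.maternal_risk.items()
        }
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_children < 1:
            raise ConfigurationError("n_children must be >= 1")
        if self.n_hospitals < 1:
            raise ConfigurationError("n_hospitals must be >= 1")
        first, last = self.birth_year_range
        if not (STUDY_PERIOD[0] <= first <= last <= STUDY_PERIOD[1]):
            raise ConfigurationError(
                f"birth_year_range {self.birth_year_range} outside "
                f"{STUDY_PERIOD}")
        for name in ("caesarean_fraction", "elective_fraction_of_cs",
                     "compliance", "ltfu_annual_prob", "multiple_birth_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not self.change_year_distribution:
            raise ConfigurationError("change_year_distribution is empty")
        total = 0.0
        for key, p in self.change_year_distribution.items():
            if p < 0:
                raise ConfigurationError(
                    f"change_year_distribution[{key!r}] negative")
            total += p
            if key in (NEVER, UNKNOWN):
                continue
            if not isinstance(key, int):
                raise ConfigurationError(
                    f"change year {key!r} must be an integer year, "
                    f"{NEVER!r} or {UNKNOWN!r}")
            if not STUDY_PERIOD[0] <= key <= STUDY_PERIOD[1]:
                raise ConfigurationError(
                    f"change year {key} outside the study period")
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"change_year_distribution sums to {total}, expected 1")
        if not self.baseline_rate:
            raise ConfigurationError("baseline_rate is empty")
        for outcome, rate in self.baseline_rate.items():
            if rate <= 0:
                raise ConfigurationError(
                    f"baseline_rate[{outcome!r}]={rate} must be positive")
        if len(self.age_rate_multipliers) != MAX_AGE_YEARS:
            raise ConfigurationError(
                f"age_rate_multipliers needs {MAX_AGE_YEARS} values")
        if any(m <= 0 for m in self.age_rate_multipliers):
            raise ConfigurationError("age_rate_multipliers must be positive")
        for name in ("year_trend", "delivery_rr", "true_irr",
                     "elective_irr_ratio"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.los_sd < 0:
            raise ConfigurationError("los_sd must be non-negative")
        for name, risk in self.maternal_risk.items():
            risk.validate(name)

    # -- (de)serialisation --------------------------------------------------

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_end"] = self.study_end.isoformat()
        d["birth_year_range"] = list(self.birth_year_range)
        d["age_rate_multipliers"] = list(self.age_rate_multipliers)
        d["maternal_risk"] = {
            k: dataclasses.asdict(v) for k, v in self.maternal_risk.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "change_year_distribution" in d:
            # YAML may stringify integer keys.
            d["change_year_distribution"] = {
                (int(k) if str(k).isdigit() else k): v
                for k, v in d["change_year_distribution"].items()
            }
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
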