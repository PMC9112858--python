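from datetime import date

import numpy as np
import pandas as pd
import pytest

from citsim import Hospital, MotherBabyRecord, SimConfig


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_children=2000, n_hospitals=10, seed=123)


@pytest.fixture()
def five_hospitals() -> list[Hospital]:
    """Constructed survey: two known change years, one never, one unknown,
    and one early adopter."""
    return [
        Hospital("H001", 2009, 2009),
        Hospital("H002", 2011, 2011),
        Hospital("H003", None, None),       # never adopted
        Hospital("H004", "unknown", 2010),  # survey response missing
        Hospital("H005", 2007, 2007),
    ]


def make_child(child_id="C1", birth=date(2010, 1, 1), delivery="caesarean",
               hospital="H001", ltfu=None, outcome_dates=None,
               caesarean_type="emergency") -> MotherBabyRecord:
    if delivery == "vaginal":
        caesarean_type = None
    return MotherBabyRecord(
        child_id=child_id, mother_id="M1", hospital_id=hospital,
        birth_date=birth, delivery_type=delivery,
        caesarean_type=caesarean_type, ltfu_date=ltfu,
        outcome_dates=outcome_dates or {}, multiple_birth_group=None,
        true_exposure=False)


def two_group_rows(d1, t1, d0, t0, n_per_group=600) -> pd.DataFrame:
    """Person-year rows with exposed/unexposed groups of known totals.

    Events and time are spread over one-event rows (all caesarean, so the
    delivery covariate is constant and drops) so the closed-form rate ratio
    (d1/t1)/(d0/t0) is the analytic oracle for the exposure IRR.
    """
    assert max(d1, d0) <= n_per_group
    rows = []
    for exp_val, d, t in ((1.0, d1, t1), (0.0, d0, t0)):
        for i in range(n_per_group):
            rows.append({
                "child_id": f"c{exp_val}_{i}",
                "birth_year": 2010,
                "age_year": 0,
                "delivery_type": "caesarean",
                "caesarean_type": "emergency",
                "exposure_value": exp_val,
                "time_at_risk": t / n_per_group,
                "event": 1 if i < d else 0,
            })
    return pd.DataFrame(rows)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
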