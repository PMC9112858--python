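"""Model fits against closed-form oracles and recovery checks."""

import numpy as np
import pandas as pd
import pytest

import citsim
from citsim import (ModelSpec, SimConfig, fit_linear_continuous, fit_maternal,
                    fit_poisson_cits, rare_guard, subgroup_interaction)

from conftest import two_group_rows


class TestRareGuard:
    @pytest.mark.parametrize("n,expected", [(199, True), (200, False),
                                            (0, True), (5000, False)])
    def test_threshold_boundary(self, n, expected):
        assert rare_guard(n) is expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rare_guard(-1)

    def test_fit_returns_summary_only_for_rare_outcome(self):
        rows = two_group_rows(d1=30, t1=500, d0=40, t0=800)
        res = fit_poisson_cits(rows)
        assert res.rare_flag
        assert res.effect is None and res.ci95 is None
        assert res.n_events == 70


class TestPoissonOracle:
    @pytest.mark.parametrize("d1,t1,d0,t0", [
        (300, 5000.0, 250, 7500.0),
        (210, 900.0, 400, 900.0),
        (500, 12000.0, 500, 3000.0),
    ])
    def test_two_group_fit_equals_closed_form(self, d1, t1, d0, t0):
        rows = two_group_rows(d1, t1, d0, t0)
        res = fit_poisson_cits(rows, enforce_rare_guard=False)
        oracle = (d1 / t1) / (d0 / t0)
        assert res.effect == pytest.approx(oracle, abs=1e-8)
        assert res.ci95[0] < res.effect < res.ci95[1]

    def test_offset_invariance_under_time_rescaling(self):
        rows = two_group_rows(d1=300, t1=5000.0, d0=250, t0=7500.0)
        res1 = fit_poisson_cits(rows, enforce_rare_guard=False)
        scaled = rows.assign(time_at_risk=rows["time_at_risk"] * 7.3)
        res2 = fit_poisson_cits(scaled, enforce_rare_guard=False)
        assert res2.effect == pytest.approx(res1.effect, rel=1e-8)

    def test_wald_ci_matches_closed_form_two_group(self):
        d1, t1, d0, t0 = 300, 5000.0, 250, 7500.0
        rows = two_group_rows(d1, t1, d0, t0)
        res = fit_poisson_cits(rows, enforce_rare_guard=False)
        se = np.sqrt(1 / d1 + 1 / d0)
        logirr = np.log((d1 / t1) / (d0 / t0))
        assert res.ci95[0] == pytest.approx(np.exp(logirr - 1.959964 * se),
                                            rel=1e-6)
        assert res.ci95[1] == pytest.approx(np.exp(logirr + 1.959964 * se),
                                            rel=1e-6)

    def test_constant_exposure_flagged_inestimable(self):
        rows = two_group_rows(d1=300, t1=5000.0, d0=250, t0=7500.0)
        rows["exposure_value"] = 0.0
        res = fit_poisson_cits(rows, enforce_rare_guard=False)
        assert not res.converged and res.effect is None


class TestProbabilityExposure:
    def test_probability_enters_linearly_on_log_scale(self):
        # two strata with exposure probabilities p and 0: the fitted IRR
        # satisfies rate1/rate0 = exp(p * beta) exactly in the two-cell model
        p = 0.4
        rows = two_group_rows(d1=300, t1=5000.0, d0=250, t0=7500.0)
        rows.loc[rows["exposure_value"] == 1.0, "exposure_value"] = p
        res = fit_poisson_cits(rows, enforce_rare_guard=False)
        rate_ratio = (300 / 5000.0) / (250 / 7500.0)
        assert np.log(res.effect) * p == pytest.approx(np.log(rate_ratio),
                                                       abs=1e-8)


class TestMaternal:
    def _deliveries(self, d1, n1, d0, n0):
        rows = []
        for exp_val, d, n in ((1.0, d1, n1), (0.0, d0, n0)):
            for i in range(n):
                rows.append({"mother_id": f"m{exp_val}_{i}",
                             "delivery_year": 2012,
                             "delivery_type": "caesarean",
                             "exposure_value": exp_val,
                             "flag_morbidity": 1 if i < d else 0})
        return pd.DataFrame(rows)

    def test_crude_risk_ratio_oracle(self):
        d1, n1, d0, n0 = 220, 4000, 410, 5000
        res = fit_maternal(self._deliveries(d1, n1, d0, n0), "morbidity")
        assert res.effect == pytest.approx((d1 / n1) / (d0 / n0), abs=1e-8)

    def test_zero_event_stratum_flagged(self):
        res = fit_maternal(self._deliveries(0, 4000, 410, 5000),
                           "morbidity", enforce_rare_guard=False)
        assert not res.converged

    def test_exposure_rr_recovered_from_simulated_morbidity(self):
        cfg = SimConfig(n_children=150_000, seed=41,
                        maternal_risk={"morbidity":
                                       {"risk_caesarean": 0.0861,
                                        "risk_vaginal": 0.0143,
                                        "exposure_rr": 0.70}})
        hospitals = citsim.generate_hospitals(cfg)
        cohort = citsim.generate_cohort_frame(cfg, hospitals,
                                              outcomes=["asthma"])
        mat = citsim.generate_maternal_frame(cfg, cohort)
        assigned = citsim.assign_exposure_hospital_frame(cohort, hospitals)
        mat["exposure_value"] = assigned["exposure_value"].to_numpy()
        mat = mat[assigned["exposure_status"].to_numpy() == "included"]
        res = fit_maternal(mat, "morbidity")
        assert np.log(res.effect) == pytest.approx(np.log(0.70),
                                                   abs=3 * res.se_log)


class TestLinearContinuous:
    def test_identical_groups_zero_difference(self):
        df = pd.DataFrame({
            "delivery_year": [2010] * 40 + [2011] * 40,
            "delivery_type": ["caesarean"] * 80,
            "exposure_value": ([0.0, 1.0] * 40),
            "los": [3.0] * 80,
        })
        res = fit_linear_continuous(df, "los")
        assert res.effect == pytest.approx(0.0, abs=1e-10)

    def test_known_shift_recovered_exactly(self):
        rng = np.random.default_rng(5)
        n = 400
        year = rng.integers(2008, 2012, n)
        exp_val = rng.integers(0, 2, n).astype(float)
        base = 2.0 + 0.1 * (year - 2008)
        delta = -0.23
        df = pd.DataFrame({
            "delivery_year": year,
            "delivery_type": ["caesarean"] * n,
            "exposure_value": exp_val,
            "los": base + delta * exp_val,  # no noise: OLS identity
        })
        res = fit_linear_continuous(df, "los")
        assert res.effect == pytest.approx(delta, abs=1e-10)

    def test_length_of_stay_ci_covers_true_shift(self):
        # simulated length of stay with a -0.23 day shift under exposure
        covered = 0
        n_reps = 100
        for rep in range(n_reps):
            cfg = SimConfig(n_children=30_000, seed=500 + rep,
                            los_exposure_shift=-0.23)
            hospitals = citsim.generate_hospitals(cfg)
            cohort = citsim.generate_cohort_frame(cfg, hospitals,
                                                  outcomes=["asthma"])
            mat = citsim.generate_maternal_frame(cfg, cohort)
            assigned = citsim.assign_exposure_hospital_frame(cohort,
                                                             hospitals)
            mat["exposure_value"] = assigned["exposure_value"].to_numpy()
            mat = mat[(assigned["exposure_status"] == "included").to_numpy()
                      & (mat["delivery_type"] == "caesarean").to_numpy()]
            res = fit_linear_continuous(mat, "length_of_stay")
            lo, hi = res.ci95
            covered += lo <= -0.23 <= hi
        # binomial 3 SE band around nominal 95% coverage
        assert covered / n_reps >= 0.95 - 3 * np.sqrt(0.95 * 0.05 / n_reps)

    def test_rank_deficiency_flagged(self):
        df = pd.DataFrame({
            "delivery_year": [2010] * 20,
            "delivery_type": ["caesarean"] * 20,
            "exposure_value": [0.0] * 20,
            "los": [3.0] * 20,
        })
        res = fit_linear_continuous(df, "los")
        assert not res.converged


class TestSubgroupInteraction:
    def _rows(self, seed, elective_irr_ratio):
        cfg = SimConfig(n_children=250_000, seed=seed, true_irr=0.8,
                        elective_irr_ratio=elective_irr_ratio,
                        baseline_rate={"asthma": 40.0})
        hospitals = citsim.generate_hospitals(cfg)
        cohort = citsim.generate_cohort_frame(cfg, hospitals,
                                              outcomes=["asthma"])
        assigned = citsim.assign_exposure_hospital_frame(cohort, hospitals)
        return citsim.build_person_year_table(assigned, "asthma",
                                              cfg.study_end)

    def test_null_interaction_within_3se(self):
        res = subgroup_interaction(self._rows(61, 1.0),
                                   ModelSpec(variant="hes"))
        assert res.converged
        assert abs(np.log(res.interaction_ratio)) < 3 * res.interaction_se_log

    def test_differential_subgroup_effect_recovered(self):
        # emergency IRR 0.8, elective IRR 1.2: ratio 1.5
        res = subgroup_interaction(self._rows(62, 1.5),
                                   ModelSpec(variant="hes"))
        assert res.converged
        assert np.log(res.interaction_ratio) == pytest.approx(
            np.log(1.5), abs=3 * res.interaction_se_log)
        assert res.irr_elective > res.irr_emergency

    def test_vaginal_only_rows_rejected(self):
        rows = two_group_rows(d1=300, t1=5000.0, d0=250, t0=7500.0)
        rows["delivery_type"] = "vaginal"
        rows["caesarean_type"] = None
        with pytest.raises(ValueError):
            subgroup_interaction(rows)

    def test_no_exposed_subgroup_flagged(self):
        rows = two_group_rows(d1=300, t1=5000.0, d0=250, t0=7500.0)
        # all exposed rows are emergency: elective subgroup has no exposure
        rows.loc[(rows["exposure_value"] == 0), "caesarean_type"] = \
            "elective"
        rows.loc[(rows["exposure_value"] == 0), "delivery_type"] = \
            "caesarean"
        res = subgroup_interaction(rows)
        assert not res.converged
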