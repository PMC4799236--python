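"""Pre-index prevalence, top-5 ranking, incidence with washout."""

import numpy as np
import pandas as pd
import pytest

import cdburden as cb
from cdburden.burden_clinical import (DAYS_PER_YEAR, compute_incidence,
                                      flag_pre_index_categories,
                                      rate_per_100_person_years,
                                      top5_prevalence)
from cdburden.claims_model import CcsMapping, ConditionDefinition
from helpers import brute_force_incidence, cohort_frame, med, med_frame


def _cohort_one(index="2009-01-01", fu_end="2010-01-01", age=40,
                sex="female"):
    return cohort_frame([("A", "case", "s1", index, fu_end, age, sex,
                          "Northeast")])


def test_pre_index_flag_set_and_index_day_excluded(ccs):
    cohort = _cohort_one()
    medical = med_frame([
        med("A", "2008-12-02", diag="COND.HYPERTENSION"),  # index-30
        med("A", "2009-01-01", diag="COND.DIABETES"),      # index day
    ])
    flags = flag_pre_index_categories(cohort, medical, ccs)
    assert bool(flags.loc["A", "hypertension"])
    assert "metabolic_disorders" not in flags.columns or \
        not bool(flags.loc["A", "metabolic_disorders"])


def test_pre_index_no_claims_all_false(ccs):
    flags = flag_pre_index_categories(_cohort_one(), med_frame([]), ccs)
    assert flags.shape[1] == 0 or not flags.to_numpy().any()


def test_pre_index_unmapped_code_counts_as_unclassified(ccs):
    medical = med_frame([med("A", "2008-12-02", diag="ZZZ.UNKNOWN")])
    flags = flag_pre_index_categories(_cohort_one(), medical, ccs)
    assert bool(flags.loc["A", "unclassified"])


def _children_cohort():
    # 172 children: 43 cases, 129 controls
    rows = []
    for i in range(43):
        rows.append((f"K{i}", "case", f"s{i}", "2009-01-01", "2010-01-01",
                     10, "female", "South"))
    for i in range(129):
        rows.append((f"L{i}", "control", f"s{i % 43}", "2009-01-01",
                     "2010-01-01", 10, "female", "South"))
    return cohort_frame(rows)


def test_top5_percentages_on_children_fixture():
    """Counts 58/35/32/28/27 of 172 children give the expected percentage
    column, ranked by total prevalence."""
    cohort = _children_cohort()
    ids = list(cohort["member_id"])
    cats = ["resp", "metab", "neuro", "skin", "psych", "rare"]
    totals = [58, 35, 32, 28, 27, 3]
    flags = pd.DataFrame(False, index=pd.Index(ids, name="member_id"),
                         columns=cats)
    for cat, k in zip(cats, totals):
        flags.loc[ids[:k], cat] = True
    out = top5_prevalence(flags, cohort)
    kids = out[out["age_stratum"] == "children"]
    assert list(kids["category"]) == ["resp", "metab", "neuro", "skin",
                                      "psych"]
    assert [round(p, 2) for p in kids["pct_total"]] == [33.72, 20.35, 18.60,
                                                        16.28, 15.70]


def test_top5_tie_broken_lexicographically():
    cohort = _children_cohort()
    ids = list(cohort["member_id"])
    flags = pd.DataFrame(False, index=pd.Index(ids, name="member_id"),
                         columns=["bbb", "aaa", "ccc"])
    flags.loc[ids[:5], "bbb"] = True
    flags.loc[ids[:5], "aaa"] = True
    flags.loc[ids[:9], "ccc"] = True
    out = top5_prevalence(flags, cohort)
    kids = out[out["age_stratum"] == "children"]
    assert list(kids["category"]) == ["ccc", "aaa", "bbb"]


def test_top5_all_zero_flags_empty():
    cohort = _children_cohort()
    flags = pd.DataFrame(False,
                         index=pd.Index(cohort["member_id"],
                                        name="member_id"),
                         columns=["x"])
    out = top5_prevalence(flags, cohort)
    assert len(out) == 0


def test_rate_contract_direct_arithmetic():
    assert rate_per_100_person_years(138, 1877.0) == pytest.approx(
        100 * 138 / 1877.0)
    assert np.isnan(rate_per_100_person_years(0, 0.0))


def _cond(name="osteoporosis", population="all"):
    return ConditionDefinition(name, frozenset({f"COND.{name.upper()}"}),
                               population, "other")


def test_washout_removes_member_entirely(config):
    cohort = _cohort_one()
    cond = _cond()
    medical = med_frame([
        med("A", "2008-11-01", diag="COND.OSTEOPOROSIS"),   # pre-index
        med("A", "2009-05-01", diag="COND.OSTEOPOROSIS"),   # post-index
    ])
    res = compute_incidence(cohort, medical, cond, config)
    assert res.events_case == 0
    assert res.person_years_case == 0.0
    # washout monotonicity: removing the pre-index claim restores the event
    res2 = compute_incidence(cohort, medical.iloc[[1]], cond, config)
    assert res2.events_case == 1
    assert res2.person_years_case > 0


def test_unit_person_year_rate(config):
    # event 365.25/366 days after index: closest whole-day approximation
    cohort = _cohort_one(index="2009-01-01", fu_end="2011-01-01")
    medical = med_frame([med("A", "2010-01-01", diag="COND.OSTEOPOROSIS")])
    res = compute_incidence(cohort, medical, _cond(), config)
    assert res.events_case == 1
    assert res.rate_case == pytest.approx(100 * 365.25 / 365, rel=1e-12)


def test_first_event_only_counts_once(config):
    cohort = _cohort_one()
    cond = _cond()
    one = med_frame([med("A", "2009-05-01", diag="COND.OSTEOPOROSIS")])
    many = med_frame([med("A", "2009-05-01", diag="COND.OSTEOPOROSIS"),
                      med("A", "2009-06-01", diag="COND.OSTEOPOROSIS"),
                      med("A", "2009-07-01", diag="COND.OSTEOPOROSIS")])
    a = compute_incidence(cohort, one, cond, config)
    b = compute_incidence(cohort, many, cond, config)
    assert (a.events_case, a.person_years_case) == (b.events_case,
                                                    b.person_years_case)


def test_population_filters_exclude_ineligible(config):
    rows = [("F", "case", "s1", "2009-01-01", "2010-01-01", 30, "female",
             "South"),
            ("M", "control", "s1", "2009-01-01", "2010-01-01", 30, "male",
             "South"),
            ("K", "control", "s1", "2009-01-01", "2010-01-01", 10, "female",
             "South")]
    cohort = cohort_frame(rows)
    medical = med_frame([med(m, "2009-05-01", diag="COND.X")
                         for m in ("F", "M", "K")])
    females = ConditionDefinition("x", frozenset({"COND.X"}), "females",
                                  "other")
    res = compute_incidence(cohort, medical, females, config)
    assert set(res.per_member["member_id"]) == {"F", "K"}
    children = ConditionDefinition("x", frozenset({"COND.X"}),
                                   "children_only", "pediatric")
    res = compute_incidence(cohort, medical, children, config)
    assert set(res.per_member["member_id"]) == {"K"}


def test_incidence_matches_brute_force_on_randomized_fixtures(config):
    """Events and person-days equal a day-by-day scan on 100 random <=20
    member fixtures (washout, first-event, censoring all exercised)."""
    rng = np.random.default_rng(2024)
    cond = _cond("checked")
    code = "COND.CHECKED"
    for trial in range(100):
        n = int(rng.integers(2, 21))
        rows, claims = [], []
        for i in range(n):
            mid = f"m{i}"
            index = (pd.Timestamp("2008-01-01")
                     + pd.Timedelta(days=int(rng.integers(0, 1000))))
            fu = int(rng.integers(183, 500))
            group = "case" if rng.random() < 0.3 else "control"
            rows.append((mid, group, f"s{i % 5}", index,
                         index + pd.Timedelta(days=fu),
                         int(rng.integers(5, 80)), "female", "South"))
            for _ in range(int(rng.integers(0, 4))):
                off = int(rng.integers(-250, 600))
                claims.append(med(mid, index + pd.Timedelta(days=off),
                                  diag=code))
        cohort = cohort_frame(rows)
        medical = med_frame(claims)
        res = compute_incidence(cohort, medical, cond, config)
        oracle = brute_force_incidence(cohort, medical, cond, config)
        assert res.events_case == oracle["case"][0]
        assert res.events_control == oracle["control"][0]
        assert res.person_years_case * DAYS_PER_YEAR == pytest.approx(
            oracle["case"][1], abs=1e-6)
        assert res.person_years_control * DAYS_PER_YEAR == pytest.approx(
            oracle["control"][1], abs=1e-6)
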