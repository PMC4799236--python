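"""CPI adjustment, admission building, PPPM computation."""

import numpy as np
import pandas as pd
import pytest

import cdburden as cb
from cdburden.burden_economic import (CpiTable, adjust_to_2011_dollars,
                                      build_admissions, compute_pppm,
                                      DAYS_PER_MONTH)
from helpers import cohort_frame, med, med_frame, rx, rx_frame


def test_cpi_identity_year():
    cpi = CpiTable({2011: 400.258, 2010: 388.4})
    assert adjust_to_2011_dollars(100.0, 2011, cpi) == pytest.approx(100.0)


def test_cpi_direct_proportion_and_roundtrip():
    cpi = CpiTable({2011: 110.0, 2010: 100.0})
    assert adjust_to_2011_dollars(100.0, 2010, cpi) == pytest.approx(110.0)
    # adjusting then deflating by the same factor is the identity
    back = adjust_to_2011_dollars(110.0, 2010, cpi) / cpi.factor(2010)
    assert back == pytest.approx(110.0, rel=1e-9)
    # adjust then deflate recovers the original to 1e-9
    amt = 123.456
    assert (cpi.adjust(amt, 2010) / cpi.factor(2010)
            == pytest.approx(amt, abs=1e-9))


def test_cpi_missing_year_names_the_year():
    cpi = CpiTable({2011: 400.0})
    with pytest.raises(KeyError, match="2008"):
        cpi.adjust(10.0, 2008)


def test_admissions_shared_stay_id():
    claims = med_frame([
        med("A", "2009-01-01", diag="BG.GEN", setting="inpatient",
            stay="S1", plan=100),
        med("A", "2009-01-03", diag="BG.GEN", setting="inpatient",
            stay="S1", plan=100),
        med("A", "2009-01-05", diag="BG.GEN", setting="inpatient",
            stay="S1", plan=100),
    ])
    adm = build_admissions(claims)
    assert len(adm) == 1
    assert adm.iloc[0]["n_claims"] == 3
    assert adm.iloc[0]["plan_paid"] == pytest.approx(300.0)


def test_admissions_interval_merge_without_stay_id():
    d = pd.Timestamp("2009-01-10")
    adjacent = med_frame([med("A", d, setting="inpatient", diag="X"),
                          med("A", d + pd.Timedelta(days=1),
                              setting="inpatient", diag="X")])
    assert len(build_admissions(adjacent)) == 1
    apart = med_frame([med("A", d, setting="inpatient", diag="X"),
                       med("A", d + pd.Timedelta(days=3),
                           setting="inpatient", diag="X")])
    assert len(build_admissions(apart)) == 2


def test_admissions_exhaustive_interval_merge_oracle():
    """Interval merging matches an exhaustive pairwise scan on random small
    date sets."""
    rng = np.random.default_rng(77)
    for _ in range(30):
        days = sorted(set(rng.integers(0, 15, rng.integers(1, 8)).tolist()))
        dates = [pd.Timestamp("2009-01-01") + pd.Timedelta(days=int(d))
                 for d in days]
        claims = med_frame([med("A", d, setting="inpatient", diag="X")
                            for d in dates])
        # oracle: count breaks where the gap exceeds one day
        expected = 1 + sum(1 for a, b in zip(days, days[1:]) if b - a > 1)
        assert len(build_admissions(claims)) == expected


def test_admissions_empty_input():
    assert len(build_admissions(med_frame([]))) == 0


def _cohort_16mo():
    # 487 days is exactly 16 average months (16 x 30.4375)
    index = pd.Timestamp("2009-01-01")
    fu_end = index + pd.Timedelta(days=487)
    return cohort_frame([("A", "case", "s1", index, fu_end, 40, "female",
                          "South"),
                         ("B", "control", "s1", index, fu_end, 40, "female",
                          "South")])


def test_pppm_visit_rate_and_cost_additivity(cpi_identity):
    """One visit per month at $100 gives ambulatory PPPM 1 and cost PPPM
    100; total = medical + pharmacy exactly."""
    cohort = _cohort_16mo()
    index = pd.Timestamp("2009-01-01")
    claims = [med("A", index + pd.Timedelta(days=30 * k), diag="BG.GEN",
                  setting="physician_office", plan=90, patient=10)
              for k in range(16)]
    medical = med_frame(claims)
    pharmacy = rx_frame([rx("A", "2009-02-01", plan=0, patient=0)])
    out = compute_pppm(cohort, medical, pharmacy, cpi_identity)
    a = out.per_member.set_index("member_id").loc["A"]
    assert a["ambulatory_visits"] == pytest.approx(1.0)
    assert a["physician_office_visits"] == pytest.approx(1.0)
    # $1600 medical + $0 pharmacy over 16 months
    assert a["medical_costs"] == pytest.approx(100.0)
    assert a["pharmacy_costs"] == pytest.approx(0.0)
    assert a["total_costs"] == pytest.approx(a["medical_costs"]
                                             + a["pharmacy_costs"])


def test_pppm_same_day_visits_deduplicated(cpi_identity):
    cohort = _cohort_16mo()
    d = pd.Timestamp("2009-03-03")
    medical = med_frame([
        med("A", d, diag="X", setting="physician_office"),
        med("A", d, diag="Y", setting="physician_office"),
        med("A", d, diag="Z", setting="outpatient_hospital"),
    ])
    out = compute_pppm(cohort, medical, rx_frame([]), cpi_identity)
    a = out.per_member.set_index("member_id").loc["A"]
    assert a["ambulatory_visits"] * 16 == pytest.approx(2.0)
    raw = compute_pppm(cohort, medical, rx_frame([]), cpi_identity,
                       dedup_visits=False)
    a2 = raw.per_member.set_index("member_id").loc["A"]
    assert a2["ambulatory_visits"] * 16 == pytest.approx(3.0)


def test_pppm_scale_invariance(cpi_identity):
    """Doubling follow-up while duplicating every claim into the second half
    leaves the member's PPPM values unchanged."""
    index = pd.Timestamp("2009-01-01")
    fu = 366
    base_rows = [("A", "case", "s1", index, index + pd.Timedelta(days=fu),
                  40, "female", "South"),
                 ("B", "control", "s1", index, index + pd.Timedelta(days=fu),
                  40, "female", "South")]
    doubled_rows = [("A", "case", "s1", index,
                     index + pd.Timedelta(days=2 * fu), 40, "female",
                     "South"),
                    ("B", "control", "s1", index,
                     index + pd.Timedelta(days=2 * fu), 40, "female",
                     "South")]
    claims = [med("A", "2009-02-01", diag="X", setting="physician_office",
                  plan=250),
              med("A", "2009-05-01", diag="X", setting="emergency_department",
                  plan=400)]
    shifted = [med("A", pd.Timestamp(c["service_date"])
                   + pd.Timedelta(days=fu), diag="X",
                   setting=c["setting"], plan=c["plan_paid"])
               for c in claims]
    one = compute_pppm(cohort_frame(base_rows), med_frame(claims),
                       rx_frame([]), cpi_identity)
    two = compute_pppm(cohort_frame(doubled_rows),
                       med_frame(claims + shifted), rx_frame([]),
                       cpi_identity)
    a1 = one.per_member.set_index("member_id").loc["A"]
    a2 = two.per_member.set_index("member_id").loc["A"]
    for m in ("ambulatory_visits", "emergency_department_visits",
              "medical_costs", "total_costs"):
        assert a1[m] == pytest.approx(a2[m], rel=1e-12)


def test_claims_outside_follow_up_never_contribute(cpi_identity):
    cohort = _cohort_16mo()
    medical = med_frame([
        med("A", "2008-12-31", diag="X", setting="physician_office",
            plan=1000),   # day before index
        med("A", "2011-01-01", diag="X", setting="physician_office",
            plan=1000),   # after follow-up end
    ])
    out = compute_pppm(cohort, medical, rx_frame([]), cpi_identity)
    a = out.per_member.set_index("member_id").loc["A"]
    assert a["total_costs"] == 0.0
    assert a["ambulatory_visits"] == 0.0


def test_pppm_costs_inflated_per_service_year():
    cpi = CpiTable({2009: 100.0, 2010: 105.0, 2011: 110.0})
    cohort = _cohort_16mo()
    medical = med_frame([med("A", "2009-02-01", diag="X",
                             setting="physician_office", plan=100)])
    out = compute_pppm(cohort, medical, rx_frame([]), cpi)
    a = out.per_member.set_index("member_id").loc["A"]
    assert a["medical_costs"] * 16 == pytest.approx(100 * 1.10)
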