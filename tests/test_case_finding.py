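"""Case-finding algorithm: CS screen, pituitary classification, index
derivation, enrollment/censoring."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import cdburden as cb
from cdburden.case_finding import (apply_enrollment_criteria, classify_cd,
                                   derive_index_event, derive_index_events,
                                   find_cs_members)
from cdburden.claims_model import ConfigError, PITUITARY_PROCEDURE_SETS
from helpers import med, med_frame, member, members_frame, span, spans_frame


def test_cs_screen_selects_office_claim(config):
    claims = med_frame([med("A", "2008-03-01", diag="255.0")])
    assert find_cs_members(claims, config) == {"A"}


def test_cs_screen_ignores_lab_place_of_service(config):
    claims = med_frame([med("A", "2008-03-01", diag="255.0", pos="81")])
    assert find_cs_members(claims, config) == set()


def test_cs_screen_ignores_claims_outside_identification_window(config):
    claims = med_frame([med("A", "2006-08-15", diag="255.0"),
                        med("B", "2012-02-01", diag="255.0")])
    assert find_cs_members(claims, config) == set()


def test_classify_requires_pituitary_qualifier(config):
    claims = med_frame([
        med("A", "2008-03-01", diag="255.0"),
        med("A", "2008-05-01", proc="PROC.HYPOPHYSECT"),
        med("B", "2008-03-01", diag="255.0"),
    ])
    cs = find_cs_members(claims, config)
    assert cs == {"A", "B"}
    assert classify_cd(cs, claims, config) == {"A"}


def test_classify_is_subset_and_lab_qualifier_rejected(config):
    claims = med_frame([
        med("A", "2008-03-01", diag="255.0"),
        med("A", "2008-05-01", diag="PIT.NEO", pos="81"),  # lab only
    ])
    cs = find_cs_members(claims, config)
    assert classify_cd(cs, claims, config) == set()
    # removing all pituitary-coded claims always empties the CD set
    no_pit = claims[~claims["diagnosis_codes"].str.startswith("PIT")]
    assert classify_cd(find_cs_members(no_pit, config), no_pit, config) == set()


def test_classify_rejects_bad_set_count(config):
    cfg_dict = config.to_dict()
    with pytest.raises(ConfigError):
        bad = dict(cfg_dict["pituitary_sets"])
        bad.pop("bipss")
        cb.AlgorithmConfig.from_dict({**cfg_dict, "pituitary_sets": bad})


def test_classified_fraction_matches_generator(config):
    """On synthetic data the classified/CS fraction recovers the generating
    proportion of pituitary qualifiers (binomial sampling error)."""
    params = cb.SimulationParams(n_members=8000, p_cs_coded=0.30,
                                 p_cd_given_cs=0.15, seed=7)
    members, enrollment, truth = cb.generate_population(params, config)
    claims, truth = cb.generate_cd_signal(members, enrollment, truth,
                                          params, config)
    cs = find_cs_members(claims, config)
    cd = classify_cd(cs, claims, config)
    frac = len(cd) / len(cs)
    se = math.sqrt(0.15 * 0.85 / len(cs))
    assert abs(frac - 0.15) <= 3 * se


def test_index_min_date_and_kinds(config):
    claims = med_frame([med("A", "2008-01-10", diag="255.0"),
                        med("A", "2008-02-01", diag="PIT.NEO")])
    ev = derive_index_event(claims, config)
    assert ev.index_date == pd.Timestamp("2008-01-10")
    assert ev.index_kind == "cs"

    claims = med_frame([med("A", "2007-05-05", diag="PIT.NEO")])
    ev = derive_index_event(claims, config)
    assert ev.index_date == pd.Timestamp("2007-05-05")
    assert ev.index_kind == "pituitary_condition"


def test_index_same_day_tie_prefers_pituitary(config):
    claims = med_frame([med("A", "2008-03-03", diag="255.0"),
                        med("A", "2008-03-03", diag="PIT.NEO")])
    ev = derive_index_event(claims, config)
    assert ev.index_kind == "pituitary_condition"
    assert ev.qualifying_set_name == "pituitary_neoplasm"


def test_index_exhaustive_two_claim_fixtures(config):
    """Exhaustive oracle over all orderings of one CS and one pituitary
    claim: index date is always the min; the label is pituitary iff the
    pituitary claim is on or before the CS claim."""
    dates = [pd.Timestamp("2008-01-01"), pd.Timestamp("2008-06-01")]
    for cs_d, pit_d in itertools.product(dates, dates):
        for set_name in ("pituitary_neoplasm", "hypophysectomy"):
            code = sorted(config.pituitary_sets[set_name])[0]
            kwargs = ({"proc": code}
                      if set_name in PITUITARY_PROCEDURE_SETS
                      else {"diag": code})
            claims = med_frame([med("A", cs_d, diag="255.0"),
                                med("A", pit_d, **kwargs)])
            ev = derive_index_event(claims, config)
            assert ev.index_date == min(cs_d, pit_d)
            if pit_d <= cs_d:
                assert ev.qualifying_set_name == set_name
            else:
                assert ev.index_kind == "cs"


def test_index_monotonicity_under_added_claims(config):
    base = [med("A", "2008-06-01", diag="255.0"),
            med("A", "2008-07-01", diag="PIT.NEO")]
    ev0 = derive_index_event(med_frame(base), config)
    later = med_frame(base + [med("A", "2010-01-01", diag="255.0")])
    assert derive_index_event(later, config).index_date == ev0.index_date
    earlier = med_frame(base + [med("A", "2007-02-02", diag="255.0")])
    assert (derive_index_event(earlier, config).index_date
            == pd.Timestamp("2007-02-02"))


def _events(mid, index, kind="cs"):
    return pd.DataFrame([{"member_id": mid,
                          "index_date": pd.Timestamp(index),
                          "index_kind": kind, "qualifying_set_name": kind}])


def test_enrollment_study_cutoff(config):
    members = members_frame([member("A")])
    spans = spans_frame([span("A", "2007-01-01", "2012-06-30")])
    elig, drops = apply_enrollment_criteria(_events("A", "2008-06-01"),
                                            members, spans, config)
    assert len(elig) == 1
    row = elig.iloc[0]
    assert row["follow_up_end"] == pd.Timestamp("2012-06-30")
    assert row["censor_reason"] == "study_cutoff"
    assert row["follow_up_days"] == (pd.Timestamp("2012-06-30")
                                     - pd.Timestamp("2008-06-01")).days


def test_enrollment_insufficient_post_window(config):
    members = members_frame([member("A")])
    spans = spans_frame([span("A", "2007-01-01", "2008-09-09")])  # idx+100d
    elig, drops = apply_enrollment_criteria(_events("A", "2008-06-01"),
                                            members, spans, config)
    assert len(elig) == 0
    assert drops["insufficient_post_enrollment"] == 1


def test_enrollment_death_censoring(config):
    members = members_frame([member("A", death="2009-07-06")])  # idx+400d
    spans = spans_frame([span("A", "2007-01-01", "2012-06-30")])
    elig, _ = apply_enrollment_criteria(_events("A", "2008-06-01"),
                                        members, spans, config)
    row = elig.iloc[0]
    assert row["censor_reason"] == "death"
    assert row["follow_up_end"] == pd.Timestamp("2009-07-06")
    assert row["follow_up_days"] == 400


def test_enrollment_needs_both_benefits_and_abutting_spans(config):
    members = members_frame([member("A"), member("B"), member("C")])
    spans = spans_frame([
        # A: abutting spans -> one chain, eligible
        span("A", "2007-01-01", "2008-12-31"),
        span("A", "2009-01-01", "2012-06-30"),
        # B: one-day gap -> chain broken at index
        span("B", "2007-01-01", "2008-05-31"),
        span("B", "2008-06-02", "2012-06-30"),
        # C: pharmacy benefit missing
        span("C", "2007-01-01", "2012-06-30", pharmacy=False),
    ])
    events = pd.concat([_events("A", "2008-06-01"), _events("B", "2008-06-01"),
                        _events("C", "2008-06-01")], ignore_index=True)
    elig, drops = apply_enrollment_criteria(events, members, spans, config)
    assert set(elig["member_id"]) == {"A"}
    assert drops["insufficient_pre_enrollment"] == 2


def test_member_without_spans_dropped(config):
    members = members_frame([member("A")])
    spans = spans_frame([])
    elig, drops = apply_enrollment_criteria(_events("A", "2008-06-01"),
                                            members, spans, config)
    assert len(elig) == 0
    assert drops["insufficient_pre_enrollment"] == 1


def test_synthetic_sensitivity_and_specificity(config):
    """Every true-CD member with emitted signal claims is classified; no
    member lacking CS codes ever is."""
    params = cb.SimulationParams(n_members=3000, p_cs_coded=0.1,
                                 p_cd_given_cs=0.3, seed=21)
    members, enrollment, truth = cb.generate_population(params, config)
    claims, truth = cb.generate_cd_signal(members, enrollment, truth,
                                          params, config)
    cs = find_cs_members(claims, config)
    cd = classify_cd(cs, claims, config)
    true_cd = set(truth.loc[truth["status"] == "true_cd", "member_id"])
    background = set(truth.loc[truth["status"] == "background", "member_id"])
    assert cd == true_cd
    assert not (cd & background)
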