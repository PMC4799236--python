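"""Shared fixture builders: tiny claims tables constructed by hand."""

from __future__ import annotations

import numpy as np
import pandas as pd

from cdburden.claims_model import (MEDICAL_COLUMNS, MEMBER_COLUMNS,
                                   PHARMACY_COLUMNS)


def member(member_id, sex="female", birth="1970-06-15", region="Northeast",
           death=None) -> dict:
    return {"member_id": member_id, "sex": sex,
            "birth_date": pd.Timestamp(birth), "region": region,
            "death_date": pd.Timestamp(death) if death else pd.NaT}


def members_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=MEMBER_COLUMNS)
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["death_date"] = pd.to_datetime(df["death_date"])
    return df


def span(member_id, start, end, medical=True, pharmacy=True) -> dict:
    return {"member_id": member_id, "start_date": pd.Timestamp(start),
            "end_date": pd.Timestamp(end), "has_medical": medical,
            "has_pharmacy": pharmacy}


def spans_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["member_id", "start_date", "end_date",
                                     "has_medical", "has_pharmacy"])
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    return df


def med(member_id, date, diag="", proc="", pos="11",
        setting="physician_office", stay="", plan=0.0, patient=0.0) -> dict:
    return {"member_id": member_id, "service_date": pd.Timestamp(date),
            "diagnosis_codes": diag, "procedure_codes": proc,
            "place_of_service": pos, "setting": setting, "stay_id": stay,
            "plan_paid": float(plan), "patient_paid": float(patient)}


def med_frame(rows) -> pd.DataFrame:
    if not rows:
        df = pd.DataFrame(columns=MEDICAL_COLUMNS)
        df["service_date"] = pd.to_datetime(df["service_date"])
        for c in ("plan_paid", "patient_paid"):
            df[c] = df[c].astype(float)
        return df
    df = pd.DataFrame(rows, columns=MEDICAL_COLUMNS)
    df["service_date"] = pd.to_datetime(df["service_date"])
    return df


def rx(member_id, date, drug="NDC.GEN", plan=0.0, patient=0.0) -> dict:
    return {"member_id": member_id, "fill_date": pd.Timestamp(date),
            "drug_code": drug, "plan_paid": float(plan),
            "patient_paid": float(patient)}


def rx_frame(rows) -> pd.DataFrame:
    if not rows:
        df = pd.DataFrame(columns=PHARMACY_COLUMNS)
        df["fill_date"] = pd.to_datetime(df["fill_date"])
        for c in ("plan_paid", "patient_paid"):
            df[c] = df[c].astype(float)
        return df
    df = pd.DataFrame(rows, columns=PHARMACY_COLUMNS)
    df["fill_date"] = pd.to_datetime(df["fill_date"])
    return df


def cohort_frame(rows) -> pd.DataFrame:
    """rows: (member_id, group, set_id, index, fu_end, age, sex, region)."""
    recs = []
    for (mid, group, set_id, index, fu_end, age, sex, region) in rows:
        index, fu_end = pd.Timestamp(index), pd.Timestamp(fu_end)
        recs.append({
            "member_id": mid, "group": group, "match_set_id": set_id,
            "index_date": index, "follow_up_end": fu_end,
            "follow_up_days": int((fu_end - index).days),
            "age_at_index": int(age), "sex": sex, "region": region,
            "index_year": int(index.year)})
    return pd.DataFrame(recs)


def brute_force_incidence(cohort, medical, condition, config):
    """Day-by-day oracle for events and person-days per group."""
    out = {"case": [0, 0], "control": [0, 0]}   # events, person-days
    pop = cohort[condition.population_mask(cohort)]
    for r in pop.itertuples(index=False):
        dates = set(
            medical.loc[(medical["member_id"] == r.member_id)
                        & medical["diagnosis_codes"].fillna("").str.split("|")
                        .map(lambda cs: any(c in condition.codes for c in cs)),
                        "service_date"])
        pre_lo = r.index_date - pd.Timedelta(days=config.pre_days)
        washed = any(pre_lo <= d <= r.index_date - pd.Timedelta(days=1)
                     for d in dates)
        if washed:
            continue
        day = r.index_date
        event = False
        while day <= r.follow_up_end:
            if day in dates:
                event = True
                break
            day += pd.Timedelta(days=1)
        if event:
            out[r.group][0] += 1
            out[r.group][1] += int((day - r.index_date).days)
        else:
            out[r.group][1] += int((r.follow_up_end - r.index_date).days)
    return out
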