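"""Cushing's disease case-finding over coded medical claims.

ICD-9-CM has no unique diagnosis code for Cushing's disease (CD), only for the
broader Cushing's syndrome (CS, 255.0). The algorithm labels a member as a CD
case if, during the identification period, they have

1. at least one medical claim carrying a CS diagnosis code, and
2. at least one claim matching any of eight pituitary condition/procedure
   code sets (neoplasm, hyperfunction, other anterior-pituitary disorder,
   hypothalamic control of the anterior pituitary, diencephalohypophyseal
   syndromes, hypophysectomy, stereotactic radiosurgery, BIPSS).

Claims from laboratories / diagnostic testing centers (by place of service)
are never examined for selection, since they can reflect rule-out testing for
a diagnosis that was never confirmed.

The index date is the first selectable claim date bearing a CS or pituitary
code; eligibility then requires continuous enrollment with medical and
pharmacy benefits over the 183 days before the index and at least 183 days
after, with follow-up censored at the earliest of death, disenrollment, or
the study cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .claims_model import (AlgorithmConfig, ClaimsBundle, ConfigError,
                           PITUITARY_PROCEDURE_SETS, codes_match_any)

INDEX_KINDS = ("cs", "pituitary_condition", "pituitary_procedure")

#: attrition-reason labels for members dropped at the eligibility stage
DROP_PRE = "insufficient_pre_enrollment"
DROP_POST = "insufficient_post_enrollment"


@dataclass(frozen=True)
class IndexEvent:
    member_id: str
    index_date: pd.Timestamp
    index_kind: str
    qualifying_set_name: str


@dataclass(frozen=True)
class EligibleCase:
    member_id: str
    index_event: IndexEvent
    follow_up_end: pd.Timestamp
    follow_up_days: int
    censor_reason: str


def selectable_claims(medical: pd.DataFrame,
                      config: AlgorithmConfig) -> pd.DataFrame:
    """Claims examinable for selection: inside the identification period and
    not from a lab/diagnostic place of service."""
    in_window = medical["service_date"].between(config.id_start, config.id_end)
    not_lab = ~medical["place_of_service"].isin(config.lab_place_of_service)
    return medical[in_window & not_lab]


def find_cs_members(medical: pd.DataFrame,
                    config: AlgorithmConfig) -> set[str]:
    """Members with >=1 selectable claim carrying a CS diagnosis code."""
    sel = selectable_claims(medical, config)
    mask = codes_match_any(sel["diagnosis_codes"], config.cs_codes)
    return set(sel.loc[mask, "member_id"])


def classify_cd(cs_members: set[str], medical: pd.DataFrame,
                config: AlgorithmConfig) -> set[str]:
    """Subset of CS members with >=1 selectable claim matching any of the
    eight pituitary condition/procedure sets."""
    if len(config.pituitary_sets) != 8:
        raise ConfigError("case-finding requires exactly 8 pituitary code sets")
    if not cs_members:
        return set()
    sel = selectable_claims(medical, config)
    sel = sel[sel["member_id"].isin(cs_members)]
    diag = codes_match_any(sel["diagnosis_codes"],
                           config.all_pituitary_diagnosis_codes)
    proc = codes_match_any(sel["procedure_codes"],
                           config.all_pituitary_procedure_codes)
    return set(sel.loc[diag | proc, "member_id"])


def _annotate_selection(sel: pd.DataFrame,
                        config: AlgorithmConfig) -> pd.DataFrame:
    """Attach is_cs and the first matching pituitary set (in config order)."""
    sel = sel.copy()
    sel["is_cs"] = codes_match_any(sel["diagnosis_codes"], config.cs_codes)
    set_name = np.full(len(sel), "", dtype=object)
    for name, codes in config.pituitary_sets.items():
        field = ("procedure_codes" if name in PITUITARY_PROCEDURE_SETS
                 else "diagnosis_codes")
        hit = codes_match_any(sel[field], codes) & (set_name == "")
        set_name[hit] = name
    sel["pituitary_set"] = set_name
    return sel[sel["is_cs"] | (sel["pituitary_set"] != "")]


def derive_index_event(member_claims: pd.DataFrame,
                       config: AlgorithmConfig) -> IndexEvent:
    """Index event for one classified CD member.

    The index date is the earliest selectable claim date bearing a CS or
    pituitary code. When CS and pituitary codes fall on that same day, the
    pituitary condition/procedure labels the event (it is the index CD
    event); among pituitary sets the first in the configured order wins.
    """
    member_id = str(member_claims["member_id"].iloc[0])
    sel = _annotate_selection(selectable_claims(member_claims, config), config)
    if sel.empty:
        raise RuntimeError(
            f"member {member_id}: classified CD but no selectable CS or "
            "pituitary claim found (internal inconsistency)")
    index_date = sel["service_date"].min()
    day = sel[sel["service_date"] == index_date]
    pit = day[day["pituitary_set"] != ""]
    if pit.empty:
        return IndexEvent(member_id, index_date, "cs", "cs")
    order = list(config.pituitary_sets)
    best = min(pit["pituitary_set"], key=order.index)
    kind = ("pituitary_procedure" if best in PITUITARY_PROCEDURE_SETS
            else "pituitary_condition")
    return IndexEvent(member_id, index_date, kind, best)


def derive_index_events(medical: pd.DataFrame, cd_members: set[str],
                        config: AlgorithmConfig) -> pd.DataFrame:
    """Index events for all classified members, as a frame with columns
    member_id, index_date, index_kind, qualifying_set_name."""
    rows = []
    claims = medical[medical["member_id"].isin(cd_members)]
    for mid, grp in claims.groupby("member_id", sort=True):
        ev = derive_index_event(grp, config)
        rows.append((ev.member_id, ev.index_date, ev.index_kind,
                     ev.qualifying_set_name))
    return pd.DataFrame(rows, columns=["member_id", "index_date",
                                       "index_kind", "qualifying_set_name"])


# ---------------------------------------------------------------------------
# enrollment / censoring
# ---------------------------------------------------------------------------

def coverage_intervals(enrollment: pd.DataFrame,
                       gap_days: int = 0) -> pd.DataFrame:
    """Merge spans with both benefits into maximal gap-free coverage
    intervals. Spans abut when the next start is within gap_days+1 days of
    the previous end."""
    spans = enrollment[enrollment["has_medical"] & enrollment["has_pharmacy"]]
    spans = spans.sort_values(["member_id", "start_date", "end_date"])
    if spans.empty:
        return pd.DataFrame(columns=["member_id", "start_date", "end_date"])
    prev_end = spans.groupby("member_id")["end_date"].shift()
    gap = (spans["start_date"] - prev_end).dt.days
    new_chain = prev_end.isna() | (gap > gap_days + 1)
    chain_id = new_chain.cumsum()
    out = spans.groupby(chain_id).agg(
        member_id=("member_id", "first"),
        start_date=("start_date", "min"),
        end_date=("end_date", "max"),
    ).reset_index(drop=True)
    return out


def apply_enrollment_criteria(index_events: pd.DataFrame,
                              members: pd.DataFrame,
                              enrollment: pd.DataFrame,
                              config: AlgorithmConfig,
                              ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the continuous-enrollment and minimum-follow-up criteria.

    Returns an eligible frame (index-event columns plus follow_up_end,
    follow_up_days, censor_reason) and a dict of drop counts by reason.
    follow_up_end = min(end of gap-free coverage, death date, study cutoff);
    eligibility requires coverage of [index - pre_days, index] and
    follow_up_days = (follow_up_end - index).days >= post_min_days.
    """
    drops = {DROP_PRE: 0, DROP_POST: 0}
    if index_events.empty:
        empty = index_events.copy()
        for col in ("follow_up_end", "follow_up_days", "censor_reason"):
            empty[col] = pd.Series(dtype=object)
        return empty, drops

    cov = coverage_intervals(enrollment, config.enrollment_gap_days)
    death = members.set_index("member_id")["death_date"]

    merged = index_events.merge(cov, on="member_id", how="left")
    containing = ((merged["start_date"] <= merged["index_date"])
                  & (merged["index_date"] <= merged["end_date"]))
    merged = merged[containing]

    rows, kept = [], set()
    for r in merged.itertuples(index=False):
        kept.add(r.member_id)
        if r.start_date > r.index_date - pd.Timedelta(days=config.pre_days):
            drops[DROP_PRE] += 1
            continue
        dd = death.get(r.member_id, pd.NaT)
        fue = min(r.end_date, config.study_end)
        reason = ("study_cutoff" if fue == config.study_end else "disenrollment")
        if pd.notna(dd) and dd < fue:
            fue, reason = dd, "death"
        fu_days = int((fue - r.index_date).days)
        if fu_days < config.post_min_days:
            drops[DROP_POST] += 1
            continue
        rows.append((r.member_id, r.index_date, r.index_kind,
                     r.qualifying_set_name, fue, fu_days, reason))

    # index events with no containing coverage interval at all
    drops[DROP_PRE] += int((~index_events["member_id"].isin(kept)).sum())

    eligible = pd.DataFrame(rows, columns=[
        "member_id", "index_date", "index_kind", "qualifying_set_name",
        "follow_up_end", "follow_up_days", "censor_reason"])
    return eligible, drops


def find_cases(bundle: ClaimsBundle, config: AlgorithmConfig,
               ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full case-finding stage: CS screen, pituitary classification, index
    derivation, eligibility. Returns (eligible cases frame, attrition dict).
    """
    cs = find_cs_members(bundle.medical, config)
    cd = classify_cd(cs, bundle.medical, config)
    events = derive_index_events(bundle.medical, cd, config)
    eligible, drops = apply_enrollment_criteria(
        events, bundle.members, bundle.enrollment, config)
    attrition = {
        "total_members": len(bundle.members),
        "cs_coded": len(cs),
        "cs_plus_pituitary": len(cd),
        "enrollment_eligible": len(eligible),
        **drops,
    }
    return eligible, attrition
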