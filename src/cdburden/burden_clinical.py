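"""Pre-index comorbidity prevalence and post-index incidence with washout.

Windows (all in whole days, both ends inclusive):

* pre-index window: ``[index - pre_days, index - 1]`` — the index day itself
  is post-index, since the index CD event occurs on it;
* post-index window: ``[index, follow_up_end]``.

Incidence of a condition is the first post-index claim carrying one of its
codes, among members with no pre-index claim for it (washout). Time at risk
is ``(event_date - index)`` days for events and the full follow-up for
non-events; person-years use 365.25 days, rates are events per 100
person-years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_model import (AlgorithmConfig, CcsMapping, ConditionDefinition,
                           codes_match_any)
from .burden_stats import IrrEstimate, poisson_irr, rao_scott_test

DAYS_PER_YEAR = 365.25


@dataclass
class IncidenceResult:
    """One incidence-table row: per-group events / person-time / rate, with
    the IRR left for the stats layer to fill (see :func:`incidence_table`)."""

    condition: str
    events_case: int
    person_years_case: float
    rate_case: float
    events_control: int
    person_years_control: float
    rate_control: float
    irr: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    per_member: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def rate_per_100_person_years(events: float, person_years: float) -> float:
    """The rate contract: 100 * events / person-time (NaN when pt <= 0)."""
    if person_years <= 0:
        return np.nan
    return 100.0 * events / person_years


def flag_pre_index_categories(cohort: pd.DataFrame, medical: pd.DataFrame,
                              ccs: CcsMapping,
                              pre_days: int = 183) -> pd.DataFrame:
    """Boolean comorbidity-category flags per member over the pre-index
    window. Diagnosis codes not covered by the mapping fall under the
    sentinel ``unclassified`` category."""
    win = cohort[["member_id", "index_date"]].copy()
    win["pre_lo"] = win["index_date"] - pd.Timedelta(days=pre_days)
    win["pre_hi"] = win["index_date"] - pd.Timedelta(days=1)
    claims = medical[["member_id", "service_date", "diagnosis_codes"]]
    merged = claims.merge(win, on="member_id", how="inner")
    merged = merged[(merged["service_date"] >= merged["pre_lo"])
                    & (merged["service_date"] <= merged["pre_hi"])]

    flags = pd.DataFrame(index=pd.Index(cohort["member_id"], name="member_id"))
    if merged.empty:
        return flags
    codes = merged.assign(code=merged["diagnosis_codes"].str.split("|")) \
                  .explode("code")
    codes = codes[codes["code"].fillna("") != ""]
    codes["category"] = ccs.map_series(codes["code"])
    present = (codes.groupby(["member_id", "category"]).size()
               .unstack(fill_value=0) > 0)
    return present.reindex(flags.index, fill_value=False).astype(bool)


def top5_prevalence(flags: pd.DataFrame, cohort: pd.DataFrame,
                    n_top: int = 5) -> pd.DataFrame:
    """Top-N pre-index comorbidity categories for children (<18) and adults.

    Ranking is by total-cohort count, descending, ties broken
    lexicographically by category name; only categories with nonzero counts
    appear. Group percentages use the group sizes within the age stratum;
    p-values come from the Rao-Scott test clustered on match sets.
    """
    meta = cohort.set_index("member_id")
    rows = []
    for stratum, mask in (("children", meta["age_at_index"] < 18),
                          ("adults", meta["age_at_index"] >= 18)):
        ids = meta.index[mask]
        if len(ids) == 0 or flags.empty:
            continue
        sub = flags.reindex(ids).fillna(False)
        totals = sub.sum(axis=0).astype(int)
        totals = totals[totals > 0]
        ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))[:n_top]
        grp = meta.loc[ids, "group"]
        clu = meta.loc[ids, "match_set_id"]
        n_case = int((grp == "case").sum())
        n_control = int((grp == "control").sum())
        for cat, total in ranked:
            fl = sub[cat]
            nc = int(fl[grp == "case"].sum())
            n0 = int(fl[grp == "control"].sum())
            res = rao_scott_test(fl.to_numpy().astype(int),
                                 (grp == "case").to_numpy(),
                                 clu.to_numpy())
            rows.append({
                "age_stratum": stratum, "category": cat,
                "n_total": total,
                "pct_total": 100.0 * total / len(ids),
                "n_case": nc,
                "pct_case": 100.0 * nc / n_case if n_case else np.nan,
                "n_control": n0,
                "pct_control": 100.0 * n0 / n_control if n_control else np.nan,
                "p_value": res.p_value,
            })
    return pd.DataFrame(rows, columns=["age_stratum", "category", "n_total",
                                       "pct_total", "n_case", "pct_case",
                                       "n_control", "pct_control", "p_value"])


def compute_incidence(cohort: pd.DataFrame, medical: pd.DataFrame,
                      condition: ConditionDefinition,
                      config: AlgorithmConfig) -> IncidenceResult:
    """Per-group incidence of one condition with washout.

    Members with a pre-index claim for the condition are excluded from the
    risk set entirely (no events, no person-time). ``per_member`` carries the
    member-level event indicator, days at risk, group and match-set cluster
    for downstream IRR estimation.
    """
    pop = cohort[condition.population_mask(cohort)].copy()
    claims = medical[codes_match_any(medical["diagnosis_codes"],
                                     condition.codes)]
    claims = claims[["member_id", "service_date"]]

    merged = claims.merge(
        pop[["member_id", "index_date", "follow_up_end"]],
        on="member_id", how="inner")
    pre_lo = merged["index_date"] - pd.Timedelta(days=config.pre_days)
    pre_hi = merged["index_date"] - pd.Timedelta(days=1)
    washed = set(merged.loc[(merged["service_date"] >= pre_lo)
                            & (merged["service_date"] <= pre_hi),
                            "member_id"])

    at_risk = pop[~pop["member_id"].isin(washed)].copy()
    post = merged[(~merged["member_id"].isin(washed))
                  & (merged["service_date"] >= merged["index_date"])
                  & (merged["service_date"] <= merged["follow_up_end"])]
    first_event = post.groupby("member_id")["service_date"].min()

    at_risk["event_date"] = at_risk["member_id"].map(first_event)
    at_risk["event"] = at_risk["event_date"].notna().astype(int)
    days = np.where(at_risk["event"] == 1,
                    (at_risk["event_date"] - at_risk["index_date"]).dt.days,
                    at_risk["follow_up_days"])
    at_risk["days_at_risk"] = days.astype(float)

    per_member = at_risk[["member_id", "group", "match_set_id", "event",
                          "days_at_risk"]].reset_index(drop=True)

    def summarize(group: str) -> tuple[int, float, float]:
        sub = per_member[per_member["group"] == group]
        events = int(sub["event"].sum())
        py = float(sub["days_at_risk"].sum()) / DAYS_PER_YEAR
        rate = rate_per_100_person_years(events, py)
        if py <= 0 and len(sub):
            warnings.warn(f"{condition.name}/{group}: zero person-time, "
                          "rate undefined", stacklevel=2)
        return events, py, rate

    e1, py1, r1 = summarize("case")
    e0, py0, r0 = summarize("control")
    return IncidenceResult(condition.name, e1, py1, r1, e0, py0, r0,
                           per_member=per_member)


def incidence_table(cohort: pd.DataFrame, medical: pd.DataFrame,
                    conditions: list[ConditionDefinition],
                    config: AlgorithmConfig) -> pd.DataFrame:
    """Incidence rows for all conditions with cluster-robust IRRs filled in."""
    rows = []
    for cond in conditions:
        res = compute_incidence(cohort, medical, cond, config)
        pm = res.per_member
        irr = IrrEstimate(np.nan, np.nan, np.nan, np.nan, 0)
        positive = pm[pm["days_at_risk"] > 0]
        if len(positive) and positive["group"].nunique() == 2:
            irr = poisson_irr(positive["event"].to_numpy(),
                              positive["days_at_risk"].to_numpy() / DAYS_PER_YEAR,
                              (positive["group"] == "case").to_numpy(),
                              positive["match_set_id"].to_numpy())
        rows.append({
            "condition": cond.name, "category": cond.category,
            "population": cond.population,
            "events_case": res.events_case,
            "person_years_case": res.person_years_case,
            "rate_case": res.rate_case,
            "events_control": res.events_control,
            "person_years_control": res.person_years_control,
            "rate_control": res.rate_control,
            "irr": irr.irr, "ci_low": irr.ci_low, "ci_high": irr.ci_high,
            "p_value": irr.p_value,
        })
    return pd.DataFrame(rows)
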