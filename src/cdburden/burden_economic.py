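"""All-cause per-patient-per-month (PPPM) utilization and costs.

PPPM standardizes to variable follow-up: each member's post-index totals are
divided by their months of follow-up (month = 30.4375 days, the average-month
constant consistent with 365.25-day person-years). Costs are the sum of plan-
and patient-paid amounts, inflation-adjusted to target-year dollars with the
annual medical-care consumer price index before summing. "Ambulatory" is the
outpatient-hospital plus physician-office settings; inpatient utilization is
counted in admissions (stays), not claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .claims_model import ConfigError
from .burden_stats import cluster_robust_mean_test

DAYS_PER_MONTH = 30.4375

COUNT_MEASURES = ["ambulatory_visits", "outpatient_hospital_visits",
                  "physician_office_visits", "emergency_department_visits",
                  "inpatient_admissions"]
COST_MEASURES = ["total_costs", "medical_costs", "pharmacy_costs"]
PPPM_MEASURES = COUNT_MEASURES + COST_MEASURES


@dataclass(frozen=True)
class CpiTable:
    """Annual price index used to restate costs in target-year dollars."""

    values: Mapping[int, float]
    target_year: int = 2011

    def __post_init__(self):
        vals = {int(k): float(v) for k, v in dict(self.values).items()}
        object.__setattr__(self, "values", vals)
        if self.target_year not in vals:
            raise ConfigError(f"CPI table missing target year {self.target_year}")
        if any(v <= 0 for v in vals.values()):
            raise ConfigError("CPI index values must be positive")

    def factor(self, service_year: int) -> float:
        """Multiplier taking service-year dollars to target-year dollars."""
        year = int(service_year)
        if year not in self.values:
            raise KeyError(f"CPI table has no index value for year {year}")
        return self.values[self.target_year] / self.values[year]

    def adjust(self, amount: float, service_year: int) -> float:
        return float(amount) * self.factor(service_year)

    def factor_series(self, years: pd.Series) -> pd.Series:
        missing = sorted(set(years.astype(int)) - set(self.values))
        if missing:
            raise KeyError(f"CPI table has no index value for year {missing[0]}")
        tgt = self.values[self.target_year]
        return years.astype(int).map(lambda y: tgt / self.values[y])

    @classmethod
    def identity(cls, years=range(2006, 2013),
                 target_year: int = 2011) -> "CpiTable":
        return cls({y: 1.0 for y in years}, target_year)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CpiTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw.get("values", {}), int(raw.get("target_year", 2011)))


def adjust_to_2011_dollars(amount: float, service_year: int,
                           cpi: CpiTable) -> float:
    """amount x index(target year) / index(service year)."""
    return cpi.adjust(amount, service_year)


def build_admissions(inpatient_claims: pd.DataFrame) -> pd.DataFrame:
    """Collapse inpatient claims into admissions (stays).

    Claims sharing a ``stay_id`` form one admission. Claims lacking a stay id
    fall back to interval merging: per member, service dates overlapping or
    adjacent (gap <= 1 day) merge into one stay. Returns one row per
    admission with admit/discharge dates and total paid amounts.
    """
    cols = ["member_id", "admit_date", "discharge_date", "n_claims",
            "plan_paid", "patient_paid"]
    if inpatient_claims.empty:
        return pd.DataFrame(columns=cols)
    claims = inpatient_claims.copy()
    claims["stay_id"] = claims["stay_id"].fillna("").astype(str)

    parts = []
    keyed = claims[claims["stay_id"] != ""]
    if len(keyed):
        agg = keyed.groupby(["member_id", "stay_id"]).agg(
            admit_date=("service_date", "min"),
            discharge_date=("service_date", "max"),
            n_claims=("service_date", "size"),
            plan_paid=("plan_paid", "sum"),
            patient_paid=("patient_paid", "sum"),
        ).reset_index().drop(columns=["stay_id"])
        parts.append(agg)

    loose = claims[claims["stay_id"] == ""].sort_values(
        ["member_id", "service_date"])
    if len(loose):
        prev = loose.groupby("member_id")["service_date"].shift()
        new_stay = prev.isna() | ((loose["service_date"] - prev).dt.days > 1)
        stay = new_stay.cumsum()
        agg = loose.groupby(stay).agg(
            member_id=("member_id", "first"),
            admit_date=("service_date", "min"),
            discharge_date=("service_date", "max"),
            n_claims=("service_date", "size"),
            plan_paid=("plan_paid", "sum"),
            patient_paid=("patient_paid", "sum"),
        ).reset_index(drop=True)
        parts.append(agg)

    out = pd.concat(parts, ignore_index=True)[cols]
    return out.sort_values(["member_id", "admit_date"]).reset_index(drop=True)


@dataclass
class PppmTable:
    """Member-level PPPM values plus group summaries with clustered p-values."""

    per_member: pd.DataFrame
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def _window_claims(claims: pd.DataFrame, cohort: pd.DataFrame,
                   date_col: str) -> pd.DataFrame:
    merged = claims.merge(
        cohort[["member_id", "index_date", "follow_up_end"]],
        on="member_id", how="inner")
    return merged[(merged[date_col] >= merged["index_date"])
                  & (merged[date_col] <= merged["follow_up_end"])]


def compute_pppm(cohort: pd.DataFrame, medical: pd.DataFrame,
                 pharmacy: pd.DataFrame, cpi: CpiTable,
                 dedup_visits: bool = True) -> PppmTable:
    """PPPM utilization counts and costs per member, with group summaries.

    Visit counts (ambulatory and emergency-department) count one visit per
    member-date-setting when ``dedup_visits`` (default); inpatient admissions
    come from :func:`build_admissions` (counted at the admit date). Member
    total cost = medical + pharmacy exactly. Only claims inside
    ``[index, follow_up_end]`` contribute.
    """
    idx = pd.Index(cohort["member_id"], name="member_id")
    pm = pd.DataFrame(0.0, index=idx, columns=PPPM_MEASURES)

    med = _window_claims(medical, cohort, "service_date")
    rx = _window_claims(pharmacy, cohort, "fill_date")

    # --- visit counts ---------------------------------------------------
    outp = med[med["setting"].isin({"outpatient_hospital", "physician_office",
                                    "emergency_department"})]
    visits = (outp[["member_id", "service_date", "setting"]]
              .drop_duplicates() if dedup_visits
              else outp[["member_id", "service_date", "setting"]])
    counts = (visits.groupby(["member_id", "setting"]).size()
              .unstack(fill_value=0))
    for setting, col in (("outpatient_hospital", "outpatient_hospital_visits"),
                         ("physician_office", "physician_office_visits"),
                         ("emergency_department",
                          "emergency_department_visits")):
        if setting in counts.columns:
            pm[col] = pm[col].add(counts[setting], fill_value=0.0)
    pm["ambulatory_visits"] = (pm["outpatient_hospital_visits"]
                               + pm["physician_office_visits"])

    inpat = med[med["setting"] == "inpatient"]
    admissions = build_admissions(inpat.drop(
        columns=["index_date", "follow_up_end"]))
    if len(admissions):
        n_adm = admissions.groupby("member_id").size()
        pm["inpatient_admissions"] = pm["inpatient_admissions"].add(
            n_adm, fill_value=0.0)

    # --- costs (inflation-adjusted per service year) ---------------------
    if len(med):
        paid = (med["plan_paid"] + med["patient_paid"]) \
            * cpi.factor_series(med["service_date"].dt.year).to_numpy()
        pm["medical_costs"] = pm["medical_costs"].add(
            paid.groupby(med["member_id"]).sum(), fill_value=0.0)
    if len(rx):
        paid = (rx["plan_paid"] + rx["patient_paid"]) \
            * cpi.factor_series(rx["fill_date"].dt.year).to_numpy()
        pm["pharmacy_costs"] = pm["pharmacy_costs"].add(
            paid.groupby(rx["member_id"]).sum(), fill_value=0.0)
    pm["total_costs"] = pm["medical_costs"] + pm["pharmacy_costs"]

    months = (cohort.set_index("member_id")["follow_up_days"]
              / DAYS_PER_MONTH)
    pm = pm.div(months, axis=0)
    pm["months"] = months

    meta = cohort.set_index("member_id")[["group", "match_set_id"]]
    per_member = pm.join(meta).reset_index()

    rows = []
    grp = (per_member["group"] == "case").to_numpy()
    clu = per_member["match_set_id"].to_numpy()
    for measure in PPPM_MEASURES:
        vals = per_member[measure].to_numpy()
        case, ctrl = vals[grp], vals[~grp]
        p = np.nan
        if len(case) and len(ctrl) and len(per_member) >= 2:
            try:
                p = cluster_robust_mean_test(vals, grp, clu).p_value
            except ValueError:
                p = np.nan
        rows.append({
            "measure": measure,
            "mean_case": case.mean() if len(case) else np.nan,
            "sd_case": case.std(ddof=1) if len(case) > 1 else np.nan,
            "median_case": float(np.median(case)) if len(case) else np.nan,
            "mean_control": ctrl.mean() if len(ctrl) else np.nan,
            "sd_control": ctrl.std(ddof=1) if len(ctrl) > 1 else np.nan,
            "median_control": float(np.median(ctrl)) if len(ctrl) else np.nan,
            "p_value": p,
        })
    return PppmTable(per_member, pd.DataFrame(rows))
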