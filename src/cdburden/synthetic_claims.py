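"""Seeded synthetic administrative-claims generator with known ground truth.

Emulates the structure of a large US commercial health-plan research
database: member demographics (~75% female, age 42 +/- 14, region mix
16/37/36/10), enrollment churn with disenrollment and death, a CS-coded
subpopulation of which a minority carries pituitary qualifiers, elevated
post-index comorbidity hazards for cases, and heavier utilization/costs for
cases. Because every member's true status (true CD / CS-only / background),
every condition's true rate ratio, and every group's true mean monthly cost
are knowable by construction, the full pipeline is testable without any real
data.

Randomness: one generator stream per stage, derived from the master seed by
a fixed stage label, so adding or re-running a later stage never perturbs an
earlier one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .claims_model import (AlgorithmConfig, ClaimsBundle, ConditionDefinition,
                           ConfigError, PITUITARY_PROCEDURE_SETS, REGIONS,
                           default_algorithm_config, default_conditions)
from .burden_economic import CpiTable, DAYS_PER_MONTH

STAGES = ("population", "cd_signal", "outcomes", "costs")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent stream for one generation stage of a master seed."""
    key = STAGES.index(stage)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=(key,)))


#: per-condition simulation settings: control-group hazard (first events per
#: person-year) and true case:control rate ratio. Defaults echo the burden
#: profile of hypercortisolism cohorts (ratios roughly 2-5, pediatric
#: weight-gain higher).
DEFAULT_CONDITION_RATES: dict[str, tuple[float, float]] = {
    "osteoporosis": (0.014, 5.0),
    "muscle_weakness": (0.0045, 7.5),
    "cardiovascular_disease": (0.038, 3.7),
    "hypertension": (0.079, 2.9),
    "diabetes": (0.023, 5.2),
    "dyslipidemia": (0.116, 2.0),
    "obesity": (0.028, 3.7),
    "menstrual_abnormality": (0.087, 2.0),
    "depression": (0.043, 2.6),
    "anxiety": (0.052, 2.3),
    "infections": (0.038, 2.2),
    "abnormal_weight_gain": (0.010, 9.0),
}

#: monthly visit rates per group and setting (ambulatory split, ED,
#: inpatient admissions) echoing the utilization profile of a CD cohort.
DEFAULT_VISIT_RATES: dict[str, dict[str, float]] = {
    "case": {"outpatient_hospital": 0.87, "physician_office": 1.76,
             "emergency_department": 0.12, "inpatient": 0.04,
             "pharmacy": 1.5},
    "control": {"outpatient_hospital": 0.22, "physician_office": 0.66,
                "emergency_department": 0.04, "inpatient": 0.01,
                "pharmacy": 0.7},
}

#: mean cost per visit/fill (target-year dollars) per group and setting.
DEFAULT_COST_MEANS: dict[str, dict[str, float]] = {
    "case": {"outpatient_hospital": 900.0, "physician_office": 700.0,
             "emergency_department": 800.0, "inpatient": 17000.0,
             "pharmacy": 288.0},
    "control": {"outpatient_hospital": 500.0, "physician_office": 230.0,
                "emergency_department": 550.0, "inpatient": 10000.0,
                "pharmacy": 150.0},
}

_BACKGROUND_CODES = ("BG.RESP", "BG.URO", "BG.MSK", "BG.SKIN", "BG.NEURO",
                     "BG.PSY", "BG.GEN")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic-claims world; defaults are the study
    conditions the generator emulates."""

    n_members: int = 5000
    p_female: float = 0.7526
    age_mean: float = 42.0
    age_sd: float = 14.0
    region_probs: tuple[float, float, float, float] = (0.16, 0.37, 0.36, 0.10)
    p_cs_coded: float = 0.02
    p_cd_given_cs: float = 0.15
    lab_qualifier_frac: float = 0.10
    p_enrolled_at_start: float = 0.6
    disenrollment_hazard: float = 0.18   # per person-year
    death_hazard: float = 0.004          # per person-year
    p_split_span: float = 0.10
    condition_rates: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_RATES))
    pre_claim_frac_case: float = 0.16
    pre_claim_frac_control: float = 0.08
    visit_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v)
                                 for g, v in DEFAULT_VISIT_RATES.items()})
    cost_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v)
                                 for g, v in DEFAULT_COST_MEANS.items()})
    cost_sigma: float = 1.0              # log-normal scale of per-visit cost
    seed: int = 0

    def __post_init__(self):
        for name in ("p_female", "p_cs_coded", "p_cd_given_cs",
                     "lab_qualifier_frac", "p_enrolled_at_start",
                     "p_split_span", "pre_claim_frac_case",
                     "pre_claim_frac_control"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.disenrollment_hazard < 0 or self.death_hazard < 0:
            raise ConfigError("hazards must be >= 0")
        probs = np.asarray(self.region_probs, dtype=float)
        if probs.min() < 0 or probs.sum() <= 0:
            raise ConfigError("region_probs must be nonnegative, nonzero sum")
        object.__setattr__(self, "region_probs",
                           tuple(probs / probs.sum()))

    def rate_for(self, name: str, group: str) -> float:
        base, ratio = self.condition_rates[name]
        return base * ratio if group == "case" else base

    def implied_pppm_means(self) -> dict[str, dict[str, float]]:
        """True mean PPPM costs per group implied by the cost parameters."""
        out = {}
        for g in ("case", "control"):
            med = sum(self.visit_rates[g][s] * self.cost_means[g][s]
                      for s in ("outpatient_hospital", "physician_office",
                                "emergency_department", "inpatient"))
            rx = self.visit_rates[g]["pharmacy"] * self.cost_means[g]["pharmacy"]
            out[g] = {"medical": med, "pharmacy": rx, "total": med + rx}
        return out


@dataclass
class GroundTruth:
    """Per-member truth plus the generating parameters' true effect sizes."""

    members: pd.DataFrame       # member_id, status, group, index_date, cov_*
    condition_ratios: dict[str, float]
    pppm_means: dict[str, dict[str, float]]

    def status_counts(self) -> dict[str, int]:
        return self.members["status"].value_counts().to_dict()


_MED_COLS = ["member_id", "service_date", "diagnosis_codes",
             "procedure_codes", "place_of_service", "setting", "stay_id",
             "plan_paid", "patient_paid"]
_RX_COLS = ["member_id", "fill_date", "drug_code", "plan_paid", "patient_paid"]


def _med_frame(**cols) -> pd.DataFrame:
    n = len(cols["member_id"])
    base = {"diagnosis_codes": "", "procedure_codes": "",
            "place_of_service": "11", "setting": "physician_office",
            "stay_id": "", "plan_paid": 0.0, "patient_paid": 0.0}
    data = {}
    for c in _MED_COLS:
        v = cols.get(c, base.get(c))
        data[c] = (np.repeat(v, n) if np.isscalar(v) or isinstance(v, str)
                   else v)
    return pd.DataFrame(data)


def _uniform_dates(rng: np.random.Generator, lo: pd.Series,
                   hi: pd.Series) -> pd.Series:
    """One uniform whole-day date per row inside [lo, hi] (inclusive)."""
    span = (hi - lo).dt.days.to_numpy()
    off = np.floor(rng.random(len(span)) * (span + 1)).astype(int)
    return lo + pd.to_timedelta(off, unit="D")


# ---------------------------------------------------------------------------
# stage 1: population
# ---------------------------------------------------------------------------

def generate_population(params: SimulationParams,
                        config: AlgorithmConfig | None = None,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Members, enrollment spans and initial truth statuses.

    Deterministic given the seed. Every member gets one contiguous coverage
    period (possibly emitted as two abutting spans) inside the study window;
    disenrollment and death are exponential with the configured hazards.
    """
    config = config or default_algorithm_config()
    rng = rng or stage_rng(params.seed, "population")
    n = int(params.n_members)

    member_id = np.array([f"M{i:07d}" for i in range(n)])
    sex = np.where(rng.random(n) < params.p_female, "female", "male")
    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), 1.0, 90.0)
    birth = (config.study_start
             - pd.to_timedelta(np.round(age * 365.25).astype(int), unit="D"))
    region = rng.choice(REGIONS, size=n, p=params.region_probs)

    study_days = (config.study_end - config.study_start).days
    at_start = rng.random(n) < params.p_enrolled_at_start
    entry_off = np.where(
        at_start, 0,
        np.floor(rng.random(n) * max(study_days - 365, 1)).astype(int))
    entry = pd.Series(config.study_start + pd.to_timedelta(entry_off, unit="D"))

    if params.disenrollment_hazard > 0:
        dur = np.maximum(
            1, np.round(rng.exponential(1.0 / params.disenrollment_hazard, n)
                        * 365.25)).astype(int)
        end = entry + pd.to_timedelta(dur, unit="D")
        end = end.where(end <= config.study_end, config.study_end)
    else:
        end = pd.Series([config.study_end] * n)

    death_date = pd.Series([pd.NaT] * n, dtype="datetime64[ns]")
    if params.death_hazard > 0:
        t_death = np.round(rng.exponential(1.0 / params.death_hazard, n)
                           * 365.25)
        # cap far-future draws before date arithmetic; anything beyond the
        # study horizon is unobserved anyway
        t_death = np.minimum(t_death, 30000).astype(int)
        cand = entry + pd.to_timedelta(t_death, unit="D")
        observed = cand <= end
        death_date = cand.where(observed, pd.NaT)
        end = end.where(~observed, cand)

    members = pd.DataFrame({
        "member_id": member_id, "sex": sex, "birth_date": birth,
        "region": region, "death_date": death_date.to_numpy()})

    # emit one span, or two abutting spans for a fraction of members, so the
    # gap-free chain logic is exercised
    span_len = (end - entry).dt.days.to_numpy()
    split = (rng.random(n) < params.p_split_span) & (span_len >= 60)
    cut_off = np.floor(30 + rng.random(n) * np.maximum(span_len - 60, 1)
                       ).astype(int)
    rows = {"member_id": [], "start_date": [], "end_date": []}
    entry_np, end_np = entry.to_numpy(), end.to_numpy()
    day = np.timedelta64(1, "D")
    for i in range(n):
        if split[i]:
            cut = entry_np[i] + cut_off[i] * day
            rows["member_id"] += [member_id[i], member_id[i]]
            rows["start_date"] += [entry_np[i], cut + day]
            rows["end_date"] += [cut, end_np[i]]
        else:
            rows["member_id"].append(member_id[i])
            rows["start_date"].append(entry_np[i])
            rows["end_date"].append(end_np[i])
    enrollment = pd.DataFrame(rows)
    enrollment["has_medical"] = True
    enrollment["has_pharmacy"] = True

    u = rng.random(n)
    cs_coded = u < params.p_cs_coded
    cd = cs_coded & (rng.random(n) < params.p_cd_given_cs)
    status = np.where(cd, "true_cd", np.where(cs_coded, "cs_only",
                                              "background"))
    truth = pd.DataFrame({
        "member_id": member_id, "status": status,
        "group": np.where(cd, "case", "control"),
        "index_date": pd.NaT,
        "cov_start": entry.to_numpy(), "cov_end": end.to_numpy()})
    truth["index_date"] = pd.to_datetime(truth["index_date"])
    return members, enrollment, truth


# ---------------------------------------------------------------------------
# stage 2: CS / pituitary signal claims
# ---------------------------------------------------------------------------

def generate_cd_signal(members: pd.DataFrame, enrollment: pd.DataFrame,
                       truth: pd.DataFrame, params: SimulationParams,
                       config: AlgorithmConfig | None = None,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CS- and pituitary-coded medical claims for the CS subpopulation.

    Every true-CD member whose coverage intersects the identification period
    receives >=1 CS claim and >=1 pituitary-qualifier claim inside that
    intersection; CS-only members receive the CS claim but no qualifier. A
    configurable fraction additionally receives lab-place-of-service claims
    carrying qualifying codes, which the case-finding algorithm must ignore.
    Members whose coverage misses the identification period are downgraded to
    background in the returned truth (truth stays consistent with claims).
    """
    config = config or default_algorithm_config()
    rng = rng or stage_rng(params.seed, "cd_signal")
    truth = truth.copy()

    lo = truth["cov_start"].where(truth["cov_start"] > config.id_start,
                                  config.id_start)
    hi = truth["cov_end"].where(truth["cov_end"] < config.id_end,
                                config.id_end)
    valid = lo <= hi
    coded = truth["status"].isin(["true_cd", "cs_only"])
    downgrade = coded & ~valid
    truth.loc[downgrade, ["status", "group"]] = ["background", "control"]
    coded = truth["status"].isin(["true_cd", "cs_only"])

    claims = []
    cs_code = sorted(config.cs_codes)[0]
    sub = truth[coded]
    cs_date = _uniform_dates(rng, lo[coded], hi[coded])
    claims.append(_med_frame(member_id=sub["member_id"].to_numpy(),
                             service_date=cs_date.to_numpy(),
                             diagnosis_codes=cs_code,
                             plan_paid=120.0, patient_paid=25.0))
    truth.loc[coded, "index_date"] = cs_date.to_numpy()

    is_cd = truth["status"] == "true_cd"
    if is_cd.any():
        names = list(config.pituitary_sets)
        pick = rng.integers(0, len(names), int(is_cd.sum()))
        codes = np.array([sorted(config.pituitary_sets[names[k]])[0]
                          for k in pick])
        is_proc = np.array([names[k] in PITUITARY_PROCEDURE_SETS
                            for k in pick])
        pit_date = _uniform_dates(rng, lo[is_cd], hi[is_cd])
        claims.append(_med_frame(
            member_id=truth.loc[is_cd, "member_id"].to_numpy(),
            service_date=pit_date.to_numpy(),
            diagnosis_codes=np.where(is_proc, "", codes),
            procedure_codes=np.where(is_proc, codes, ""),
            setting=np.where(is_proc, "outpatient_hospital",
                             "physician_office"),
            place_of_service=np.where(is_proc, "22", "11"),
            plan_paid=400.0, patient_paid=50.0))
        truth.loc[is_cd, "index_date"] = np.minimum(
            truth.loc[is_cd, "index_date"].to_numpy(), pit_date.to_numpy())

    # adversarial lab claims: pituitary qualifiers at a lab place of service
    lab_pos = sorted(config.lab_place_of_service)[0]
    lab = coded & (rng.random(len(truth)) < params.lab_qualifier_frac)
    if lab.any():
        names = list(config.condition_sets)
        pick = rng.integers(0, len(names), int(lab.sum()))
        codes = np.array([sorted(config.condition_sets[names[k]])[0]
                          for k in pick])
        lab_date = _uniform_dates(rng, lo[lab], hi[lab])
        claims.append(_med_frame(
            member_id=truth.loc[lab, "member_id"].to_numpy(),
            service_date=lab_date.to_numpy(),
            diagnosis_codes=codes,
            place_of_service=lab_pos,
            setting="outpatient_hospital",
            plan_paid=60.0, patient_paid=0.0))

    medical = (pd.concat(claims, ignore_index=True) if claims
               else _med_frame(member_id=np.array([], dtype=object)))
    return medical, truth


# ---------------------------------------------------------------------------
# stage 3: outcome (comorbidity) claims and background index anchors
# ---------------------------------------------------------------------------

def generate_outcome_claims(members: pd.DataFrame, enrollment: pd.DataFrame,
                            truth: pd.DataFrame,
                            conditions: list[ConditionDefinition] | None = None,
                            params: SimulationParams | None = None,
                            config: AlgorithmConfig | None = None,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Post-index first-event comorbidity claims plus background claims.

    Background members get one anchor claim (their control index date) inside
    the identification period; a configurable per-group fraction of members
    gets a pre-index claim per condition (exercising washout); first post-
    index event times per condition are exponential with group-specific
    hazards, emitted only while the member is enrolled and inside the study
    window. Returns (claims, truth-with-index-dates).
    """
    params = params or SimulationParams()
    config = config or default_algorithm_config()
    conditions = conditions if conditions is not None else default_conditions()
    rng = rng or stage_rng(params.seed, "outcomes")
    truth = truth.copy()

    unknown = [c.name for c in conditions
               if c.name not in params.condition_rates]
    if unknown:
        raise ConfigError(f"no simulation rates for condition(s): {unknown}")

    claims = []
    bg = (truth["status"] == "background") & truth["index_date"].isna()
    lo = truth["cov_start"].where(truth["cov_start"] > config.id_start,
                                  config.id_start)
    hi = truth["cov_end"].where(truth["cov_end"] < config.id_end,
                                config.id_end)
    anchor_ok = bg & (lo <= hi)
    if anchor_ok.any():
        anchor = _uniform_dates(rng, lo[anchor_ok], hi[anchor_ok])
        codes = rng.choice(_BACKGROUND_CODES, int(anchor_ok.sum()))
        claims.append(_med_frame(
            member_id=truth.loc[anchor_ok, "member_id"].to_numpy(),
            service_date=anchor.to_numpy(), diagnosis_codes=codes,
            plan_paid=90.0, patient_paid=15.0))
        truth.loc[anchor_ok, "index_date"] = anchor.to_numpy()

    has_index = truth["index_date"].notna()
    sub = truth[has_index].reset_index(drop=True)
    if len(sub):
        mem = members.set_index("member_id")
        birth = sub["member_id"].map(mem["birth_date"])
        age = (sub["index_date"] - birth).dt.days / 365.25
        female = sub["member_id"].map(mem["sex"]).eq("female").to_numpy()
        child = (age < 18).to_numpy()
        is_case = (sub["group"] == "case").to_numpy()
        claim_end = sub["cov_end"].where(sub["cov_end"] < config.study_end,
                                         config.study_end)

        for cond in conditions:
            if cond.population == "females":
                elig = female
            elif cond.population in ("children", "children_only"):
                elig = child
            elif cond.population == "adults":
                elig = ~child
            else:
                elig = np.ones(len(sub), dtype=bool)

            code = sorted(cond.codes)[0]

            # washout-exercising pre-index claims; for control members these
            # must predate the identification window, otherwise they would
            # redefine the control's first-claim index date
            pre_frac = np.where(is_case, params.pre_claim_frac_case,
                                params.pre_claim_frac_control)
            pre = elig & (rng.random(len(sub)) < pre_frac)
            pre_lo = sub["index_date"] - pd.Timedelta(days=config.pre_days)
            pre_lo = pre_lo.where(pre_lo > sub["cov_start"], sub["cov_start"])
            pre_hi = sub["index_date"] - pd.Timedelta(days=1)
            cap = config.id_start - pd.Timedelta(days=1)
            pre_hi = pre_hi.mask(~is_case & (pre_hi > cap), cap)
            pre &= (pre_lo <= pre_hi).to_numpy()
            if pre.any():
                dates = _uniform_dates(rng, pre_lo[pre], pre_hi[pre])
                claims.append(_med_frame(
                    member_id=sub.loc[pre, "member_id"].to_numpy(),
                    service_date=dates.to_numpy(), diagnosis_codes=code,
                    plan_paid=85.0, patient_paid=15.0))

            # first post-index event: exponential, rounded up to whole days
            rate = np.where(is_case,
                            params.rate_for(cond.name, "case"),
                            params.rate_for(cond.name, "control"))
            with np.errstate(divide="ignore"):
                t_years = rng.exponential(1.0, len(sub)) / np.where(
                    rate > 0, rate, np.inf)
            days = np.ceil(t_years * 365.25)
            ok = elig & np.isfinite(days) & (days <= 30000)
            dates = sub["index_date"] + pd.to_timedelta(
                np.where(ok, days, 0).astype(int), unit="D")
            ok &= (dates <= claim_end).to_numpy()
            if ok.any():
                claims.append(_med_frame(
                    member_id=sub.loc[ok, "member_id"].to_numpy(),
                    service_date=dates[ok].to_numpy(), diagnosis_codes=code,
                    plan_paid=85.0, patient_paid=15.0))

    medical = (pd.concat(claims, ignore_index=True) if claims
               else _med_frame(member_id=np.array([], dtype=object)))
    return medical, truth


# ---------------------------------------------------------------------------
# stage 4: utilization / cost claims
# ---------------------------------------------------------------------------

def generate_cost_claims(members: pd.DataFrame, enrollment: pd.DataFrame,
                         truth: pd.DataFrame,
                         params: SimulationParams | None = None,
                         config: AlgorithmConfig | None = None,
                         cpi: CpiTable | None = None,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-cause utilization and cost claims over each member's follow-up.

    Visit counts per setting are Poisson with group-specific monthly rates;
    per-visit costs are log-normal around group/setting means expressed in
    target-year dollars. When a CPI table is supplied, emitted amounts are
    deflated to nominal service-year dollars so that the pipeline's inflation
    adjustment restates them at the intended level. Returns
    (medical claims, pharmacy claims).
    """
    params = params or SimulationParams()
    config = config or default_algorithm_config()
    rng = rng or stage_rng(params.seed, "costs")

    sub = truth[truth["index_date"].notna()].reset_index(drop=True)
    end = sub["cov_end"].where(sub["cov_end"] < config.study_end,
                               config.study_end)
    days = (end - sub["index_date"]).dt.days.to_numpy()
    keep = days > 0
    sub, end, days = sub[keep].reset_index(drop=True), end[keep], days[keep]
    months = days / DAYS_PER_MONTH
    is_case = (sub["group"] == "case").to_numpy()

    med_parts, rx_parts = [], []

    def _emit(setting: str) -> tuple[np.ndarray, pd.Series, np.ndarray]:
        """Poisson visit counts -> (member row idx, dates, costs)."""
        rate = np.where(is_case, params.visit_rates["case"][setting],
                        params.visit_rates["control"][setting])
        n = rng.poisson(rate * months)
        rows = np.repeat(np.arange(len(sub)), n)
        off = np.floor(rng.random(len(rows))
                       * (days[rows] + 1)).astype(int)
        dates = (sub.loc[rows, "index_date"].reset_index(drop=True)
                 + pd.to_timedelta(off, unit="D"))
        mean = np.where(is_case[rows], params.cost_means["case"][setting],
                        params.cost_means["control"][setting])
        sig = params.cost_sigma
        cost = rng.lognormal(np.log(mean) - sig ** 2 / 2.0, sig)
        return rows, dates, cost

    def _deflate(cost: np.ndarray, dates: pd.Series) -> np.ndarray:
        if cpi is None:
            return cost
        return cost / cpi.factor_series(dates.dt.year).to_numpy()

    pos = {"outpatient_hospital": "22", "physician_office": "11",
           "emergency_department": "23"}
    for setting in ("outpatient_hospital", "physician_office",
                    "emergency_department"):
        rows, dates, cost = _emit(setting)
        cost = _deflate(cost, dates)
        med_parts.append(_med_frame(
            member_id=sub.loc[rows, "member_id"].to_numpy(),
            service_date=dates.to_numpy(),
            diagnosis_codes="BG.GEN",
            place_of_service=pos[setting], setting=setting,
            plan_paid=cost * 0.9, patient_paid=cost * 0.1))

    # inpatient admissions: two facility claims per stay sharing a stay_id
    rows, dates, cost = _emit("inpatient")
    if len(rows):
        los = 1 + rng.poisson(2.0, len(rows))
        admit = dates
        discharge = admit + pd.to_timedelta(los, unit="D")
        limit = end.iloc[rows].reset_index(drop=True)
        discharge = discharge.where(discharge <= limit, limit)
        stay_ids = np.array([f"{m}-A{j}" for j, m in
                             enumerate(sub.loc[rows, "member_id"])])
        half = _deflate(cost, admit) / 2.0
        half2 = _deflate(cost, discharge) / 2.0
        for d, c in ((admit, half), (discharge, half2)):
            med_parts.append(_med_frame(
                member_id=sub.loc[rows, "member_id"].to_numpy(),
                service_date=d.to_numpy(), diagnosis_codes="BG.GEN",
                place_of_service="21", setting="inpatient",
                stay_id=stay_ids, plan_paid=c * 0.9, patient_paid=c * 0.1))

    rows, dates, cost = _emit("pharmacy")
    cost = _deflate(cost, dates)
    rx_parts.append(pd.DataFrame({
        "member_id": sub.loc[rows, "member_id"].to_numpy(),
        "fill_date": dates.to_numpy(), "drug_code": "NDC.GEN",
        "plan_paid": cost * 0.9, "patient_paid": cost * 0.1}))

    medical = pd.concat(med_parts, ignore_index=True)[_MED_COLS]
    pharmacy = pd.concat(rx_parts, ignore_index=True)[_RX_COLS]
    if pharmacy.empty:
        pharmacy = pharmacy.astype({"fill_date": "datetime64[ns]"})
    return medical, pharmacy


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def generate_dataset(params: SimulationParams,
                     config: AlgorithmConfig | None = None,
                     conditions: list[ConditionDefinition] | None = None,
                     cpi: CpiTable | None = None,
                     ) -> tuple[ClaimsBundle, GroundTruth]:
    """Full four-table synthetic dataset plus ground truth."""
    config = config or default_algorithm_config()
    conditions = conditions if conditions is not None else default_conditions()
    members, enrollment, truth = generate_population(params, config)
    signal, truth = generate_cd_signal(members, enrollment, truth, params,
                                       config)
    outcomes, truth = generate_outcome_claims(members, enrollment, truth,
                                              conditions, params, config)
    costs_med, pharmacy = generate_cost_claims(members, enrollment, truth,
                                               params, config, cpi)
    medical = pd.concat([signal, outcomes, costs_med], ignore_index=True)
    medical = medical.sort_values(["member_id", "service_date"],
                                  kind="mergesort").reset_index(drop=True)
    pharmacy = pharmacy.sort_values(["member_id", "fill_date"],
                                    kind="mergesort").reset_index(drop=True)
    bundle = ClaimsBundle(members, enrollment, medical, pharmacy)
    gt = GroundTruth(truth,
                     {k: v[1] for k, v in params.condition_rates.items()},
                     params.implied_pppm_means())
    return bundle, gt


def make_matched_cohort(n_sets: int, ratio: int = 3,
                        params: SimulationParams | None = None,
                        config: AlgorithmConfig | None = None,
                        seed: int = 0,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                   pd.DataFrame]:
    """Directly construct a matched cohort with members/enrollment/truth.

    A stage-level harness for the burden modules: ``n_sets`` match sets of
    one case and ``ratio`` exactly-matched controls, with index dates inside
    the identification period and follow-up already satisfying eligibility.
    Returns (members, enrollment, truth, cohort).
    """
    params = params or SimulationParams()
    config = config or default_algorithm_config()
    rng = np.random.default_rng(seed)

    per_set = 1 + ratio
    n = n_sets * per_set
    set_idx = np.repeat(np.arange(n_sets), per_set)
    is_case = (np.arange(n) % per_set) == 0

    age = rng.integers(20, 65, n_sets)[set_idx]
    sex = np.where(rng.random(n_sets) < params.p_female,
                   "female", "male")[set_idx]
    region = rng.choice(REGIONS, n_sets, p=params.region_probs)[set_idx]

    id_days = (config.id_end - config.id_start).days
    idx_off = np.floor(rng.random(n_sets) * (id_days + 1)).astype(int)[set_idx]
    index_date = config.id_start + pd.to_timedelta(idx_off, unit="D")

    max_fu = (config.study_end - index_date).days.to_numpy()
    fu_frac = rng.random(n)
    fu_days = (config.post_min_days
               + np.floor(fu_frac * np.maximum(
                   max_fu - config.post_min_days, 0) + 0.5).astype(int))
    fu_days = np.minimum(fu_days, max_fu)
    follow_up_end = index_date + pd.to_timedelta(fu_days, unit="D")

    member_id = np.array([f"C{i:06d}" for i in range(n)])
    birth = index_date - pd.to_timedelta(
        (age * 365.25 + 100).astype(int), unit="D")
    members = pd.DataFrame({
        "member_id": member_id, "sex": sex, "birth_date": birth.to_numpy(),
        "region": region,
        "death_date": pd.Series([pd.NaT] * n, dtype="datetime64[ns]")})
    start = index_date - pd.Timedelta(days=config.pre_days)
    enrollment = pd.DataFrame({
        "member_id": member_id, "start_date": start.to_numpy(),
        "end_date": follow_up_end.to_numpy(),
        "has_medical": True, "has_pharmacy": True})
    truth = pd.DataFrame({
        "member_id": member_id,
        "status": np.where(is_case, "true_cd", "background"),
        "group": np.where(is_case, "case", "control"),
        "index_date": index_date.to_numpy(),
        "cov_start": start.to_numpy(), "cov_end": follow_up_end.to_numpy()})
    cohort = pd.DataFrame({
        "member_id": member_id,
        "group": np.where(is_case, "case", "control"),
        "match_set_id": np.array([f"set_{k:05d}" for k in set_idx]),
        "index_date": index_date.to_numpy(),
        "follow_up_end": follow_up_end.to_numpy(),
        "follow_up_days": fu_days,
        "age_at_index": age, "sex": sex, "region": region,
        "index_year": index_date.year.to_numpy()})
    return members, enrollment, truth, cohort


def with_seed(params: SimulationParams, seed: int) -> SimulationParams:
    return replace(params, seed=int(seed))
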