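"""CD-free control selection and seeded 1:k exact matching.

Controls are members with no CS or pituitary-coded claim anywhere in the
study period (the exclusion scan deliberately includes lab claims: any such
code disqualifies, for control purity), at least one medical claim during the
identification period (its first date is the control's index date), and the
same continuous-enrollment / minimum-follow-up requirements as cases.

Matching is exact on (age at index in completed years, sex, region, index
year), 1 case : ``ratio`` controls, controls drawn uniformly without
replacement within the stratum, cases processed in seeded random order. A
case with fewer than ``ratio`` available controls is reported unmatched and
dropped; its tentative controls stay in the pool.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .claims_model import (AlgorithmConfig, ClaimsBundle, ConfigError,
                           codes_match_any)
from .case_finding import apply_enrollment_criteria

COHORT_COLUMNS = ["member_id", "group", "match_set_id", "index_date",
                  "follow_up_end", "follow_up_days", "age_at_index",
                  "sex", "region", "index_year"]


def age_at(index_date: pd.Series, birth_date: pd.Series) -> pd.Series:
    """Completed years of age at the index date."""
    before_birthday = ((index_date.dt.month * 100 + index_date.dt.day)
                       < (birth_date.dt.month * 100 + birth_date.dt.day))
    return (index_date.dt.year - birth_date.dt.year
            - before_birthday.astype(int)).astype(int)


def cd_excluded_members(medical: pd.DataFrame,
                        config: AlgorithmConfig) -> set[str]:
    """Members with any CS or pituitary code during the study period.

    No lab exemption here: a rule-out claim still disqualifies a control.
    """
    claims = medical[medical["service_date"].between(config.study_start,
                                                     config.study_end)]
    diag = codes_match_any(claims["diagnosis_codes"],
                           config.cs_codes | config.all_pituitary_diagnosis_codes)
    proc = codes_match_any(claims["procedure_codes"],
                           config.all_pituitary_procedure_codes)
    return set(claims.loc[diag | proc, "member_id"])


def identify_control_pool(bundle: ClaimsBundle, config: AlgorithmConfig,
                          ) -> pd.DataFrame:
    """Candidate controls with index dates, follow-up, and match covariates."""
    excluded = cd_excluded_members(bundle.medical, config)
    med = bundle.medical
    in_id = med[med["service_date"].between(config.id_start, config.id_end)]
    in_id = in_id[~in_id["member_id"].isin(excluded)]
    first = (in_id.groupby("member_id")["service_date"].min()
             .rename("index_date").reset_index())
    first["index_kind"] = "control"
    first["qualifying_set_name"] = ""
    eligible, _ = apply_enrollment_criteria(first, bundle.members,
                                            bundle.enrollment, config)
    return attach_demographics(eligible, bundle.members)


def attach_demographics(frame: pd.DataFrame,
                        members: pd.DataFrame) -> pd.DataFrame:
    """Add sex, region, age_at_index, index_year to an indexed frame."""
    out = frame.merge(members[["member_id", "sex", "birth_date", "region"]],
                      on="member_id", how="left")
    if len(out):
        out["age_at_index"] = age_at(out["index_date"], out["birth_date"])
        out["index_year"] = out["index_date"].dt.year.astype(int)
    else:
        out["age_at_index"] = pd.Series(dtype=int)
        out["index_year"] = pd.Series(dtype=int)
    return out.drop(columns=["birth_date"])


_STRATUM = ["age_at_index", "sex", "region", "index_year"]


def match_controls(cases: pd.DataFrame, pool: pd.DataFrame, ratio: int,
                   seed: int) -> tuple[pd.DataFrame, list[str]]:
    """Seeded greedy 1:ratio exact matching.

    ``cases`` and ``pool`` carry the stratum covariates plus index/follow-up
    columns. Returns (cohort frame, list of unmatched case member_ids). The
    cohort satisfies: every match set has exactly one case and ``ratio``
    controls, all identical on the stratum covariates; no member is reused.
    """
    if ratio < 1:
        raise ConfigError("match ratio must be >= 1")
    rng = np.random.default_rng(seed)

    pool = pool[~pool["member_id"].isin(set(cases["member_id"]))]
    strata: dict[tuple, list[int]] = {
        key: list(grp.index) for key, grp in pool.groupby(_STRATUM, sort=True)}

    order = rng.permutation(len(cases))
    rows, unmatched = [], []
    for pos in order:
        case = cases.iloc[pos]
        key = (int(case["age_at_index"]), case["sex"], case["region"],
               int(case["index_year"]))
        avail = strata.get(key, [])
        if len(avail) < ratio:
            unmatched.append(str(case["member_id"]))
            continue
        picked = rng.choice(len(avail), size=ratio, replace=False)
        chosen = [avail[i] for i in picked]
        strata[key] = [ix for j, ix in enumerate(avail) if j not in set(picked)]
        set_id = f"set_{case['member_id']}"
        rows.append(_cohort_row(case, "case", set_id))
        for ix in chosen:
            rows.append(_cohort_row(pool.loc[ix], "control", set_id))

    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    if len(cohort):
        cohort = cohort.sort_values(["match_set_id", "group", "member_id"],
                                    ).reset_index(drop=True)
    return cohort, sorted(unmatched)


def _cohort_row(rec: pd.Series, group: str, set_id: str) -> tuple:
    return (str(rec["member_id"]), group, set_id, rec["index_date"],
            rec["follow_up_end"], int(rec["follow_up_days"]),
            int(rec["age_at_index"]), rec["sex"], rec["region"],
            int(rec["index_year"]))


def build_cohort(bundle: ClaimsBundle, eligible_cases: pd.DataFrame,
                 config: AlgorithmConfig, seed: int,
                 ) -> tuple[pd.DataFrame, dict]:
    """Pool identification + matching; returns (cohort, report dict)."""
    cases = attach_demographics(eligible_cases, bundle.members)
    pool = identify_control_pool(bundle, config)
    cohort, unmatched = match_controls(cases, pool, config.match_ratio, seed)
    n_case = int((cohort["group"] == "case").sum()) if len(cohort) else 0
    report = {
        "eligible_cases": len(cases),
        "control_pool": len(pool),
        "matched_cases": n_case,
        "matched_controls": int((cohort["group"] == "control").sum())
        if len(cohort) else 0,
        "unmatched_cases": unmatched,
    }
    return cohort, report
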