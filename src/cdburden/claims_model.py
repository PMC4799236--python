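"""Claims data model: the four administrative-claims tables, configuration
types, reading/writing, and dataset validation.

The package works with four delimited-text tables, mirroring the layout of a
commercial health-plan research database:

* ``members`` — one row per enrollee (demographics, optional death date),
* ``enrollment`` — coverage spans with medical/pharmacy benefit flags,
* ``medical_claims`` — professional and facility claims with diagnosis and
  procedure codes, site of service, setting, and paid amounts,
* ``pharmacy_claims`` — outpatient drug fills.

Tables are held as :class:`pandas.DataFrame` inside a :class:`ClaimsBundle`.
Multi-code fields (diagnosis/procedure codes on a medical claim) are stored as
pipe-delimited strings; codes are normalized (trimmed, uppercased, dots kept)
once at load time so downstream matching is exact-string.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml


class SchemaError(ValueError):
    """A required column is missing or a table cannot be interpreted."""


class RowParseError(ValueError):
    """A row-level value (typically a date) could not be parsed."""


class ConfigError(ValueError):
    """An algorithm/condition/CPI configuration violates its invariants."""


# ---------------------------------------------------------------------------
# code normalization
# ---------------------------------------------------------------------------

def normalize_code(code: str) -> str:
    """Normalize a single code: strip whitespace, uppercase. Dots are kept."""
    return str(code).strip().upper()


def normalize_code_field(value: str) -> str:
    """Normalize a pipe-delimited multi-code field."""
    if value is None or value != value or value == "":
        return ""
    toks = [normalize_code(t) for t in str(value).split("|") if t.strip()]
    return "|".join(toks)


def split_codes(value: str) -> list[str]:
    if not value or value != value:
        return []
    return [t for t in str(value).split("|") if t]


def codes_match_any(code_field: pd.Series, code_set: frozenset[str]) -> np.ndarray:
    """Boolean mask: does the pipe-delimited field share a code with ``code_set``?"""
    if not code_set:
        return np.zeros(len(code_field), dtype=bool)
    vals = code_field.fillna("").to_numpy()
    out = np.empty(len(vals), dtype=bool)
    for i, v in enumerate(vals):
        out[i] = bool(v) and any(tok in code_set for tok in v.split("|"))
    return out


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

#: The eight pituitary condition/procedure rule sets of the case-finding
#: algorithm, in fixed order. The first five are conditions (matched against
#: diagnosis codes); the last three are procedures (matched against procedure
#: codes).
PITUITARY_SET_NAMES: tuple[str, ...] = (
    "pituitary_neoplasm",
    "hyperfunction",
    "other_anterior_pituitary_disorder",
    "hypothalamic_control_anterior_pituitary",
    "diencephalohypophyseal_syndromes",
    "hypophysectomy",
    "stereotactic_radiosurgery",
    "bipss",
)

PITUITARY_PROCEDURE_SETS: frozenset[str] = frozenset(
    {"hypophysectomy", "stereotactic_radiosurgery", "bipss"}
)


def _ts(value) -> pd.Timestamp:
    ts = pd.Timestamp(value)
    return ts.normalize()


@dataclass(frozen=True)
class AlgorithmConfig:
    """Code sets and temporal parameters of the case-finding algorithm.

    The shipped default code values are documented placeholders (symbolic
    tokens); real deployments override them from a YAML config. The single
    default Cushing's syndrome diagnosis code is ``255.0``.
    """

    cs_codes: frozenset[str] = frozenset({"255.0"})
    pituitary_sets: Mapping[str, frozenset[str]] = field(default_factory=dict)
    lab_place_of_service: frozenset[str] = frozenset({"81"})
    study_start: pd.Timestamp = _ts("2006-07-01")
    study_end: pd.Timestamp = _ts("2012-06-30")
    id_start: pd.Timestamp = _ts("2007-01-01")
    id_end: pd.Timestamp = _ts("2011-12-31")
    pre_days: int = 183
    post_min_days: int = 183
    match_ratio: int = 3
    enrollment_gap_days: int = 0

    def __post_init__(self):
        object.__setattr__(self, "cs_codes",
                           frozenset(normalize_code(c) for c in self.cs_codes))
        sets = {str(k): frozenset(normalize_code(c) for c in v)
                for k, v in dict(self.pituitary_sets).items()}
        if not sets:
            sets = {name: frozenset({_DEFAULT_PITUITARY_CODES[name]})
                    for name in PITUITARY_SET_NAMES}
        object.__setattr__(self, "pituitary_sets", sets)
        object.__setattr__(self, "lab_place_of_service",
                           frozenset(normalize_code(c)
                                     for c in self.lab_place_of_service))
        for f in ("study_start", "study_end", "id_start", "id_end"):
            object.__setattr__(self, f, _ts(getattr(self, f)))
        if len(self.pituitary_sets) != 8:
            raise ConfigError(
                f"exactly 8 pituitary code sets required, got {len(self.pituitary_sets)}")
        unknown = set(self.pituitary_sets) - set(PITUITARY_SET_NAMES)
        if unknown:
            raise ConfigError(f"unknown pituitary set names: {sorted(unknown)}")
        if not (self.study_start <= self.id_start <= self.id_end <= self.study_end):
            raise ConfigError("identification window must be nested in study window")
        if self.pre_days <= 0 or self.post_min_days <= 0:
            raise ConfigError("pre_days and post_min_days must be positive")
        if self.match_ratio < 1:
            raise ConfigError("match_ratio must be >= 1")
        if self.enrollment_gap_days < 0:
            raise ConfigError("enrollment_gap_days must be >= 0")

    @property
    def condition_sets(self) -> dict[str, frozenset[str]]:
        """Pituitary *condition* sets, matched against diagnosis codes."""
        return {k: v for k, v in self.pituitary_sets.items()
                if k not in PITUITARY_PROCEDURE_SETS}

    @property
    def procedure_sets(self) -> dict[str, frozenset[str]]:
        """Pituitary *procedure* sets, matched against procedure codes."""
        return {k: v for k, v in self.pituitary_sets.items()
                if k in PITUITARY_PROCEDURE_SETS}

    @property
    def all_pituitary_diagnosis_codes(self) -> frozenset[str]:
        out: set[str] = set()
        for v in self.condition_sets.values():
            out |= v
        return frozenset(out)

    @property
    def all_pituitary_procedure_codes(self) -> frozenset[str]:
        out: set[str] = set()
        for v in self.procedure_sets.values():
            out |= v
        return frozenset(out)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AlgorithmConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AlgorithmConfig":
        kwargs = {}
        for key in ("cs_codes", "lab_place_of_service"):
            if key in raw:
                kwargs[key] = frozenset(str(c) for c in raw[key])
        if "pituitary_sets" in raw:
            kwargs["pituitary_sets"] = {
                str(k): frozenset(str(c) for c in v)
                for k, v in raw["pituitary_sets"].items()}
        for key in ("study_start", "study_end", "id_start", "id_end"):
            if key in raw:
                kwargs[key] = _ts(raw[key])
        for key in ("pre_days", "post_min_days", "match_ratio",
                    "enrollment_gap_days"):
            if key in raw:
                kwargs[key] = int(raw[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "cs_codes": sorted(self.cs_codes),
            "pituitary_sets": {k: sorted(v) for k, v in self.pituitary_sets.items()},
            "lab_place_of_service": sorted(self.lab_place_of_service),
            "study_start": str(self.study_start.date()),
            "study_end": str(self.study_end.date()),
            "id_start": str(self.id_start.date()),
            "id_end": str(self.id_end.date()),
            "pre_days": self.pre_days,
            "post_min_days": self.post_min_days,
            "match_ratio": self.match_ratio,
            "enrollment_gap_days": self.enrollment_gap_days,
        }


# Placeholder (symbolic) codes for the eight rule sets. Real ICD-9/CPT/HCPCS
# values are licensing/lookup concerns of the deployment and are supplied via
# config; nothing in the package logic depends on these literals.
_DEFAULT_PITUITARY_CODES = {
    "pituitary_neoplasm": "PIT.NEO",
    "hyperfunction": "PIT.HYPER",
    "other_anterior_pituitary_disorder": "PIT.ANT.OTH",
    "hypothalamic_control_anterior_pituitary": "PIT.HYPOTHAL",
    "diencephalohypophyseal_syndromes": "PIT.DIENCEPH",
    "hypophysectomy": "PROC.HYPOPHYSECT",
    "stereotactic_radiosurgery": "PROC.SRS",
    "bipss": "PROC.BIPSS",
}

VALID_POPULATIONS = {"all", "adults", "children", "children_only", "females"}
VALID_CATEGORIES = {"musculoskeletal", "cardiovascular", "endocrine_metabolic",
                    "mental_health", "other", "pediatric"}


@dataclass(frozen=True)
class ConditionDefinition:
    """A comorbidity/complication tracked in the incidence analysis."""

    name: str
    codes: frozenset[str]
    population: str = "all"
    category: str = "other"

    def __post_init__(self):
        object.__setattr__(self, "codes",
                           frozenset(normalize_code(c) for c in self.codes))
        if not self.codes:
            raise ConfigError(f"condition {self.name!r}: empty code set")
        if self.population not in VALID_POPULATIONS:
            raise ConfigError(f"condition {self.name!r}: bad population "
                              f"{self.population!r}")
        if self.category not in VALID_CATEGORIES:
            raise ConfigError(f"condition {self.name!r}: bad category "
                              f"{self.category!r}")

    def population_mask(self, cohort: pd.DataFrame) -> np.ndarray:
        """Row mask over a cohort frame for this condition's population."""
        age = cohort["age_at_index"].to_numpy()
        if self.population == "all":
            return np.ones(len(cohort), dtype=bool)
        if self.population == "adults":
            return age >= 18
        if self.population in ("children", "children_only"):
            return age < 18
        if self.population == "females":
            return (cohort["sex"] == "female").to_numpy()
        raise AssertionError(self.population)


def load_conditions(path: str | Path) -> list[ConditionDefinition]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    out = []
    for item in raw:
        out.append(ConditionDefinition(
            name=str(item["name"]),
            codes=frozenset(str(c) for c in item["codes"]),
            population=str(item.get("population", "all")),
            category=str(item.get("category", "other")),
        ))
    return out


class CcsMapping:
    """Diagnosis-code → broad comorbidity-category mapping.

    Mirrors the interface of a clinical-classification grouper: a total
    function on the codes it covers, with every unmapped code collapsing to
    the sentinel category ``unclassified``. The shipped table is a toy mapping
    over the package's symbolic codes; a licensed grouper table can be dropped
    in as a two-column CSV (code,category).
    """

    UNCLASSIFIED = "unclassified"

    def __init__(self, mapping: Mapping[str, str]):
        self._map = {normalize_code(k): str(v) for k, v in mapping.items()}

    def category(self, code: str) -> str:
        return self._map.get(normalize_code(code), self.UNCLASSIFIED)

    def categories(self) -> set[str]:
        return set(self._map.values())

    def map_series(self, codes: pd.Series) -> pd.Series:
        return codes.map(self._map).fillna(self.UNCLASSIFIED)

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CcsMapping":
        df = pd.read_csv(path, dtype=str)
        for col in ("code", "category"):
            if col not in df.columns:
                raise SchemaError(f"CCS mapping file missing column {col!r}")
        return cls(dict(zip(df["code"], df["category"])))


def packaged_config(name: str) -> Path:
    """Path to a config file shipped inside the package (toy defaults)."""
    return Path(str(resources.files("cdburden").joinpath("configs", name)))


def default_algorithm_config() -> AlgorithmConfig:
    return AlgorithmConfig.from_yaml(packaged_config("algorithm.yaml"))


def default_conditions() -> list[ConditionDefinition]:
    return load_conditions(packaged_config("conditions.yaml"))


def default_ccs_mapping() -> CcsMapping:
    return CcsMapping.from_csv(packaged_config("ccs_map.csv"))


# ---------------------------------------------------------------------------
# the four tables
# ---------------------------------------------------------------------------

MEMBER_COLUMNS = ["member_id", "sex", "birth_date", "region", "death_date"]
ENROLLMENT_COLUMNS = ["member_id", "start_date", "end_date",
                      "has_medical", "has_pharmacy"]
MEDICAL_COLUMNS = ["member_id", "service_date", "diagnosis_codes",
                   "procedure_codes", "place_of_service", "setting",
                   "stay_id", "plan_paid", "patient_paid"]
PHARMACY_COLUMNS = ["member_id", "fill_date", "drug_code",
                    "plan_paid", "patient_paid"]

VALID_SETTINGS = {"outpatient_hospital", "physician_office",
                  "emergency_department", "inpatient"}
REGIONS = ("Midwest", "Northeast", "South", "West")


@dataclass
class ClaimsBundle:
    """The four parsed claims tables."""

    members: pd.DataFrame
    enrollment: pd.DataFrame
    medical: pd.DataFrame
    pharmacy: pd.DataFrame

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (len(self.members), len(self.enrollment),
                len(self.medical), len(self.pharmacy))

    def copy(self) -> "ClaimsBundle":
        return ClaimsBundle(self.members.copy(), self.enrollment.copy(),
                            self.medical.copy(), self.pharmacy.copy())


def _require_columns(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r}: missing column(s) {missing}")


def _parse_dates(df: pd.DataFrame, col: str, table: str,
                 required: bool) -> pd.Series:
    raw = df[col].fillna("").astype(str).str.strip()
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & (raw != "")
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowParseError(
            f"table {table!r}, line {i + 2}: unparseable date "
            f"{raw.iloc[i]!r} in column {col!r}")
    if required and (raw == "").any():
        i = int(np.flatnonzero((raw == "").to_numpy())[0])
        raise RowParseError(
            f"table {table!r}, line {i + 2}: missing date in column {col!r}")
    return parsed


def _parse_bool(df: pd.DataFrame, col: str) -> pd.Series:
    return (df[col].astype(str).str.strip().str.lower()
            .isin({"true", "1", "t", "yes", "y"}))


def read_claims_tables(members_path: str | Path,
                       enrollment_path: str | Path,
                       medical_path: str | Path,
                       pharmacy_path: str | Path) -> ClaimsBundle:
    """Read and parse the four CSV tables into a :class:`ClaimsBundle`.

    Dates must be ISO-8601 (``YYYY-MM-DD``); multi-code fields are
    pipe-delimited; codes are normalized on load.
    """
    members = pd.read_csv(members_path, dtype=str, keep_default_na=False)
    _require_columns(members, MEMBER_COLUMNS, "members")
    members = members[MEMBER_COLUMNS].copy()
    members["birth_date"] = _parse_dates(members, "birth_date", "members", True)
    members["death_date"] = _parse_dates(members, "death_date", "members", False)

    enrollment = pd.read_csv(enrollment_path, dtype=str, keep_default_na=False)
    _require_columns(enrollment, ENROLLMENT_COLUMNS, "enrollment")
    enrollment = enrollment[ENROLLMENT_COLUMNS].copy()
    for col in ("start_date", "end_date"):
        enrollment[col] = _parse_dates(enrollment, col, "enrollment", True)
    for col in ("has_medical", "has_pharmacy"):
        enrollment[col] = _parse_bool(enrollment, col)

    medical = pd.read_csv(medical_path, dtype=str, keep_default_na=False)
    _require_columns(medical, MEDICAL_COLUMNS, "medical_claims")
    medical = medical[MEDICAL_COLUMNS].copy()
    medical["service_date"] = _parse_dates(medical, "service_date",
                                           "medical_claims", True)
    for col in ("diagnosis_codes", "procedure_codes"):
        medical[col] = medical[col].map(normalize_code_field)
    medical["place_of_service"] = medical["place_of_service"].map(normalize_code)
    for col in ("plan_paid", "patient_paid"):
        medical[col] = pd.to_numeric(medical[col], errors="raise").astype(float)

    pharmacy = pd.read_csv(pharmacy_path, dtype=str, keep_default_na=False)
    _require_columns(pharmacy, PHARMACY_COLUMNS, "pharmacy_claims")
    pharmacy = pharmacy[PHARMACY_COLUMNS].copy()
    pharmacy["fill_date"] = _parse_dates(pharmacy, "fill_date",
                                         "pharmacy_claims", True)
    pharmacy["drug_code"] = pharmacy["drug_code"].map(normalize_code)
    for col in ("plan_paid", "patient_paid"):
        pharmacy[col] = pd.to_numeric(pharmacy[col], errors="raise").astype(float)

    return ClaimsBundle(members, enrollment, medical, pharmacy)


def read_claims_dir(directory: str | Path) -> ClaimsBundle:
    d = Path(directory)
    return read_claims_tables(d / "members.csv", d / "enrollment.csv",
                              d / "medical_claims.csv", d / "pharmacy_claims.csv")


def _date_str(s: pd.Series) -> pd.Series:
    return s.dt.strftime("%Y-%m-%d").fillna("")


def write_claims_tables(bundle: ClaimsBundle, directory: str | Path) -> None:
    """Write the bundle back to the four-CSV layout (dates ISO-8601)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    members = bundle.members.copy()
    members["birth_date"] = _date_str(members["birth_date"])
    members["death_date"] = _date_str(members["death_date"])
    members.to_csv(d / "members.csv", index=False)

    enrollment = bundle.enrollment.copy()
    enrollment["start_date"] = _date_str(enrollment["start_date"])
    enrollment["end_date"] = _date_str(enrollment["end_date"])
    enrollment.to_csv(d / "enrollment.csv", index=False)

    medical = bundle.medical.copy()
    medical["service_date"] = _date_str(medical["service_date"])
    medical.to_csv(d / "medical_claims.csv", index=False)

    pharmacy = bundle.pharmacy.copy()
    pharmacy["fill_date"] = _date_str(pharmacy["fill_date"])
    pharmacy.to_csv(d / "pharmacy_claims.csv", index=False)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Violation:
    kind: str
    member_id: str
    detail: str = ""


def validate_dataset(bundle: ClaimsBundle) -> list[Violation]:
    """Check cross-table invariants. Violations are data, not exceptions.

    Reported kinds: ``duplicate_member``, ``death_before_birth``,
    ``span_inverted``, ``overlap``, ``negative_amount``,
    ``claim_outside_enrollment``, ``post_death_claim``, ``empty_codes``.
    The report is deterministic (sorted) and therefore row-order insensitive.
    """
    out: list[Violation] = []
    m = bundle.members

    dup = m["member_id"][m["member_id"].duplicated()]
    out += [Violation("duplicate_member", mid) for mid in dup.unique()]

    has_death = m["death_date"].notna()
    bad = has_death & (m["death_date"] < m["birth_date"])
    out += [Violation("death_before_birth", mid)
            for mid in m.loc[bad, "member_id"]]

    e = bundle.enrollment
    inv = e["start_date"] > e["end_date"]
    out += [Violation("span_inverted", mid) for mid in e.loc[inv, "member_id"]]

    ok = e[~inv].sort_values(["member_id", "start_date", "end_date"])
    prev_end = ok.groupby("member_id")["end_date"].shift()
    overlap = prev_end.notna() & (ok["start_date"] <= prev_end)
    out += [Violation("overlap", mid)
            for mid in ok.loc[overlap, "member_id"].unique()]

    death = m.set_index("member_id")["death_date"]

    for table, date_col, label in ((bundle.medical, "service_date", "medical"),
                                   (bundle.pharmacy, "fill_date", "pharmacy")):
        neg = (table["plan_paid"] < 0) | (table["patient_paid"] < 0)
        out += [Violation("negative_amount", mid, label)
                for mid in table.loc[neg, "member_id"]]

        # claim must fall inside some enrollment span of its member
        merged = table[["member_id", date_col]].reset_index().merge(
            e[["member_id", "start_date", "end_date"]], on="member_id",
            how="left")
        inside = ((merged[date_col] >= merged["start_date"])
                  & (merged[date_col] <= merged["end_date"]))
        covered = inside.groupby(merged["index"]).any()
        uncovered = covered.index[~covered]
        out += [Violation("claim_outside_enrollment",
                          str(table.loc[i, "member_id"]), label)
                for i in uncovered]

        dd = table["member_id"].map(death)
        post = dd.notna() & (table[date_col] > dd)
        out += [Violation("post_death_claim", mid, label)
                for mid in table.loc[post, "member_id"]]

    med = bundle.medical
    empty = ((med["diagnosis_codes"].fillna("") == "")
             & (med["procedure_codes"].fillna("") == ""))
    out += [Violation("empty_codes", mid)
            for mid in med.loc[empty, "member_id"]]

    return sorted(set(out))


def config_digest(*objs) -> str:
    """Stable SHA-256 over JSON-serializable config payloads (manifests)."""
    blob = json.dumps(objs, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
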