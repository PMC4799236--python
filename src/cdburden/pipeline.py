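"""End-to-end orchestration: case finding, matching, burden tables, attrition.

``run_pipeline`` chains the stages over a parsed :class:`ClaimsBundle` and
emits the study's standard outputs: an attrition report (sample
identification funnel), a demographics/pre-index table, an incidence table
with cluster-robust IRRs, a PPPM utilization/cost table, and a
reproducibility manifest. Outputs are deterministic given data + seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .claims_model import (AlgorithmConfig, CcsMapping, ClaimsBundle,
                           ConditionDefinition, config_digest,
                           default_algorithm_config, default_ccs_mapping,
                           default_conditions)
from .case_finding import find_cases
from .cohort_builder import build_cohort
from .burden_clinical import (flag_pre_index_categories, incidence_table,
                              top5_prevalence)
from .burden_economic import CpiTable, compute_pppm
from .burden_stats import is_significant


@dataclass
class PipelineResult:
    attrition: dict
    cohort: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    manifest: dict
    table2_top5: pd.DataFrame = field(default_factory=pd.DataFrame)
    pppm_per_member: pd.DataFrame = field(default_factory=pd.DataFrame)


def _demographics_rows(cohort: pd.DataFrame) -> pd.DataFrame:
    rows = []
    if cohort.empty:
        return pd.DataFrame(columns=["block", "level", "n_total", "pct_total",
                                     "n_case", "pct_case", "n_control",
                                     "pct_control"])
    grp = cohort["group"]
    n, n1, n0 = len(cohort), int((grp == "case").sum()), \
        int((grp == "control").sum())

    def add(block, level, mask):
        rows.append({
            "block": block, "level": level,
            "n_total": int(mask.sum()),
            "pct_total": 100.0 * mask.sum() / n,
            "n_case": int((mask & (grp == "case")).sum()),
            "pct_case": 100.0 * (mask & (grp == "case")).sum() / n1,
            "n_control": int((mask & (grp == "control")).sum()),
            "pct_control": 100.0 * (mask & (grp == "control")).sum() / n0,
        })

    for sex in ("female", "male"):
        add("sex", sex, cohort["sex"] == sex)
    add("age", "children", cohort["age_at_index"] < 18)
    add("age", "adults", cohort["age_at_index"] >= 18)
    for region in sorted(cohort["region"].unique()):
        add("region", region, cohort["region"] == region)
    for year in sorted(cohort["index_year"].unique()):
        add("index_year", str(year), cohort["index_year"] == year)
    return pd.DataFrame(rows)


def attrition_invariants_ok(attrition: dict, match_ratio: int) -> bool:
    """Case-stage counts non-increasing; controls = ratio x cases."""
    stages = [attrition["total_members"], attrition["cs_coded"],
              attrition["cs_plus_pituitary"],
              attrition["enrollment_eligible"], attrition["matched_cases"]]
    non_increasing = all(a >= b for a, b in zip(stages, stages[1:]))
    return non_increasing and (attrition["matched_controls"]
                               == match_ratio * attrition["matched_cases"])


def run_pipeline(bundle: ClaimsBundle,
                 config: AlgorithmConfig | None = None,
                 conditions: list[ConditionDefinition] | None = None,
                 ccs: CcsMapping | None = None,
                 cpi: CpiTable | None = None,
                 seed: int = 0,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run case finding -> matching -> clinical & economic burden.

    When ``out_dir`` is given, writes attrition.json, cohort.csv,
    table2_demographics.csv, table2_top5.csv, table3_incidence.csv,
    table4_pppm.csv, manifest.json and summary.txt.
    """
    config = config or default_algorithm_config()
    conditions = conditions if conditions is not None else default_conditions()
    ccs = ccs or default_ccs_mapping()
    cpi = cpi or CpiTable.identity()

    cases, attrition = find_cases(bundle, config)
    cohort, match_report = build_cohort(bundle, cases, config, seed)
    attrition["matched_cases"] = match_report["matched_cases"]
    attrition["matched_controls"] = match_report["matched_controls"]
    attrition["unmatched_cases"] = len(match_report["unmatched_cases"])

    if cohort.empty:
        table2 = _demographics_rows(cohort)
        top5 = pd.DataFrame()
        table3 = pd.DataFrame()
        table4 = pd.DataFrame()
        pppm_members = pd.DataFrame()
    else:
        table2 = _demographics_rows(cohort)
        flags = flag_pre_index_categories(cohort, bundle.medical, ccs,
                                          config.pre_days)
        top5 = top5_prevalence(flags, cohort)
        table3 = incidence_table(cohort, bundle.medical, conditions, config)
        pppm = compute_pppm(cohort, bundle.medical, bundle.pharmacy, cpi)
        table4 = pppm.summary
        pppm_members = pppm.per_member

    manifest = {
        "package_version": __version__,
        "seed": int(seed),
        "config_sha256": config_digest(
            config.to_dict(),
            [c.name for c in conditions],
            {"cpi_target": cpi.target_year, "cpi_values": cpi.values}),
        "input_counts": dict(zip(
            ("members", "enrollment", "medical", "pharmacy"), bundle.counts)),
        "attrition": attrition,
    }

    result = PipelineResult(attrition, cohort, table2, table3, table4,
                            manifest, top5, pppm_members)
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "attrition.json", "w") as fh:
        json.dump(result.attrition, fh, indent=2, sort_keys=True)
        fh.write("\n")
    cohort = result.cohort.copy()
    for col in ("index_date", "follow_up_end"):
        if col in cohort.columns and len(cohort):
            cohort[col] = cohort[col].dt.strftime("%Y-%m-%d")
    cohort.to_csv(d / "cohort.csv", index=False)
    result.table2.to_csv(d / "table2_demographics.csv", index=False)
    result.table2_top5.to_csv(d / "table2_top5.csv", index=False)
    result.table3.to_csv(d / "table3_incidence.csv", index=False)
    result.table4.to_csv(d / "table4_pppm.csv", index=False)
    with open(d / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    with open(d / "summary.txt", "w") as fh:
        fh.write(emit_summary(result))


def emit_summary(result: PipelineResult) -> str:
    """Human-readable report applying the dual significance rule
    (p < 0.05 AND 95% CI excluding 1)."""
    lines = ["=== Attrition ==="]
    for key in ("total_members", "cs_coded", "cs_plus_pituitary",
                "enrollment_eligible", "matched_cases", "matched_controls"):
        lines.append(f"{key}: {result.attrition.get(key, 0)}")
    lines.append("")
    lines.append("=== Incidence (per 100 person-years) ===")
    for r in result.table3.itertuples(index=False):
        sig = is_significant(r.p_value, r.ci_low, r.ci_high)
        flag = "significant" if sig else "not significant"
        irr = f"{r.irr:.4f}" if np.isfinite(r.irr) else "undefined"
        ci = (f"({r.ci_low:.4f}, {r.ci_high:.4f})"
              if np.isfinite(r.ci_low) else "(-)")
        lines.append(f"{r.condition}: case {r.rate_case:.4f} vs control "
                     f"{r.rate_control:.4f}; IRR {irr} {ci} [{flag}]")
    lines.append("")
    lines.append("=== PPPM (per patient per month) ===")
    for r in result.table4.itertuples(index=False):
        p = f"{r.p_value:.4g}" if np.isfinite(r.p_value) else "NA"
        lines.append(f"{r.measure}: case {r.mean_case:.2f} vs control "
                     f"{r.mean_control:.2f} (p={p})")
    return "\n".join(lines) + "\n"
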