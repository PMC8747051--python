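"""End-to-end analysis run: ingest or simulate, build metrics, code
outcomes, fit models and emit report tables.

Every run writes its fully-resolved configuration, the eligibility flow,
a descriptive participant table, association and marginal-effect tables
and a manifest (with content hashes) into the output directory so the run
is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .composition import add_diversity_flags, composition_table
from .iycf import ROUND_UNAVAILABLE_DEFAULT, outcome_table
from .kinship import build_ego_network
from .models import DEFAULT_COVARIATES, DEFAULT_EXPOSURES, AssociationResults, run_association_suite
from .roster import (
    HouseholdRoster,
    ChildFeedingRecord,
    read_children,
    read_rosters,
    select_eligible,
    write_children,
    write_rosters,
)
from .simulate import GeneratorConfig, generate_dataset
from .structure import structural_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run", "build_analysis_table"]


class RunConfig(BaseModel):
    """Configuration of one pipeline run (serialized into the output dir)."""

    roster_path: str | None = None
    children_path: str | None = None
    covariates_path: str | None = None
    generator: GeneratorConfig | None = None
    output_dir: str = "hhnet_run"
    seed: int = 0
    min_age_months: int = 6
    max_age_months: int = 23
    exposures: list[str] = Field(default_factory=lambda: list(DEFAULT_EXPOSURES))
    covariates: list[str] = Field(default_factory=lambda: list(DEFAULT_COVARIATES))
    round_unavailable: dict[str, tuple[str, ...]] = Field(
        default_factory=lambda: dict(ROUND_UNAVAILABLE_DEFAULT)
    )
    pooled_weighted: bool = True

    def data_source(self) -> str:
        if self.generator is not None:
            return "synthetic"
        if self.roster_path and self.children_path and self.covariates_path:
            return "files"
        raise ValueError("config needs either a generator block or roster/children/covariates paths")


@dataclass
class RunResult:
    analysis_table: pd.DataFrame
    participants: pd.DataFrame
    associations: pd.DataFrame
    marginal_effects: pd.DataFrame
    flow: dict[str, int]
    manifest: dict


def build_analysis_table(
    rosters: list[HouseholdRoster],
    children: list[ChildFeedingRecord],
    covariates: pd.DataFrame,
    min_age_months: int = 6,
    max_age_months: int = 23,
    round_unavailable: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join metrics, outcomes and covariates for the eligible cohort."""
    cohort = select_eligible(rosters, children, min_age_months, max_age_months)
    kept_rosters = [r for r, _ in cohort.pairs]
    kept_children = [(c, r.round) for r, c in cohort.pairs]

    struct = structural_table((r.household_id, build_ego_network(r)) for r in kept_rosters)
    comp = composition_table(kept_rosters)
    comp = add_diversity_flags(comp)
    outcomes = outcome_table(kept_children, unavailable=round_unavailable)

    table = (
        struct.merge(comp.drop(columns=["round", "weight"]), on="household_id")
        .merge(outcomes.drop(columns=["round"]), on="household_id")
        .merge(covariates, on="household_id")
    )
    return table, cohort.flow


def describe_participants(table: pd.DataFrame) -> pd.DataFrame:
    """Weighted descriptive table per round: mean (SE) for approximately
    normal variables, median (Q1, Q3) for skewed ones, n (%) for
    categorical ones."""
    rows = []
    mean_se_vars = ["resp_age_years"]
    median_vars = ["degree", "effective_size", "constraint_raw", "constraint", "age_sd", "iqv_sex", "iqv_education", "iqv_kinship"]
    cat_vars = [
        "resp_education",
        "residence",
        "head_sex",
        "earnings",
        "wealth_tercile",
        "iqv_de_facto_diverse",
        "iqv_de_jure_diverse",
        "mdd_met",
        "mmf_met",
    ]
    for rnd, grp in table.groupby("round"):
        w = grp["weight"].to_numpy(dtype=float)
        for var in mean_se_vars:
            x = grp[var].to_numpy(dtype=float)
            mean = np.average(x, weights=w)
            se = np.sqrt(np.average((x - mean) ** 2, weights=w) / len(x))
            rows.append({"round": rnd, "variable": var, "category": None, "statistic": "mean (SE)",
                         "value": f"{mean:.2f} ({se:.2f})", "n": len(grp)})
        for var in median_vars:
            x = grp[var].astype(float)
            q1, med, q3 = x.quantile([0.25, 0.5, 0.75])
            rows.append({"round": rnd, "variable": var, "category": None, "statistic": "median (Q1, Q3)",
                         "value": f"{med:.2f} ({q1:.2f}, {q3:.2f})", "n": int(x.notna().sum())})
        for var in cat_vars:
            col = grp[var]
            ok = col.notna()
            total_w = w[ok.to_numpy()].sum()
            for cat, sub in grp[ok].groupby(col[ok].astype(str)):
                n = len(sub)
                pct = 100.0 * sub["weight"].sum() / total_w if total_w > 0 else np.nan
                rows.append({"round": rnd, "variable": var, "category": cat, "statistic": "n (%)",
                             "value": f"{n} ({pct:.1f})", "n": n})
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write all artifacts to the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    source = config.data_source()

    if source == "synthetic":
        cohort = generate_dataset(config.generator)
        rosters, children, covariates = cohort.rosters, cohort.children, cohort.covariates
        write_rosters(rosters, out / "rosters.csv")
        write_children(children, out / "children.csv")
        covariates.to_csv(out / "covariates.csv", index=False)
    else:
        rosters = list(read_rosters(config.roster_path))
        children = read_children(config.children_path)
        covariates = pd.read_csv(config.covariates_path)

    table, flow = build_analysis_table(
        rosters,
        children,
        covariates,
        config.min_age_months,
        config.max_age_months,
        config.round_unavailable,
    )
    logger.info("eligibility flow: %s", flow)

    participants = describe_participants(table)
    results: AssociationResults = run_association_suite(
        table,
        exposures=config.exposures,
        covariates=config.covariates,
        pooled_weighted=config.pooled_weighted,
    )

    table.to_csv(out / "analysis_table.csv", index=False)
    participants.to_csv(out / "participants.csv", index=False)
    results.associations.to_csv(out / "associations.csv", index=False)
    results.marginal_effects.to_csv(out / "marginal_effects.csv", index=False)
    (out / "exclusion_flow.json").write_text(json.dumps(flow, indent=2))
    (out / "config.json").write_text(config.model_dump_json(indent=2))

    artifacts = ["analysis_table.csv", "participants.csv", "associations.csv",
                 "marginal_effects.csv", "exclusion_flow.json"]
    manifest = {
        "package_version": __version__,
        "data_source": source,
        "n_households": len(rosters),
        "n_analyzed": len(table),
        "artifacts": {a: _sha256(out / a) for a in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunResult(
        analysis_table=table,
        participants=participants,
        associations=results.associations,
        marginal_effects=results.marginal_effects,
        flow=flow,
        manifest=manifest,
    )
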