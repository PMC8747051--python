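"""Synthetic DHS-like survey generator.

Emulates the structure of the Ethiopian DHS household rosters this
pipeline targets: four survey rounds with unequal sample shares, two-stage
cluster sampling weights, mostly rural three-generation extended
households versus mostly nuclear urban ones, one last-born child aged 6-23
months per household, and round-specific availability of the feeding
recall items.  Outcomes are drawn from a configurable logistic model on
standardized network exposures with a Gaussian random intercept per survey
round, and the recall records (food-group flags, feed counts) are
back-filled to be consistent with the drawn indicators, so re-coding the
records recovers the drawn outcomes exactly.

The generator emulates marginal distributions (household size, kin mix,
prevalences), not an actual DHS sampling frame, regional strata or
wealth-index construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit, logit

from .composition import composition_table
from .iycf import ROUND_UNAVAILABLE_DEFAULT
from .kinship import build_ego_network
from .roster import (
    ChildFeedingRecord,
    Education,
    FOOD_GROUPS,
    HouseholdRoster,
    Member,
    Relationship,
    Sex,
)
from .structure import structural_table

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate_households", "generate_outcomes", "generate_dataset"]

_ARCHETYPES = ("nuclear", "extended", "with_nonrelatives")


class OutcomeModelConfig(BaseModel):
    """Logistic outcome model on standardized exposures.

    ``prevalence`` gives the per-round outcome probability at mean
    exposure and zero random effect (the intercept is its logit);
    ``coefficients`` are log-odds per SD of each exposure column;
    ``random_intercept_sd`` is the SD of the per-round Gaussian intercept
    added on top of the fixed per-round intercepts.
    """

    prevalence: dict[str, float]
    coefficients: dict[str, float] = Field(default_factory=dict)
    random_intercept_sd: float = 0.3


class GeneratorConfig(BaseModel):
    """Study-condition defaults for the synthetic survey."""

    n_households: int = 2000
    seed: int  # mandatory: every draw is reproducible
    round_props: dict[str, float] = Field(
        default_factory=lambda: {"2000": 0.30, "2005": 0.13, "2011": 0.28, "2016": 0.29}
    )
    urban_fraction: float = 0.20
    rural_archetype_probs: dict[str, float] = Field(
        default_factory=lambda: {"nuclear": 0.42, "extended": 0.40, "with_nonrelatives": 0.18}
    )
    urban_archetype_probs: dict[str, float] = Field(
        default_factory=lambda: {"nuclear": 0.68, "extended": 0.12, "with_nonrelatives": 0.20}
    )
    female_head_fraction: float = 0.15
    visitor_rate: float = 0.11
    away_rate: float = 0.14
    cluster_size: int = 25
    weight_lognorm_sigma: float = 0.4
    mdd: OutcomeModelConfig = Field(
        default_factory=lambda: OutcomeModelConfig(
            prevalence={"2000": 0.05, "2005": 0.0514, "2011": 0.0424, "2016": 0.124},
            coefficients={"degree": 0.05, "constraint": 0.10, "age_sd": 0.15},
        )
    )
    mmf: OutcomeModelConfig = Field(
        default_factory=lambda: OutcomeModelConfig(
            prevalence={"2000": 0.435, "2005": 0.47, "2011": 0.502, "2016": 0.489},
            coefficients={"degree": -0.15, "constraint": 0.30},
        )
    )

    @model_validator(mode="after")
    def _check_probs(self) -> "GeneratorConfig":
        for name, probs in (
            ("round_props", self.round_props),
            ("rural_archetype_probs", self.rural_archetype_probs),
            ("urban_archetype_probs", self.urban_archetype_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if set(self.rural_archetype_probs) != set(_ARCHETYPES) or set(self.urban_archetype_probs) != set(
            _ARCHETYPES
        ):
            raise ValueError(f"archetype probabilities must cover {_ARCHETYPES}")
        return self


@dataclass
class SyntheticCohort:
    rosters: list[HouseholdRoster]
    children: list[ChildFeedingRecord]
    covariates: pd.DataFrame


def _education(rng: np.random.Generator, urban: bool) -> Education:
    p = 0.55 if urban else 0.22
    return Education.PRIMARY_OR_ABOVE if rng.random() < p else Education.NONE


def _member(
    mid: str,
    rel: Relationship,
    sex: Sex,
    age: float,
    edu: Education,
    respondent: bool = False,
    de_jure: bool = True,
    de_facto: bool = True,
) -> Member:
    return Member(
        member_id=mid,
        relationship=rel,
        sex=sex,
        age_years=age,
        education=edu,
        de_jure=de_jure,
        de_facto=de_facto,
        is_respondent=respondent,
    )


#: Attached relatives occasionally listed in predominantly nuclear rosters.
_EXTRA_RELATIVES = (
    Relationship.PARENT,
    Relationship.PARENT_IN_LAW,
    Relationship.SIBLING,
    Relationship.NIECE_NEPHEW,
    Relationship.OTHER_RELATIVE,
    Relationship.NON_RELATIVE,
)


def _nuclear_members(rng: np.random.Generator, urban: bool, female_head: bool, child_age_years: float):
    """Couple (or lone mother) plus children, frequently with an attached
    relative (a grandparent, sibling, niece or boarder); the respondent is
    the mother."""
    members = []
    ego_age = float(np.round(np.clip(rng.normal(28, 6), 16, 49)))
    if female_head:
        members.append(
            _member("m1", Relationship.HEAD, Sex.FEMALE, ego_age, _education(rng, urban), respondent=True)
        )
    else:
        members.append(_member("m1", Relationship.HEAD, Sex.MALE, float(ego_age + rng.integers(2, 9)), _education(rng, urban)))
        members.append(
            _member("m2", Relationship.SPOUSE, Sex.FEMALE, ego_age, _education(rng, urban), respondent=True)
        )
    n_children = int(rng.integers(1, 5))  # includes the index child
    for i in range(n_children - 1):
        sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        age = float(rng.integers(2, max(3, int(ego_age) - 14)))
        edu = Education.PRIMARY_OR_ABOVE if age >= 10 and rng.random() < 0.5 else Education.NONE
        members.append(_member(f"m{len(members) + 1}", Relationship.CHILD, sex, age, edu))
    members.append(
        _member(
            f"m{len(members) + 1}",
            Relationship.CHILD,
            Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
            child_age_years,
            Education.NONE,
        )
    )
    # attached relatives: strictly nuclear rosters are the minority
    n_extra = int(rng.choice([0, 1, 2], p=[0.45, 0.40, 0.15]))
    for _ in range(n_extra):
        rel = _EXTRA_RELATIVES[int(rng.integers(len(_EXTRA_RELATIVES)))]
        if rel in (Relationship.PARENT, Relationship.PARENT_IN_LAW):
            age, sex = float(rng.integers(45, 62)), Sex.FEMALE if rng.random() < 0.7 else Sex.MALE
        elif rel == Relationship.SIBLING:
            age, sex = float(rng.integers(15, 35)), Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        else:
            age, sex = float(rng.integers(8, 30)), Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        members.append(_member(f"m{len(members) + 1}", rel, sex, age, _education(rng, urban)))
    return members, not female_head, ego_age


def _extended_members(rng: np.random.Generator, urban: bool, child_age_years: float):
    """Three generations: eldest couple, their sons, sons' wives and
    grandchildren; the respondent is one son's wife."""
    members = []
    head_age = float(rng.integers(40, 54))
    members.append(_member("m1", Relationship.HEAD, Sex.MALE, head_age, _education(rng, urban)))
    members.append(
        _member("m2", Relationship.SPOUSE, Sex.FEMALE, head_age - rng.integers(3, 9), Education.NONE)
    )
    ego_age = float(np.round(np.clip(rng.normal(24, 4), 16, 40)))
    n_sons = int(rng.integers(1, 3))
    for s in range(n_sons):
        members.append(
            _member(
                f"m{len(members) + 1}",
                Relationship.CHILD,
                Sex.MALE,
                float(np.round(np.clip(rng.normal(25, 3), 20, 36))),
                _education(rng, urban),
            )
        )
    # respondent: wife of one of the sons
    members.append(
        _member(
            f"m{len(members) + 1}",
            Relationship.CHILD_IN_LAW,
            Sex.FEMALE,
            ego_age,
            _education(rng, urban),
            respondent=True,
        )
    )
    if n_sons > 1 and rng.random() < 0.5:  # another son's wife
        members.append(
            _member(
                f"m{len(members) + 1}",
                Relationship.CHILD_IN_LAW,
                Sex.FEMALE,
                float(np.round(np.clip(rng.normal(24, 4), 16, 40))),
                _education(rng, urban),
            )
        )
    if rng.random() < 0.6:  # an unmarried daughter
        members.append(
            _member(
                f"m{len(members) + 1}",
                Relationship.CHILD,
                Sex.FEMALE,
                float(rng.integers(10, 18)),
                _education(rng, urban),
            )
        )
    n_grandchildren = int(rng.integers(0, 3))  # siblings/cousins of the index child
    for g in range(n_grandchildren):
        members.append(
            _member(
                f"m{len(members) + 1}",
                Relationship.GRANDCHILD,
                Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
                float(rng.integers(1, 13)),
                Education.NONE,
            )
        )
    members.append(
        _member(
            f"m{len(members) + 1}",
            Relationship.GRANDCHILD,
            Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
            child_age_years,
            Education.NONE,
        )
    )
    return members, True, ego_age


def generate_households(config: GeneratorConfig) -> SyntheticCohort:
    """Draw rosters, child skeletons (recall fields unfilled) and covariates."""
    rng = np.random.default_rng(config.seed)
    rounds = sorted(config.round_props)
    round_draw = rng.choice(rounds, size=config.n_households, p=[config.round_props[r] for r in rounds])
    round_draw = np.sort(round_draw)

    rosters: list[HouseholdRoster] = []
    children: list[ChildFeedingRecord] = []
    cov_rows: list[dict] = []
    counter_in_round: dict[str, int] = {r: 0 for r in rounds}

    for i in range(config.n_households):
        rnd = str(round_draw[i])
        idx = counter_in_round[rnd]
        counter_in_round[rnd] += 1
        hid = f"{rnd}_h{idx:05d}"
        cluster = f"{rnd}_c{idx // config.cluster_size:04d}"
        urban = rng.random() < config.urban_fraction
        probs = config.urban_archetype_probs if urban else config.rural_archetype_probs
        archetype = str(rng.choice(_ARCHETYPES, p=[probs[a] for a in _ARCHETYPES]))

        age_months = int(rng.integers(6, 24))
        child_age_years = float(age_months // 12)
        if archetype == "extended":
            members, coresident, ego_age = _extended_members(rng, urban, child_age_years)
        else:
            female_head = rng.random() < config.female_head_fraction
            members, coresident, ego_age = _nuclear_members(rng, urban, female_head, child_age_years)
            if archetype == "with_nonrelatives":
                for k in range(int(rng.integers(1, 3))):
                    members.append(
                        _member(
                            f"m{len(members) + 1}",
                            Relationship.NON_RELATIVE,
                            Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
                            float(rng.integers(12, 60)),
                            _education(rng, urban),
                        )
                    )
        # usual residents away last night / visitors present
        members = [
            m
            if m.is_respondent or m.age_years < 2 or rng.random() > config.away_rate
            else Member(**{**m.__dict__, "de_facto": False})
            for m in members
        ]
        if rng.random() < config.visitor_rate:
            members.append(
                _member(
                    f"m{len(members) + 1}",
                    Relationship.OTHER_RELATIVE if rng.random() < 0.6 else Relationship.NON_RELATIVE,
                    Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
                    float(rng.integers(15, 60)),
                    Education.NONE,
                    de_jure=False,
                    de_facto=True,
                )
            )

        weight = float(rng.lognormal(mean=0.0, sigma=config.weight_lognorm_sigma))
        roster = HouseholdRoster(
            household_id=hid, cluster_id=cluster, round=rnd, weight=weight, members=tuple(members)
        )
        rosters.append(roster)

        breastfed = rng.random() < (0.92 - 0.02 * (age_months - 6))
        children.append(
            ChildFeedingRecord(
                child_id=f"{hid}_k",
                household_id=hid,
                age_months=age_months,
                is_last_born=True,
                breastfed=bool(breastfed),
                food_groups={g: 0 for g in FOOD_GROUPS},
                feed_count=0,
                solid_feed_count=0,
            )
        )
        head = members[0]
        cov_rows.append(
            {
                "household_id": hid,
                "round": rnd,
                "cluster_id": cluster,
                "weight": weight,
                "resp_age_years": ego_age,
                "resp_education": roster.respondent.education.value,
                "residence": "urban" if urban else "rural",
                "earnings": str(rng.choice(["not_working", "unpaid", "paid"], p=[0.55, 0.15, 0.30])),
                "wealth_tercile": str(rng.choice(["poor", "middle", "rich"], p=[0.33, 0.34, 0.33])),
                "head_sex": head.sex.value,
                "coresident_husband": bool(coresident),
                "maternal_respondent": bool(rng.random() < 0.88),
            }
        )

    covariates = pd.DataFrame(cov_rows)
    # normalize weights to mean 1 (relative sampling weights)
    covariates["weight"] = covariates["weight"] / covariates["weight"].mean()
    rosters = [
        HouseholdRoster(
            household_id=r.household_id,
            cluster_id=r.cluster_id,
            round=r.round,
            weight=float(w),
            members=r.members,
        )
        for r, w in zip(rosters, covariates["weight"])
    ]
    return SyntheticCohort(rosters=rosters, children=children, covariates=covariates)


def _standardize(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        return col * 0.0
    return (col - col.mean()) / sd


def _exposure_frame(cohort: SyntheticCohort) -> pd.DataFrame:
    nets = ((r.household_id, build_ego_network(r)) for r in cohort.rosters)
    struct = structural_table(nets)
    comp = composition_table(cohort.rosters).drop(columns=["round", "weight"])
    return struct.merge(comp, on="household_id")


def generate_outcomes(
    cohort: SyntheticCohort,
    config: GeneratorConfig,
    exposures: pd.DataFrame | None = None,
) -> list[ChildFeedingRecord]:
    """Draw MDD/MMF through the configured logistic model and back-fill
    recall records consistently with the drawn indicators.

    Round availability is *not* applied here: the generator produces
    complete recall records and the outcome coder applies the per-round
    masks, as with real data.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if exposures is None:
        exposures = _exposure_frame(cohort)
    exposures = exposures.set_index("household_id")

    rounds = sorted(config.round_props)
    out: list[ChildFeedingRecord] = []
    z_cols: dict[str, pd.Series] = {}
    for model in (config.mdd, config.mmf):
        for var in model.coefficients:
            if var not in z_cols:
                z_cols[var] = _standardize(exposures[var].astype(float))

    u_round = {
        "mdd": {r: rng.normal(0.0, config.mdd.random_intercept_sd) for r in rounds},
        "mmf": {r: rng.normal(0.0, config.mmf.random_intercept_sd) for r in rounds},
    }

    for roster, child in zip(cohort.rosters, cohort.children):
        hid = roster.household_id
        etas = {}
        for name, model in (("mdd", config.mdd), ("mmf", config.mmf)):
            eta = logit(model.prevalence[roster.round]) + u_round[name][roster.round]
            for var, beta in model.coefficients.items():
                eta += beta * float(z_cols[var].loc[hid])
            etas[name] = eta
        mdd_met = rng.random() < expit(etas["mdd"])
        mmf_met = rng.random() < expit(etas["mmf"])
        out.append(_backfill_record(child, bool(mdd_met), bool(mmf_met), rng))
    return out


def _backfill_record(
    child: ChildFeedingRecord, mdd_met: bool, mmf_met: bool, rng: np.random.Generator
) -> ChildFeedingRecord:
    """Fill food-group flags and feed counts so that re-coding the record
    reproduces exactly the drawn indicator values."""
    # dietary diversity: pick a score in the met/not-met band, then groups
    if mdd_met:
        score = int(rng.integers(5, 9))
    else:
        score = int(rng.integers(1 if child.breastfed else 0, 5))
    flags = {g: 0 for g in FOOD_GROUPS}
    if child.breastfed:
        flags["breast_milk"] = 1
    remaining = [g for g in FOOD_GROUPS if not flags[g]]
    need = score - sum(flags.values())
    if need > 0:
        for g in rng.choice(remaining, size=min(need, len(remaining)), replace=False):
            flags[str(g)] = 1
    # meal frequency
    if child.breastfed:
        required = 2 if child.age_months <= 8 else 3
        feed = int(rng.integers(required, required + 4)) if mmf_met else int(rng.integers(0, required))
        solid = int(rng.integers(0, feed + 1))
    else:
        if mmf_met:
            feed = int(rng.integers(4, 8))
            solid = int(rng.integers(1, feed + 1))
        else:
            if rng.random() < 0.8:  # usually fails on frequency, sometimes on solids
                feed = int(rng.integers(0, 4))
                solid = int(rng.integers(0, min(feed, 3) + 1))
            else:
                feed = int(rng.integers(4, 8))
                solid = 0
    return ChildFeedingRecord(
        child_id=child.child_id,
        household_id=child.household_id,
        age_months=child.age_months,
        is_last_born=child.is_last_born,
        breastfed=child.breastfed,
        food_groups=flags,
        feed_count=feed,
        solid_feed_count=solid,
    )


def generate_dataset(config: GeneratorConfig) -> SyntheticCohort:
    """Households plus fully back-filled feeding records."""
    cohort = generate_households(config)
    children = generate_outcomes(cohort, config)
    return SyntheticCohort(rosters=cohort.rosters, children=children, covariates=cohort.covariates)
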