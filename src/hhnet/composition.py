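"""Compositional household variables: qualitative-variation indices (IQV),
alter age diversity, and de jure / de facto residence diversity.

The IQV used throughout is the category-count-normalized Gibbs-Martin
index,

    IQV = (K / (K - 1)) * (1 - sum_k p_k^2),

the probability that a randomly selected pair of members falls in
different categories, scaled so its maximum (the even split over K
categories) is 1.  K is the codebook category count, not the number of
categories observed in the household; this keeps single-category
households at 0 rather than undefined and makes values comparable across
variables with different numbers of categories.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .roster import HouseholdRoster, Member, Relationship

__all__ = [
    "iqv",
    "age_diversity",
    "residence_diversity",
    "CompositionMetrics",
    "compute_composition_metrics",
    "composition_table",
    "add_diversity_flags",
    "KINSHIP_CATEGORY_COUNT",
]

#: Codebook size for the kinship IQV: the relationship enumeration less the
#: ego's own listing slot (configurable).
KINSHIP_CATEGORY_COUNT = 12


def iqv(categories: Iterable, k: int) -> float:
    """Index of qualitative variation of a label multiset over ``k`` categories.

    0 when every member shares one category, 1 at the even split.  Values
    are clamped to [0, 1] (an observed category outside the codebook count
    could otherwise push past 1).
    """
    if k < 2:
        raise ValueError(f"IQV needs at least 2 possible categories, got k={k}")
    counts = Counter(categories)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("IQV of an empty multiset is undefined")
    p2 = sum((c / n) ** 2 for c in counts.values())
    return float(np.clip(k / (k - 1) * (1.0 - p2), 0.0, 1.0))


def age_diversity(alters: Sequence[Member]) -> float:
    """Sample standard deviation (ddof=1) of alter ages in years.

    A single alter yields 0 by convention; no known ages yields NaN.
    """
    ages = [m.age_years for m in alters if m.age_years is not None and np.isfinite(m.age_years)]
    if not ages:
        return float("nan")
    if len(ages) == 1:
        return 0.0
    return float(np.std(ages, ddof=1))


def residence_diversity(roster: HouseholdRoster) -> tuple[float, float]:
    """De jure and de facto residence IQVs of the household's alters.

    * de jure IQV: over {usual resident, visitor} status among everyone
      listed (usual residents plus visitors present last night);
      positive iff at least one visitor is listed.
    * de facto IQV: over {slept here, away} among usual residents;
      positive iff at least one usual resident was away last night.
    """
    listed = [m for m in roster.members if not m.is_respondent]
    if not listed:
        raise ValueError("household has no alters")
    iqv_de_jure = iqv(["usual" if m.de_jure else "visitor" for m in listed], k=2)
    usual = [m for m in listed if m.de_jure]
    if usual:
        iqv_de_facto = iqv(["present" if m.de_facto else "away" for m in usual], k=2)
    else:
        iqv_de_facto = float("nan")
    return iqv_de_jure, iqv_de_facto


@dataclass(frozen=True)
class CompositionMetrics:
    iqv_sex: float
    iqv_education: float
    iqv_kinship: float
    age_sd: float
    iqv_de_jure: float
    iqv_de_facto: float


def compute_composition_metrics(
    roster: HouseholdRoster,
    kinship_categories: int = KINSHIP_CATEGORY_COUNT,
) -> CompositionMetrics:
    """Compositional variables over the de jure alters of one household.

    The respondent's own attributes are excluded from every multiset: the
    measures describe her network, not herself.
    """
    alters = roster.alters()
    if not alters:
        raise ValueError(f"household {roster.household_id!r} has no de jure alters")
    return CompositionMetrics(
        iqv_sex=iqv([m.sex.value for m in alters], k=2),
        iqv_education=iqv([m.education.value for m in alters], k=2),
        iqv_kinship=iqv([m.relationship.value for m in alters], k=kinship_categories),
        age_sd=age_diversity(alters),
        iqv_de_jure=residence_diversity(roster)[0],
        iqv_de_facto=residence_diversity(roster)[1],
    )


def composition_table(
    rosters: Iterable[HouseholdRoster],
    kinship_categories: int = KINSHIP_CATEGORY_COUNT,
) -> pd.DataFrame:
    rows = []
    for r in rosters:
        m = compute_composition_metrics(r, kinship_categories=kinship_categories)
        rows.append({"household_id": r.household_id, "round": r.round, "weight": r.weight, **m.__dict__})
    return pd.DataFrame(rows)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def add_diversity_flags(
    table: pd.DataFrame,
    columns: Sequence[str] = ("iqv_de_jure", "iqv_de_facto"),
    weight_col: str = "weight",
    by_round: bool = True,
) -> pd.DataFrame:
    """Median-split diversity flags: present iff the IQV exceeds the
    weighted cohort median (computed per survey round by default).

    Adds ``<col>_diverse`` boolean columns and returns a copy.
    """
    out = table.copy()
    if by_round and "round" in out.columns:
        groups = list(out.groupby("round"))
    else:
        groups = [(None, out)]
    for col in columns:
        flag = pd.Series(index=out.index, dtype=bool)
        for _, grp in groups:
            vals = grp[col].to_numpy(dtype=float)
            w = grp[weight_col].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            med = _weighted_median(vals[ok], w[ok]) if ok.any() else float("nan")
            flag.loc[grp.index] = grp[col] > med
        out[f"{col}_diverse"] = flag
    return out
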