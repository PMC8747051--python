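"""WHO infant-and-young-child-feeding indicator coding.

Two indicators are coded from the previous-day feeding recall of children
aged 6-23 completed months:

* **Minimum Dietary Diversity (MDD)** — the dietary-diversity score is the
  count of the eight food groups consumed (breast milk; grains/roots/
  tubers; legumes/nuts; dairy; flesh foods and eggs; vitamin-A-rich fruits
  and vegetables; other fruits and vegetables; remaining solids), and the
  indicator is met at 5-8 groups.
* **Minimum Meal Frequency (MMF)** — breastfed children need at least 2
  feeds at 6-8 months and at least 3 at 9-23 months; non-breastfed
  children need at least 4 feeds (milk feeds included) of which at least
  one is solid, semi-solid or soft food.

Survey rounds differ in which recall items were collected; a
round-availability mask drops indicators that cannot be constructed for a
round.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .roster import FOOD_GROUPS, ChildFeedingRecord

__all__ = [
    "MDD_MIN_GROUPS",
    "ROUND_UNAVAILABLE_DEFAULT",
    "OutcomeRecord",
    "mdd",
    "mmf",
    "apply_round_availability",
    "outcome_table",
]

#: Food groups needed to meet minimum dietary diversity (of 8).
MDD_MIN_GROUPS = 5

#: Default outcome availability: items for MDD were not collected in the
#: 2000 round and items for MMF not in 2005.
ROUND_UNAVAILABLE_DEFAULT: dict[str, tuple[str, ...]] = {
    "2000": ("mdd",),
    "2005": ("mmf",),
    "2011": (),
    "2016": (),
}


@dataclass(frozen=True)
class OutcomeRecord:
    child_id: str
    dd_score: int | None
    mdd_met: bool | None
    mmf_met: bool | None


def mdd(
    record: ChildFeedingRecord,
    min_groups: int = MDD_MIN_GROUPS,
    count_breast_milk: bool = True,
) -> tuple[int | None, bool | None]:
    """Dietary-diversity score and MDD indicator for one child.

    Returns ``(None, None)`` when any required food-group flag is missing.
    ``count_breast_milk=False`` switches to the 7-group variant that drops
    breast milk from the score (the threshold is then ``min_groups - 1``).
    """
    groups = FOOD_GROUPS if count_breast_milk else FOOD_GROUPS[1:]
    threshold = min_groups if count_breast_milk else min_groups - 1
    flags = [record.food_groups[g] for g in groups]
    if any(f is None for f in flags):
        return None, None
    score = int(sum(flags))
    return score, score >= threshold


def mmf(record: ChildFeedingRecord) -> bool:
    """Minimum-meal-frequency indicator for one child aged 6-23 months."""
    if not 6 <= record.age_months <= 23:
        raise ValueError(
            f"child {record.child_id!r}: MMF is defined for 6-23 months, got {record.age_months}"
        )
    if record.breastfed:
        required = 2 if record.age_months <= 8 else 3
        return record.feed_count >= required
    return record.feed_count >= 4 and record.solid_feed_count >= 1


def apply_round_availability(
    outcome: OutcomeRecord,
    round: str,
    unavailable: Mapping[str, tuple[str, ...]] | None = None,
) -> OutcomeRecord:
    """Mask indicators whose recall items were not collected in ``round``."""
    table = ROUND_UNAVAILABLE_DEFAULT if unavailable is None else unavailable
    if round not in table:
        raise KeyError(f"unknown survey round {round!r}; known rounds: {sorted(table)}")
    masked = table[round]
    return OutcomeRecord(
        child_id=outcome.child_id,
        dd_score=None if "mdd" in masked else outcome.dd_score,
        mdd_met=None if "mdd" in masked else outcome.mdd_met,
        mmf_met=None if "mmf" in masked else outcome.mmf_met,
    )


def outcome_table(
    children: Iterable[tuple[ChildFeedingRecord, str]],
    unavailable: Mapping[str, tuple[str, ...]] | None = None,
    count_breast_milk: bool = True,
) -> pd.DataFrame:
    """Code MDD and MMF for (child, round) pairs into a tidy table.

    Masked or missing indicators are NA; a ``n_missing_food_flags`` column
    is not emitted, but missing flags propagate to NA outcomes so they can
    be counted downstream.
    """
    rows = []
    for child, rnd in children:
        score, met = mdd(child, count_breast_milk=count_breast_milk)
        rec = OutcomeRecord(child.child_id, score, met, mmf(child))
        rec = apply_round_availability(rec, rnd, unavailable)
        rows.append(
            {
                "child_id": child.child_id,
                "household_id": child.household_id,
                "round": rnd,
                "dd_score": rec.dd_score,
                "mdd_met": rec.mdd_met,
                "mmf_met": rec.mmf_met,
            }
        )
    df = pd.DataFrame(rows)
    for col in ("dd_score", "mdd_met", "mmf_met"):
        df[col] = df[col].astype("object")
    return df
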