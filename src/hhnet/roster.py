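"""Household roster and child feeding-recall domain types and table IO.

The on-disk dialect is a flat CSV/Parquet layout modelled on DHS household
(PR) and child (KR) recode exports: one row per household member in the
roster table, one row per child in the feeding table.  Column names are the
package's own documented dictionary (see ``ROSTER_COLUMNS`` /
``CHILD_COLUMNS``); no hierarchical .REC parsing is attempted.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Relationship",
    "Sex",
    "Education",
    "Member",
    "HouseholdRoster",
    "ChildFeedingRecord",
    "EgoCovariates",
    "FOOD_GROUPS",
    "ROSTER_COLUMNS",
    "CHILD_COLUMNS",
    "SchemaError",
    "IntegrityError",
    "LinkageError",
    "RosterReadResult",
    "EligibleCohort",
    "read_rosters",
    "write_rosters",
    "read_children",
    "write_children",
    "select_eligible",
]


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class IntegrityError(ValueError):
    """Duplicate identifiers or inconsistent row groupings."""


class LinkageError(KeyError):
    """A child record references a household that is not in the roster set."""


class Relationship(str, enum.Enum):
    """Relationship-to-household-head codes (closed DHS-style enumeration)."""

    HEAD = "head"
    SPOUSE = "spouse"
    CHILD = "child"
    CHILD_IN_LAW = "child_in_law"
    GRANDCHILD = "grandchild"
    PARENT = "parent"
    PARENT_IN_LAW = "parent_in_law"
    SIBLING = "sibling"
    ADOPTED_FOSTER_STEP = "adopted_foster_step"
    OTHER_RELATIVE = "other_relative"
    NIECE_NEPHEW = "niece_nephew"
    NON_RELATIVE = "non_relative"
    UNSPECIFIED = "unspecified"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Education(str, enum.Enum):
    NONE = "none"
    PRIMARY_OR_ABOVE = "primary_or_above"


@dataclass(frozen=True)
class Member:
    """One household-roster row.

    ``de_jure`` marks a usual resident (listed whether or not present);
    ``de_facto`` marks a person who slept in the household the night before
    the interview.  Visitors are de facto but not de jure.  At least one of
    the two flags must be set for the row to be a household member at all.
    """

    member_id: str
    relationship: Relationship
    sex: Sex
    age_years: float
    education: Education
    de_jure: bool
    de_facto: bool
    is_respondent: bool = False

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError(f"negative age for member {self.member_id!r}")
        if not (self.de_jure or self.de_facto):
            raise ValueError(
                f"member {self.member_id!r} is neither a de jure nor a de facto member"
            )


@dataclass(frozen=True)
class HouseholdRoster:
    """One surveyed household: identifiers, survey metadata and members."""

    household_id: str
    cluster_id: str
    round: str
    weight: float
    members: tuple[Member, ...]

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"non-positive weight for household {self.household_id!r}")
        if len(self.members) < 2:
            raise ValueError(
                f"household {self.household_id!r} needs the respondent plus at least one alter"
            )
        n_resp = sum(m.is_respondent for m in self.members)
        if n_resp != 1:
            raise ValueError(
                f"household {self.household_id!r} has {n_resp} respondents; expected exactly 1"
            )

    @property
    def respondent(self) -> Member:
        return next(m for m in self.members if m.is_respondent)

    def alters(self, de_facto_only: bool = False) -> tuple[Member, ...]:
        """Household members other than the respondent.

        By default the de jure listing (usual residents) defines the
        network; ``de_facto_only`` restricts to members present on the
        night before the survey instead.
        """
        flag = (lambda m: m.de_facto) if de_facto_only else (lambda m: m.de_jure)
        return tuple(m for m in self.members if not m.is_respondent and flag(m))


#: The eight food groups of the dietary-diversity recall, in column order.
FOOD_GROUPS: tuple[str, ...] = (
    "breast_milk",
    "grains_roots_tubers",
    "legumes_nuts",
    "dairy",
    "flesh_eggs",
    "vitamin_a_fruit_veg",
    "other_fruit_veg",
    "other_solids",
)


@dataclass(frozen=True)
class ChildFeedingRecord:
    """Previous-day feeding recall for one child."""

    child_id: str
    household_id: str
    age_months: int
    is_last_born: bool
    breastfed: bool
    food_groups: Mapping[str, int | None]
    feed_count: int
    solid_feed_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.age_months <= 59:
            raise ValueError(f"child {self.child_id!r}: age {self.age_months} months out of [0, 59]")
        if set(self.food_groups) != set(FOOD_GROUPS):
            missing = set(FOOD_GROUPS) - set(self.food_groups)
            extra = set(self.food_groups) - set(FOOD_GROUPS)
            raise ValueError(f"child {self.child_id!r}: bad food groups (missing={missing}, extra={extra})")
        for k, v in self.food_groups.items():
            if v not in (0, 1, None):
                raise ValueError(f"child {self.child_id!r}: food group {k!r} flag must be 0/1/missing")
        if self.feed_count < 0 or self.solid_feed_count < 0:
            raise ValueError(f"child {self.child_id!r}: negative feed count")
        if self.solid_feed_count > self.feed_count:
            raise ValueError(
                f"child {self.child_id!r}: solid feeds ({self.solid_feed_count}) exceed total feeds ({self.feed_count})"
            )


@dataclass(frozen=True)
class EgoCovariates:
    """Respondent and household covariates used in the adjusted models."""

    age_years: float
    education: Education
    residence: str  # urban | rural
    earnings: str  # not_working | unpaid | paid
    wealth_tercile: str  # poor | middle | rich
    head_sex: Sex
    coresident_husband: bool
    maternal_respondent: bool

    _RESIDENCE = ("urban", "rural")
    _EARNINGS = ("not_working", "unpaid", "paid")
    _WEALTH = ("poor", "middle", "rich")

    def __post_init__(self) -> None:
        if self.residence not in self._RESIDENCE:
            raise ValueError(f"residence {self.residence!r} not in {self._RESIDENCE}")
        if self.earnings not in self._EARNINGS:
            raise ValueError(f"earnings {self.earnings!r} not in {self._EARNINGS}")
        if self.wealth_tercile not in self._WEALTH:
            raise ValueError(f"wealth tercile {self.wealth_tercile!r} not in {self._WEALTH}")


ROSTER_COLUMNS: tuple[str, ...] = (
    "household_id",
    "cluster_id",
    "round",
    "weight",
    "member_id",
    "relationship",
    "sex",
    "age_years",
    "education",
    "de_jure",
    "de_facto",
    "is_respondent",
)

CHILD_COLUMNS: tuple[str, ...] = (
    "child_id",
    "household_id",
    "age_months",
    "is_last_born",
    "breastfed",
    *(f"fg_{g}" for g in FOOD_GROUPS),
    "feed_count",
    "solid_feed_count",
)


@dataclass
class RosterReadResult:
    """Parsed rosters plus a count of relationship codes outside the enumeration."""

    rosters: list[HouseholdRoster]
    n_unknown_relationship: int = 0

    def __iter__(self) -> Iterator[HouseholdRoster]:
        return iter(self.rosters)

    def __len__(self) -> int:
        return len(self.rosters)

    def __getitem__(self, i):  # noqa: ANN001 - sequence protocol
        return self.rosters[i]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in {".parquet", ".pq"}:
        return pd.read_parquet(path)
    # correctly-rounded float parsing so CSV round-trips are bit-exact
    return pd.read_csv(path, float_precision="round_trip")


def _write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in {".parquet", ".pq"}:
        df.to_parquet(path, index=False)
    else:
        # %.17g guarantees float64 round-trips bit-exactly through text
        df.to_csv(path, index=False, float_format="%.17g")


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing mandatory column {col!r}")


def read_rosters(path: str | Path) -> RosterReadResult:
    """Read a member-per-row roster table into :class:`HouseholdRoster` objects.

    Relationship codes outside the enumeration are kept as ``unspecified``
    and counted on the returned result (also logged as a warning).
    """
    df = _read_table(path)
    _require_columns(df, ROSTER_COLUMNS, "roster")
    dupes = df.duplicated(subset=["household_id", "member_id"])
    if dupes.any():
        bad = df.loc[dupes, ["household_id", "member_id"]].iloc[0]
        raise IntegrityError(
            f"duplicate (household_id, member_id) pair: ({bad.household_id!r}, {bad.member_id!r})"
        )

    valid_codes = {r.value for r in Relationship}
    n_unknown = 0
    rosters: list[HouseholdRoster] = []
    for hid, grp in df.groupby("household_id", sort=False):
        head_row = grp.iloc[0]
        members = []
        for row in grp.itertuples(index=False):
            rel = str(row.relationship)
            if rel not in valid_codes:
                n_unknown += 1
                rel = Relationship.UNSPECIFIED.value
            members.append(
                Member(
                    member_id=str(row.member_id),
                    relationship=Relationship(rel),
                    sex=Sex(str(row.sex)),
                    age_years=float(row.age_years),
                    education=Education(str(row.education)),
                    de_jure=bool(row.de_jure),
                    de_facto=bool(row.de_facto),
                    is_respondent=bool(row.is_respondent),
                )
            )
        rosters.append(
            HouseholdRoster(
                household_id=str(hid),
                cluster_id=str(head_row.cluster_id),
                round=str(head_row["round"]),
                weight=float(head_row.weight),
                members=tuple(members),
            )
        )
    if n_unknown:
        logger.warning("mapped %d unparseable relationship codes to 'unspecified'", n_unknown)
    return RosterReadResult(rosters=rosters, n_unknown_relationship=n_unknown)


def rosters_to_frame(rosters: Iterable[HouseholdRoster]) -> pd.DataFrame:
    rows = []
    for r in rosters:
        for m in r.members:
            rows.append(
                {
                    "household_id": r.household_id,
                    "cluster_id": r.cluster_id,
                    "round": r.round,
                    "weight": r.weight,
                    "member_id": m.member_id,
                    "relationship": m.relationship.value,
                    "sex": m.sex.value,
                    "age_years": m.age_years,
                    "education": m.education.value,
                    "de_jure": int(m.de_jure),
                    "de_facto": int(m.de_facto),
                    "is_respondent": int(m.is_respondent),
                }
            )
    return pd.DataFrame(rows, columns=list(ROSTER_COLUMNS))


def write_rosters(rosters: Iterable[HouseholdRoster], path: str | Path) -> None:
    _write_table(rosters_to_frame(rosters), path)


def children_to_frame(children: Iterable[ChildFeedingRecord]) -> pd.DataFrame:
    rows = []
    for c in children:
        row = {
            "child_id": c.child_id,
            "household_id": c.household_id,
            "age_months": c.age_months,
            "is_last_born": int(c.is_last_born),
            "breastfed": int(c.breastfed),
            "feed_count": c.feed_count,
            "solid_feed_count": c.solid_feed_count,
        }
        for g in FOOD_GROUPS:
            v = c.food_groups[g]
            row[f"fg_{g}"] = v if v is None else int(v)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CHILD_COLUMNS))


def write_children(children: Iterable[ChildFeedingRecord], path: str | Path) -> None:
    _write_table(children_to_frame(children), path)


def read_children(path: str | Path) -> list[ChildFeedingRecord]:
    df = _read_table(path)
    _require_columns(df, CHILD_COLUMNS, "child")
    if df.duplicated(subset=["child_id"]).any():
        raise IntegrityError("duplicate child_id in child table")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        fgs = {}
        for g in FOOD_GROUPS:
            v = d[f"fg_{g}"]
            fgs[g] = None if pd.isna(v) else int(v)
        out.append(
            ChildFeedingRecord(
                child_id=str(d["child_id"]),
                household_id=str(d["household_id"]),
                age_months=int(d["age_months"]),
                is_last_born=bool(d["is_last_born"]),
                breastfed=bool(d["breastfed"]),
                food_groups=fgs,
                feed_count=int(d["feed_count"]),
                solid_feed_count=int(d["solid_feed_count"]),
            )
        )
    return out


@dataclass
class EligibleCohort:
    """Analysis cohort (roster, child) pairs plus the exclusion flow.

    ``flow`` counts partition the input children: ``retained`` plus the
    sum of the exclusion counters equals ``n_input``.  Filters are applied
    sequentially in the order listed, mirroring a participant-flow diagram.
    """

    pairs: list[tuple[HouseholdRoster, ChildFeedingRecord]]
    flow: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


def select_eligible(
    rosters: Iterable[HouseholdRoster],
    children: Iterable[ChildFeedingRecord],
    min_age_months: int = 6,
    max_age_months: int = 23,
) -> EligibleCohort:
    """Select last-born children in the eligible age window with a respondent.

    The eligibility window defaults to 6-23 completed months, matching the
    age bands of the meal-frequency indicator; the upper bound is
    configurable for sensitivity analyses.
    """
    by_hh = {r.household_id: r for r in rosters}
    children = list(children)
    missing = sorted({c.household_id for c in children} - set(by_hh))
    if missing:
        raise LinkageError(f"children reference households absent from the roster set: {missing}")

    flow = {
        "n_input": len(children),
        "excluded_not_last_born": 0,
        "excluded_age_below_min": 0,
        "excluded_age_above_max": 0,
        "retained": 0,
    }
    pairs: list[tuple[HouseholdRoster, ChildFeedingRecord]] = []
    for c in children:
        if not c.is_last_born:
            flow["excluded_not_last_born"] += 1
            continue
        if c.age_months < min_age_months:
            flow["excluded_age_below_min"] += 1
            continue
        if c.age_months > max_age_months:
            flow["excluded_age_above_max"] += 1
            continue
        pairs.append((by_hh[c.household_id], c))
        flow["retained"] += 1
    return EligibleCohort(pairs=pairs, flow=flow)
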