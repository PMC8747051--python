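"""Ego-network construction from relationship-to-head codes.

The survey roster records only each member's relationship to the household
head, so pairwise kinship between two non-head members is inferred through a
published rule table keyed on the unordered pair of relationship codes.
Scores are coefficients of relatedness: 0.5 for parent-child and siblings,
0.25 for grandparent-grandchild, 0.125 for aunt/uncle-niece/nephew-type
pairs, and 0 for non-blood pairs (spouses, in-laws, adopted/foster/step
members, non-relatives).  The respondent (ego) is assigned a tie of weight 1
to every household member regardless of kinship; alter-alter ties carry the
relatedness normalized by 0.5 so the strongest kin tie has weight 1.

Pairs whose genealogy is under-determined by the two head-relative codes
(e.g. a head's child and a head's grandchild may be parent and child or
aunt and nephew) resolve to a single documented default; the full 91-pair
table ships as a CSV resource and can be overridden.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path

import numpy as np

from .roster import HouseholdRoster, Member, Relationship

logger = logging.getLogger(__name__)

__all__ = [
    "RELATEDNESS_NORMALIZER",
    "DegenerateNetworkError",
    "RelatednessTable",
    "EgoNetwork",
    "load_relatedness_table",
    "infer_pairwise_relatedness",
    "build_ego_network",
]

#: Raw coefficients are divided by this so a parent-child tie has weight 1.
RELATEDNESS_NORMALIZER = 0.5

#: Relationship-code pairs treated as married couples when spousal ties are enabled.
_SPOUSE_PAIRS = frozenset(
    {
        frozenset({Relationship.HEAD, Relationship.SPOUSE}),
        frozenset({Relationship.CHILD, Relationship.CHILD_IN_LAW}),
        frozenset({Relationship.PARENT}),  # the head's two parents
        frozenset({Relationship.PARENT_IN_LAW}),
    }
)


class DegenerateNetworkError(ValueError):
    """The roster has no alters, so no ego network can be built."""


@dataclass
class RelatednessTable:
    """Symmetric map from unordered relationship-code pairs to relatedness r."""

    pairs: dict[frozenset, float]
    n_unresolved: int = 0  # pairs looked up that were absent from the table

    def lookup(self, a: Relationship, b: Relationship) -> float:
        key = frozenset({a, b})
        try:
            return self.pairs[key]
        except KeyError:
            self.n_unresolved += 1
            logger.warning("unresolved relationship pair (%s, %s); scoring 0", a.value, b.value)
            return 0.0


def load_relatedness_table(path: str | Path | None = None) -> RelatednessTable:
    """Load the pairwise relatedness rules (packaged CSV unless overridden)."""
    if path is None:
        source = files("hhnet").joinpath("resources/relatedness_rules.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    pairs: dict[frozenset, float] = {}
    for row in csv.DictReader(text.splitlines()):
        key = frozenset({Relationship(row["code_a"]), Relationship(row["code_b"])})
        pairs[key] = float(row["relatedness"])
    return RelatednessTable(pairs=pairs)


_DEFAULT_TABLE: RelatednessTable | None = None


def _default_table() -> RelatednessTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_relatedness_table()
    return _DEFAULT_TABLE


def infer_pairwise_relatedness(
    a: Member,
    b: Member,
    table: RelatednessTable | None = None,
) -> float:
    """Coefficient of relatedness between two members of one household.

    Blood relationships only: spouses and in-law pairs score 0 by default.
    """
    table = table or _default_table()
    return table.lookup(a.relationship, b.relationship)


@dataclass
class EgoNetwork:
    """The respondent's household network.

    ``Z`` is the symmetric (n+1) x (n+1) tie-weight matrix with the ego in
    row/column 0.  Ego-alter entries are all 1; alter-alter entries are the
    pairwise relatedness divided by 0.5, hence in {0, 0.25, 0.5, 1}.
    """

    ego: Member
    alters: tuple[Member, ...]
    Z: np.ndarray

    @property
    def n_alters(self) -> int:
        return len(self.alters)

    def alter_tie_matrix(self) -> np.ndarray:
        """The n x n alter-alter block of ``Z``."""
        return self.Z[1:, 1:]


def build_ego_network(
    roster: HouseholdRoster,
    de_facto_only: bool = False,
    include_spousal_ties: bool = False,
    binarize: bool = False,
    table: RelatednessTable | None = None,
) -> EgoNetwork:
    """Build the respondent's ego network from a household roster.

    Parameters
    ----------
    roster:
        The household; must contain the respondent and at least one alter.
    de_facto_only:
        Restrict alters to members present the night before the survey
        instead of the de jure (usual-resident) listing.
    include_spousal_ties:
        Also score married couples (head-spouse, child-child-in-law,
        parent pairs) as tied at weight 1.  Off by default: the printed
        coefficient table is blood-only.
    binarize:
        Replace positive alter-alter weights by 1 (presence/absence only).
    table:
        Override the packaged relatedness rule table.
    """
    table = table or _default_table()
    ego = roster.respondent
    alters = roster.alters(de_facto_only=de_facto_only)
    if not alters:
        raise DegenerateNetworkError(
            f"household {roster.household_id!r} has no alters under the current membership filter"
        )
    n = len(alters)
    Z = np.zeros((n + 1, n + 1))
    Z[0, 1:] = 1.0
    Z[1:, 0] = 1.0
    # half matrix over unordered alter pairs, mirrored for symmetry
    for j in range(n):
        for k in range(j + 1, n):
            w = table.lookup(alters[j].relationship, alters[k].relationship) / RELATEDNESS_NORMALIZER
            if include_spousal_ties and w == 0.0:
                pair = frozenset({alters[j].relationship, alters[k].relationship})
                if pair in _SPOUSE_PAIRS:
                    w = 1.0
            if binarize and w > 0:
                w = 1.0
            Z[j + 1, k + 1] = Z[k + 1, j + 1] = w
    return EgoNetwork(ego=ego, alters=alters, Z=Z)
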