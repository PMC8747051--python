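from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the shared oracles module

from hhnet.roster import Education, HouseholdRoster, Member, Relationship, Sex
from hhnet.simulate import GeneratorConfig, generate_dataset, generate_households


def make_member(
    mid: str,
    rel: Relationship,
    sex: Sex = Sex.FEMALE,
    age: float = 30.0,
    respondent: bool = False,
    de_jure: bool = True,
    de_facto: bool = True,
    education: Education = Education.NONE,
) -> Member:
    return Member(
        member_id=mid,
        relationship=rel,
        sex=sex,
        age_years=age,
        education=education,
        de_jure=de_jure,
        de_facto=de_facto,
        is_respondent=respondent,
    )


def make_roster(*relationships: Relationship, respondent_index: int = 0, **kwargs) -> HouseholdRoster:
    members = tuple(
        make_member(f"m{i}", rel, respondent=(i == respondent_index))
        for i, rel in enumerate(relationships)
    )
    defaults = dict(household_id="h1", cluster_id="c1", round="2016", weight=1.0)
    defaults.update(kwargs)
    return HouseholdRoster(members=members, **defaults)


@pytest.fixture
def nuclear_roster() -> HouseholdRoster:
    """Respondent (head's wife), her husband and their two children."""
    return make_roster(
        Relationship.HEAD, Relationship.SPOUSE, Relationship.CHILD, Relationship.CHILD,
        respondent_index=1,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic survey reused by read-only tests."""
    return generate_dataset(GeneratorConfig(seed=101, n_households=300))


@pytest.fixture(scope="session")
def calibration_cohort():
    """Default-configuration households at a size adequate for medians."""
    return generate_households(GeneratorConfig(seed=7, n_households=2000))
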