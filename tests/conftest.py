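import pytest

from edgame.game_engine import PolicySet, SessionConfig, run_session
from edgame.profile_deck import (
    ActivityRequirement,
    ArrivalSchedule,
    PatientProfile,
    generate_arrivals,
    generate_deck,
)


@pytest.fixture(scope="session")
def deck90():
    return generate_deck(90, 0.15, seed=7)


@pytest.fixture(scope="session")
def default_session(deck90):
    """One full default session (12 rounds, 5 modules) with its log."""
    schedule = generate_arrivals(deck90, 12, 3.0, seed=11)
    return run_session(SessionConfig(seed=11), deck90, schedule, PolicySet())


@pytest.fixture
def empty_schedule():
    return ArrivalSchedule(rounds=12, arrivals=((),) * 12)


def make_profile(pid="P001", urgent=False, activities=None):
    acts = activities or [
        ActivityRequirement(f"{pid}-A1", planned_rounds=1, required_doctors=0, required_nurses=1)
    ]
    return PatientProfile(
        profile_id=pid,
        urgent=urgent,
        priority_class=1 if urgent else 3,
        activities=tuple(acts),
    )


@pytest.fixture
def single_patient_factory():
    return make_profile
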