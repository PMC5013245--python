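import pytest

from knwtriage.cohort import CohortConfig, simulate_cohort
from knwtriage.instruments import (
    DietProfile,
    PAProfile,
    ScreeningProfile,
    SmokingStatus,
)


def healthy_profile(**overrides) -> ScreeningProfile:
    """A profile that classifies green on every topic unless overridden."""
    base = dict(
        cis_fatigue=10,
        hads_a=2,
        hads_d=2,
        mac_neg=20,
        ssl_d=6,
        casun_relationship_needs=False,
        work_needs_total=0,
        work_no_needs=True,
        pa=PAProfile(weekly_mvpa_minutes=300.0, days_with_30min_moderate=7),
        diet=DietProfile(250.0, 3.0, 3.0, 30.0, 5.0),
        smoking=SmokingStatus.NEVER,
    )
    base.update(overrides)
    return ScreeningProfile(**base)


def worst_profile() -> ScreeningProfile:
    """A profile that classifies red on every topic."""
    return ScreeningProfile(
        cis_fatigue=56,
        hads_a=21,
        hads_d=21,
        mac_neg=64,
        ssl_d=24,
        casun_relationship_needs=True,
        work_needs_total=20,
        work_no_needs=False,
        pa=PAProfile(weekly_mvpa_minutes=0.0, days_with_30min_moderate=0),
        diet=DietProfile(0.0, 0.0, 0.0, 0.0, 0.0),
        smoking=SmokingStatus.CURRENT,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-participant synthetic cohort at the published calibration."""
    return simulate_cohort(CohortConfig(n_participants=300, seed=7))
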