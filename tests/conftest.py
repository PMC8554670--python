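import pytest

from mostmh import BehaviorProfile, CheckInEngine, EmotionalRating


def point_rating(level: EmotionalRating) -> dict:
    return {r: (1.0 if r is level else 0.0) for r in EmotionalRating}


def make_profile(level: EmotionalRating, **kwargs) -> BehaviorProfile:
    """Degenerate profile placing all rating mass on one level."""
    defaults = dict(
        name=f"point_{level.value}",
        p_rating=point_rating(level),
        p_stressor={"school": 0.5, "finances": 0.3},
        p_effect={"poor_sleep": 0.5, "low_motivation": 0.4},
        p_low_se=0.0,
    )
    defaults.update(kwargs)
    return BehaviorProfile(**defaults)


@pytest.fixture
def engine() -> CheckInEngine:
    return CheckInEngine()
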