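"""Domain types shared across the engine, simulator, and analytics.

The intervention is a just-in-time adaptive intervention (JITAI): a weekly
emotional-health rating delivered by text message gates a more detailed
web-based check-in (stressor checklist, negative-effect checklist, and a
single self-efficacy item), which in turn drives the cadence of future
check-ins (monthly when no support need is detected, weekly otherwise) and
an escalation rule prompting formal care-seeking.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class EmotionalRating(str, enum.Enum):
    """Five-level emotional-health rating collected by text message."""

    EXCELLENT = "excellent"
    VERY_GOOD = "very_good"
    GOOD = "good"
    FAIR = "fair"
    POOR = "poor"

    @property
    def is_positive(self) -> bool:
        return self in POSITIVE_RATINGS

    @property
    def is_suboptimal(self) -> bool:
        return self in SUBOPTIMAL_RATINGS


POSITIVE_RATINGS = frozenset(
    {EmotionalRating.EXCELLENT, EmotionalRating.VERY_GOOD, EmotionalRating.GOOD}
)
SUBOPTIMAL_RATINGS = frozenset({EmotionalRating.FAIR, EmotionalRating.POOR})


class SelfEfficacyLevel(str, enum.Enum):
    """Response to "To what extent do you feel you can manage your stressors
    and negative effects with supports and skills you have?"."""

    COMPLETELY = "completely"
    SOMEWHAT = "somewhat"
    A_LITTLE = "a_little"
    NOT_AT_ALL = "not_at_all"

    @property
    def is_high(self) -> bool:
        return self in HIGH_SELF_EFFICACY

    @property
    def is_low(self) -> bool:
        return self in LOW_SELF_EFFICACY


HIGH_SELF_EFFICACY = frozenset({SelfEfficacyLevel.COMPLETELY})
LOW_SELF_EFFICACY = frozenset(
    {
        SelfEfficacyLevel.SOMEWHAT,
        SelfEfficacyLevel.A_LITTLE,
        SelfEfficacyLevel.NOT_AT_ALL,
    }
)

# Canonical checklist vocabularies shown on the web check-in page.
STRESSORS: tuple[str, ...] = (
    "school",
    "finances",
    "friends_roommates",
    "family",
    "romantic",
    "other",
)

NEGATIVE_EFFECTS: tuple[str, ...] = (
    "feeling_worn_out",
    "low_motivation",
    "trouble_focusing",
    "poor_sleep",
    "unhealthy_eating",
    "overreacting",
    "no_one_to_talk_to",
    "alcohol_or_drugs",
    "other",
)


@dataclass
class TextCheckIn:
    """One text-message check-in.  ``rating`` is None when the prompt (and
    its single reprompt) went unanswered and the check-in was marked missed.
    """

    day: int
    rating: Optional[EmotionalRating]
    reprompted: bool = False

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("check-in day must be >= 0")


@dataclass
class WebCheckIn:
    """One web-based check-in.  An incomplete check-in carries no content."""

    day: int
    stressors: frozenset[str] = frozenset()
    negative_effects: frozenset[str] = frozenset()
    self_efficacy: Optional[SelfEfficacyLevel] = None
    completed: bool = True

    def __post_init__(self) -> None:
        self.stressors = frozenset(self.stressors)
        self.negative_effects = frozenset(self.negative_effects)
        unknown = self.stressors - set(STRESSORS)
        if unknown:
            raise ValueError(f"unknown stressor token(s): {sorted(unknown)}")
        unknown = self.negative_effects - set(NEGATIVE_EFFECTS)
        if unknown:
            raise ValueError(f"unknown negative-effect token(s): {sorted(unknown)}")
        if not self.completed and (
            self.stressors or self.negative_effects or self.self_efficacy is not None
        ):
            raise ValueError("incomplete web check-in must have no content fields")


@dataclass
class CheckInRecord:
    """A text check-in paired with the web check-in it triggered, if any."""

    text: TextCheckIn
    web: Optional[WebCheckIn] = None


class ActionKind(str, enum.Enum):
    """Everything the engine can emit toward a participant."""

    SEND_WELCOME = "send_welcome"
    SEND_TEXT_CHECKIN = "send_text_checkin"
    SEND_POSITIVE_FEEDBACK_WITH_VIDEO = "send_positive_feedback_with_video"
    SEND_WEB_LINK = "send_web_link"
    SEND_SKILL_MESSAGE = "send_skill_message"
    SEND_WEEKLY_CONSENT_ASK = "send_weekly_consent_ask"
    SEND_CARE_PROMPT = "send_care_prompt"
    SEND_SAFETY_CARE_PROMPT = "send_safety_care_prompt"
    REPROMPT = "reprompt"
    NONE = "none"


@dataclass
class EngineAction:
    """An outbound event: the kind, message payload tokens, and (for
    scheduling actions) the day the payload refers to."""

    kind: ActionKind
    payload: dict = field(default_factory=dict)
    scheduled_day: Optional[int] = None


@dataclass(frozen=True)
class SetComparison:
    """Difference of one checklist between two consecutive web check-ins."""

    resolved: frozenset[str]
    persisting: frozenset[str]
    new: frozenset[str]


@dataclass(frozen=True)
class ComparisonRecord:
    """compare_checkins output: stressors and negative effects separately."""

    stressors: SetComparison
    negative_effects: SetComparison


@dataclass
class PendingPrompt:
    """An outstanding prompt awaiting a reply (text check-in or web link)."""

    prompt_day: int
    reprompted: bool = False


@dataclass
class ParticipantState:
    """The engine's complete per-participant memory.

    Invariants: ``quit`` implies ``active`` is False; ``next_checkin_day`` is
    None iff not active; ``consecutive_flag_count`` counts successive
    qualifying (suboptimal rating + low self-efficacy) check-ins and resets
    on any observed non-qualifying one.
    """

    participant_id: str
    enrolled_day: int
    current_day: int = 0
    next_checkin_day: Optional[int] = None
    history: list[CheckInRecord] = field(default_factory=list)
    consecutive_flag_count: int = 0
    active: bool = True
    quit: bool = False
    pending_text: Optional[PendingPrompt] = None
    pending_web: Optional[PendingPrompt] = None
    skill_cursor: int = 0
    escalation_days: list[int] = field(default_factory=list)

    def copy(self) -> "ParticipantState":
        """Cheap deep copy (the state graph is shallow by construction)."""
        return ParticipantState(
            participant_id=self.participant_id,
            enrolled_day=self.enrolled_day,
            current_day=self.current_day,
            next_checkin_day=self.next_checkin_day,
            history=[CheckInRecord(text=r.text, web=r.web) for r in self.history],
            consecutive_flag_count=self.consecutive_flag_count,
            active=self.active,
            quit=self.quit,
            pending_text=(
                PendingPrompt(self.pending_text.prompt_day, self.pending_text.reprompted)
                if self.pending_text
                else None
            ),
            pending_web=(
                PendingPrompt(self.pending_web.prompt_day, self.pending_web.reprompted)
                if self.pending_web
                else None
            ),
            skill_cursor=self.skill_cursor,
            escalation_days=list(self.escalation_days),
        )
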