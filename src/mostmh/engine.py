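"""Deterministic per-participant state machine for adaptive check-ins.

The protocol, in the order a participant experiences it:

1. Enrollment: a welcome sequence; the first text check-in lands on the
   enrollment day itself.
2. Text check-in: "How would you rate your emotional health this past
   week?".  A positive rating (excellent / very good / good) earns positive
   feedback plus a psychoeducation video link and steps the cadence *down*
   to monthly.  A suboptimal rating (fair / poor) triggers a web check-in
   link instead.
3. Web check-in: stressor and negative-effect checklists plus a single
   self-efficacy item.  High self-efficacy ("completely") behaves like a
   positive rating (monthly cadence); low self-efficacy steps the cadence
   *up* to weekly, delivers a coping-skill message, the video link, and a
   consent ask for the weekly follow-up.  From the second completed web
   check-in onward, feedback carries a comparison against the prior
   check-in (resolved / persisting / new stressors and effects), and
   repeated low self-efficacy adds a care-seeking prompt.
4. Safety escalation: two qualifying check-ins (suboptimal rating + low
   self-efficacy) no more than 14 days apart trigger a formal
   care-seeking safety prompt.

Every prompt is reprompted at most once; a check-in still unanswered after
the reprompt window is marked missed and the participant is re-approached
a week later.  Texting "quit" is absorbing: no action is ever emitted
afterwards.  The clock is whole days; the program runs for 90 days.

All transition functions mutate the passed state in place and return it
alongside the emitted actions; use ``ParticipantState.copy()`` when an
unmodified snapshot is needed.  Given equal states and inputs the emitted
actions are identical — the engine holds no hidden randomness.
"""

from __future__ import annotations

from typing import Optional

from .config import Config, EngineConfig
from .types import (
    ActionKind,
    CheckInRecord,
    ComparisonRecord,
    EmotionalRating,
    EngineAction,
    ParticipantState,
    PendingPrompt,
    SelfEfficacyLevel,
    SetComparison,
    SUBOPTIMAL_RATINGS,
    TextCheckIn,
    WebCheckIn,
)


class ProtocolError(RuntimeError):
    """An input arrived out of protocol order (no matching pending prompt)."""


class AlreadyEnrolledError(ValueError):
    """start_program called twice for the same participant id."""


class TimeReversalError(ValueError):
    """advance_clock asked to move the clock backwards."""


_QUIT = "quit"

# Accepted spellings of each rating, lowercase, single-spaced.
_RATING_WORDS = {
    "excellent": EmotionalRating.EXCELLENT,
    "very good": EmotionalRating.VERY_GOOD,
    "very_good": EmotionalRating.VERY_GOOD,
    "good": EmotionalRating.GOOD,
    "fair": EmotionalRating.FAIR,
    "poor": EmotionalRating.POOR,
}


def parse_reply(reply: str) -> Optional[EmotionalRating | str]:
    """Parse a raw text reply.

    Returns an :class:`EmotionalRating`, the string ``"quit"`` for a quit
    request, or None when the reply is unparseable.  Matching is
    case-insensitive and whitespace-tolerant; anything beyond the five
    rating words and "quit" is unparseable by design.
    """
    norm = " ".join(reply.strip().lower().split())
    if norm == _QUIT:
        return _QUIT
    return _RATING_WORDS.get(norm)


def compare_checkins(prior: WebCheckIn, current: WebCheckIn) -> ComparisonRecord:
    """Set-difference of two completed web check-ins, per checklist.

    ``resolved`` items were reported before but not now, ``persisting``
    both times, ``new`` only now.  The three sets partition the union of
    the two reports; feedback phrases resolved items as improvement and
    persisting items as still unresolved.
    """
    if not prior.completed or not current.completed:
        raise ValueError("compare_checkins requires two completed web check-ins")

    def diff(a: frozenset[str], b: frozenset[str]) -> SetComparison:
        return SetComparison(resolved=a - b, persisting=a & b, new=b - a)

    return ComparisonRecord(
        stressors=diff(prior.stressors, current.stressors),
        negative_effects=diff(prior.negative_effects, current.negative_effects),
    )


def decide_next_checkin(
    rating: EmotionalRating,
    self_efficacy: Optional[SelfEfficacyLevel],
    current_day: int,
    *,
    active: bool = True,
    config: EngineConfig | None = None,
) -> Optional[int]:
    """Step-down / step-up scheduling rule.

    Positive rating, or suboptimal rating with high self-efficacy, steps
    down to the monthly interval; suboptimal with low self-efficacy steps
    up to weekly.  Inactive (quit or completed) participants get None.
    """
    cfg = config or EngineConfig()
    if not active:
        return None
    if rating.is_positive or (self_efficacy is not None and self_efficacy.is_high):
        return current_day + cfg.monthly_interval_days
    return current_day + cfg.weekly_interval_days


def _qualifying(record: CheckInRecord, cfg: EngineConfig) -> bool:
    """Does one check-in meet the escalation rule (suboptimal + low SE)?"""
    if record.text.rating is None:
        return False
    if cfg.escalation_rating == "poor":
        if record.text.rating is not EmotionalRating.POOR:
            return False
    elif record.text.rating not in SUBOPTIMAL_RATINGS:
        return False
    web = record.web
    return web is not None and web.completed and web.self_efficacy is not None and web.self_efficacy.is_low


def check_safety_escalation(
    state: ParticipantState, config: EngineConfig | None = None
) -> bool:
    """True iff the two most recent check-ins both qualify (suboptimal
    rating and low self-efficacy) and fall within the consecutiveness
    window (<= 14 days apart by default) — "2 weeks in a row"."""
    cfg = config or EngineConfig()
    if len(state.history) < 2:
        return False
    prev, last = state.history[-2], state.history[-1]
    if not (_qualifying(prev, cfg) and _qualifying(last, cfg)):
        return False
    return abs(last.text.day - prev.text.day) <= cfg.escalation_window_days


class CheckInEngine:
    """The adaptive check-in protocol bound to one configuration.

    The engine itself is stateless apart from a registry of enrolled ids
    (used only to reject duplicate enrollment); all per-participant memory
    lives in :class:`ParticipantState`.
    """

    def __init__(self, config: Config | EngineConfig | None = None) -> None:
        if isinstance(config, Config):
            self.config = config.engine
        else:
            self.config = config or EngineConfig()
        self._enrolled: set[str] = set()

    # ------------------------------------------------------------------
    # enrollment
    # ------------------------------------------------------------------
    def start_program(
        self, participant_id: str, enrolled_day: int
    ) -> tuple[ParticipantState, list[EngineAction]]:
        """Enroll a participant: welcome sequence, first check-in scheduled
        on the enrollment day itself."""
        if participant_id in self._enrolled:
            raise AlreadyEnrolledError(f"participant {participant_id!r} already enrolled")
        if enrolled_day < 0:
            raise ValueError("enrolled_day must be >= 0")
        self._enrolled.add(participant_id)
        state = ParticipantState(
            participant_id=participant_id,
            enrolled_day=enrolled_day,
            current_day=enrolled_day,
            next_checkin_day=enrolled_day,
        )
        actions = [
            EngineAction(
                ActionKind.SEND_WELCOME,
                payload={"template": "welcome"},
                scheduled_day=enrolled_day,
            ),
            EngineAction(
                ActionKind.SEND_WELCOME,
                payload={"template": "welcome_quit_info"},
                scheduled_day=enrolled_day,
            ),
        ]
        return state, actions

    # ------------------------------------------------------------------
    # clock
    # ------------------------------------------------------------------
    def advance_clock(
        self, state: ParticipantState, to_day: int
    ) -> tuple[ParticipantState, list[EngineAction]]:
        """Advance the participant's clock, firing due prompts, reprompts,
        missed-markings, and the horizon shutdown along the way."""
        if to_day < state.current_day:
            raise TimeReversalError(
                f"cannot move clock from day {state.current_day} back to {to_day}"
            )
        if state.quit or not state.active:
            state.current_day = to_day
            return state, []

        cfg = self.config
        actions: list[EngineAction] = []
        for day in range(state.current_day, to_day + 1):
            if not state.active:
                break
            # Reprompt-once / missed-marking for an outstanding text prompt.
            pt = state.pending_text
            if pt is not None:
                if not pt.reprompted and day >= pt.prompt_day + cfg.reprompt_after_days:
                    pt.reprompted = True
                    actions.append(
                        EngineAction(
                            ActionKind.REPROMPT,
                            payload={"template": "text_checkin", "of": "text_checkin"},
                            scheduled_day=day,
                        )
                    )
                elif pt.reprompted and day >= pt.prompt_day + cfg.missing_after_days:
                    state.history.append(
                        CheckInRecord(TextCheckIn(pt.prompt_day, None, reprompted=True))
                    )
                    state.next_checkin_day = pt.prompt_day + cfg.missing_reschedule_days
                    state.pending_text = None
            # Same policy for an outstanding web link.
            pw = state.pending_web
            if pw is not None:
                if not pw.reprompted and day >= pw.prompt_day + cfg.reprompt_after_days:
                    pw.reprompted = True
                    actions.append(
                        EngineAction(
                            ActionKind.REPROMPT,
                            payload={"template": "web_link", "of": "web_link",
                                     "web_checkin_url": cfg.web_checkin_url},
                            scheduled_day=day,
                        )
                    )
                elif pw.reprompted and day >= pw.prompt_day + cfg.missing_after_days:
                    # Missed web data: recorded, but never feeds escalation.
                    if state.history and state.history[-1].web is None:
                        state.history[-1].web = WebCheckIn(day=pw.prompt_day, completed=False)
                    state.next_checkin_day = pw.prompt_day + cfg.missing_reschedule_days
                    state.pending_web = None
            # Scheduled check-in fires once no prompt is outstanding; a
            # check-in scheduled at/after the horizon ends the program.
            if (
                state.next_checkin_day is not None
                and state.pending_text is None
                and state.pending_web is None
            ):
                if state.next_checkin_day >= cfg.horizon_days:
                    state.active = False
                    state.next_checkin_day = None
                elif day >= state.next_checkin_day:
                    state.pending_text = PendingPrompt(prompt_day=day)
                    actions.append(
                        EngineAction(
                            ActionKind.SEND_TEXT_CHECKIN,
                            payload={"template": "text_checkin"},
                            scheduled_day=day,
                        )
                    )
        state.current_day = to_day
        return state, actions

    # ------------------------------------------------------------------
    # text replies
    # ------------------------------------------------------------------
    def process_text_reply(
        self, state: ParticipantState, day: int, reply: str
    ) -> tuple[ParticipantState, list[EngineAction]]:
        """Consume a raw text reply to a pending check-in prompt."""
        if state.quit:
            return state, []
        if state.pending_text is None:
            raise ProtocolError(
                f"participant {state.participant_id!r} has no pending text check-in"
            )
        if day < state.pending_text.prompt_day:
            raise ProtocolError("reply dated before the prompt it answers")
        state.current_day = max(state.current_day, day)
        cfg = self.config
        prompt = state.pending_text
        parsed = parse_reply(reply)

        if parsed == _QUIT:
            state.quit = True
            state.active = False
            state.next_checkin_day = None
            state.pending_text = None
            state.pending_web = None
            return state, []

        if parsed is None:
            if not prompt.reprompted:
                prompt.reprompted = True
                return state, [
                    EngineAction(
                        ActionKind.REPROMPT,
                        payload={"template": "text_checkin", "of": "text_checkin"},
                        scheduled_day=day,
                    )
                ]
            # Second unparseable reply: mark missed, re-approach in a week.
            state.history.append(
                CheckInRecord(TextCheckIn(prompt.prompt_day, None, reprompted=True))
            )
            state.next_checkin_day = prompt.prompt_day + cfg.missing_reschedule_days
            state.pending_text = None
            return state, []

        rating: EmotionalRating = parsed
        record = CheckInRecord(
            TextCheckIn(prompt.prompt_day, rating, reprompted=prompt.reprompted)
        )
        state.history.append(record)
        state.pending_text = None

        if rating.is_positive:
            state.consecutive_flag_count = 0
            state.next_checkin_day = decide_next_checkin(rating, None, day, config=cfg)
            return state, [
                EngineAction(
                    ActionKind.SEND_POSITIVE_FEEDBACK_WITH_VIDEO,
                    payload={"template": "positive_feedback", "video_url": cfg.video_url},
                    scheduled_day=day,
                )
            ]

        # Suboptimal rating: hand off to the web check-in.  Provisionally
        # schedule the missed-response fallback; a completed web check-in
        # overwrites it.
        state.pending_web = PendingPrompt(prompt_day=day)
        state.next_checkin_day = day + cfg.missing_reschedule_days
        return state, [
            EngineAction(
                ActionKind.SEND_WEB_LINK,
                payload={"template": "web_link", "web_checkin_url": cfg.web_checkin_url},
                scheduled_day=day,
            )
        ]

    # ------------------------------------------------------------------
    # web check-ins
    # ------------------------------------------------------------------
    def process_web_checkin(
        self, state: ParticipantState, checkin: WebCheckIn
    ) -> tuple[ParticipantState, list[EngineAction]]:
        """Consume a submitted web check-in for an outstanding link."""
        if state.quit:
            return state, []
        if state.pending_web is None:
            raise ProtocolError(
                f"participant {state.participant_id!r} has no outstanding web link"
            )
        cfg = self.config
        link_day = state.pending_web.prompt_day
        state.current_day = max(state.current_day, checkin.day)

        if not checkin.completed:
            # Explicit missed marking: same path as the reprompt timeout.
            if state.history and state.history[-1].web is None:
                state.history[-1].web = checkin
            state.next_checkin_day = link_day + cfg.missing_reschedule_days
            state.pending_web = None
            return state, []

        if checkin.self_efficacy is None:
            raise ValueError("completed web check-in must carry a self-efficacy level")

        # Comparison against the most recent prior completed web check-in.
        prior = next(
            (r.web for r in reversed(state.history) if r.web is not None and r.web.completed),
            None,
        )
        comparison = compare_checkins(prior, checkin) if prior is not None else None

        if not state.history or state.history[-1].web is not None:
            raise ProtocolError("web check-in arrived without a matching text check-in")
        state.history[-1].web = checkin
        state.pending_web = None

        actions: list[EngineAction] = []
        payload_common: dict = {"video_url": cfg.video_url}
        if comparison is not None:
            payload_common["comparison"] = comparison

        rating = state.history[-1].text.rating
        if checkin.self_efficacy.is_high:
            state.consecutive_flag_count = 0
            actions.append(
                EngineAction(
                    ActionKind.SEND_POSITIVE_FEEDBACK_WITH_VIDEO,
                    payload={
                        "template": "positive_feedback_comparison"
                        if comparison is not None
                        else "positive_feedback",
                        **payload_common,
                    },
                    scheduled_day=checkin.day,
                )
            )
        else:
            state.consecutive_flag_count += 1
            actions.append(
                EngineAction(
                    ActionKind.SEND_SKILL_MESSAGE,
                    payload={
                        "skill_index": state.skill_cursor,
                        **payload_common,
                    },
                    scheduled_day=checkin.day,
                )
            )
            state.skill_cursor += 1
            actions.append(
                EngineAction(
                    ActionKind.SEND_WEEKLY_CONSENT_ASK,
                    payload={"template": "weekly_consent_ask"},
                    scheduled_day=checkin.day,
                )
            )
            if state.consecutive_flag_count >= 2:
                actions.append(
                    EngineAction(
                        ActionKind.SEND_CARE_PROMPT,
                        payload={"template": "care_prompt"},
                        scheduled_day=checkin.day,
                    )
                )
            if check_safety_escalation(state, cfg):
                pair_day = state.history[-1].text.day
                if pair_day not in state.escalation_days:
                    state.escalation_days.append(pair_day)
                    actions.append(
                        EngineAction(
                            ActionKind.SEND_SAFETY_CARE_PROMPT,
                            payload={"template": "safety_care_prompt"},
                            scheduled_day=checkin.day,
                        )
                    )

        state.next_checkin_day = decide_next_checkin(
            rating, checkin.self_efficacy, checkin.day, config=cfg
        )
        return state, actions
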