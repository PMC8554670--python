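"""Engine state-machine behavior: branching, scheduling, escalation,
comparison algebra, reprompt policy, and replay determinism."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from mostmh import (
    ActionKind,
    AlreadyEnrolledError,
    CheckInEngine,
    CheckInRecord,
    EmotionalRating,
    ProtocolError,
    SelfEfficacyLevel,
    TextCheckIn,
    TimeReversalError,
    WebCheckIn,
    check_safety_escalation,
    compare_checkins,
    decide_next_checkin,
    parse_reply,
)
from mostmh.types import ParticipantState, STRESSORS

R = EmotionalRating
SE = SelfEfficacyLevel


def enroll(engine, pid="p1", day=0):
    state, actions = engine.start_program(pid, day)
    state, more = engine.advance_clock(state, day)
    return state, actions + more


def web(day, se, stressors=(), effects=()):
    return WebCheckIn(day=day, stressors=frozenset(stressors),
                      negative_effects=frozenset(effects), self_efficacy=se)


def record(day, rating, se=None):
    w = web(day, se) if se is not None else None
    return CheckInRecord(TextCheckIn(day, rating), w)


# ----------------------------------------------------------------------
# enrollment
# ----------------------------------------------------------------------
class TestStartProgram:
    def test_welcome_then_first_checkin_on_enrollment_day(self, engine):
        state, actions = enroll(engine)
        kinds = [a.kind for a in actions]
        assert kinds[0] is ActionKind.SEND_WELCOME
        assert ActionKind.SEND_TEXT_CHECKIN in kinds
        assert state.pending_text.prompt_day == 0

    def test_duplicate_enrollment_rejected(self, engine):
        engine.start_program("p1", 0)
        with pytest.raises(AlreadyEnrolledError):
            engine.start_program("p1", 0)

    def test_enrollment_relative_clock(self, engine):
        state, _ = engine.start_program("p2", 5)
        assert state.next_checkin_day == 5


# ----------------------------------------------------------------------
# text replies
# ----------------------------------------------------------------------
class TestTextReply:
    @pytest.mark.parametrize("reply", ["good", "GOOD", "  Very Good ", "excellent"])
    def test_positive_rating_gets_feedback_and_video(self, engine, reply):
        state, _ = enroll(engine)
        state, actions = engine.process_text_reply(state, 0, reply)
        assert [a.kind for a in actions] == [ActionKind.SEND_POSITIVE_FEEDBACK_WITH_VIDEO]
        assert state.next_checkin_day == 30

    @pytest.mark.parametrize("reply", ["fair", "poor", "Poor"])
    def test_suboptimal_rating_gets_web_link(self, engine, reply):
        state, _ = enroll(engine)
        state, actions = engine.process_text_reply(state, 0, reply)
        assert [a.kind for a in actions] == [ActionKind.SEND_WEB_LINK]
        assert state.pending_web is not None

    def test_quit_is_absorbing(self, engine):
        state, _ = enroll(engine)
        state, actions = engine.process_text_reply(state, 0, "Quit")
        assert actions == []
        assert state.quit and not state.active and state.next_checkin_day is None
        for day in (1, 30, 89):
            state, actions = engine.advance_clock(state, day)
            assert actions == []

    def test_unparseable_reply_reprompted_exactly_once(self, engine):
        state, _ = enroll(engine)
        state, actions = engine.process_text_reply(state, 0, "meh")
        assert [a.kind for a in actions] == [ActionKind.REPROMPT]
        state, actions = engine.process_text_reply(state, 0, "still meh")
        assert actions == []  # marked missed, no second reprompt
        assert state.history[-1].text.rating is None
        assert state.next_checkin_day == 7  # conservative weekly retry

    def test_reply_without_pending_prompt_is_protocol_error(self, engine):
        state, _ = engine.start_program("p1", 0)
        state.pending_text = None
        with pytest.raises(ProtocolError):
            engine.process_text_reply(state, 0, "good")

    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("excellent", R.EXCELLENT),
            ("very good", R.VERY_GOOD),
            ("very_good", R.VERY_GOOD),
            ("qUiT", "quit"),
            ("fine", None),
            ("", None),
        ],
    )
    def test_parse_reply(self, raw, expected):
        assert parse_reply(raw) == expected


# ----------------------------------------------------------------------
# web check-ins
# ----------------------------------------------------------------------
class TestWebCheckIn:
    def _to_web(self, engine, state, day, rating="poor"):
        state, _ = engine.advance_clock(state, day)
        state, actions = engine.process_text_reply(state, day, rating)
        assert actions[-1].kind is ActionKind.SEND_WEB_LINK
        return state

    def test_high_self_efficacy_steps_down_to_monthly(self, engine):
        state, _ = enroll(engine)
        state = self._to_web(engine, state, 0, "fair")
        state, actions = engine.process_web_checkin(state, web(0, SE.COMPLETELY))
        assert [a.kind for a in actions] == [ActionKind.SEND_POSITIVE_FEEDBACK_WITH_VIDEO]
        assert state.next_checkin_day == 30
        assert state.consecutive_flag_count == 0

    def test_low_self_efficacy_steps_up_to_weekly_with_skill(self, engine):
        state, _ = enroll(engine)
        state = self._to_web(engine, state, 0)
        state, actions = engine.process_web_checkin(state, web(0, SE.A_LITTLE))
        kinds = [a.kind for a in actions]
        assert kinds == [ActionKind.SEND_SKILL_MESSAGE, ActionKind.SEND_WEEKLY_CONSENT_ASK]
        assert state.next_checkin_day == 7
        assert state.consecutive_flag_count == 1

    def test_second_consecutive_low_se_adds_care_and_safety_prompts(self, engine):
        state, _ = enroll(engine)
        state = self._to_web(engine, state, 0)
        state, _ = engine.process_web_checkin(state, web(0, SE.NOT_AT_ALL))
        state = self._to_web(engine, state, 7)
        state, actions = engine.process_web_checkin(state, web(7, SE.SOMEWHAT))
        kinds = [a.kind for a in actions]
        assert ActionKind.SEND_CARE_PROMPT in kinds
        assert ActionKind.SEND_SAFETY_CARE_PROMPT in kinds

    def test_feedback_carries_comparison_from_prior_checkin(self, engine):
        state, _ = enroll(engine)
        state = self._to_web(engine, state, 0)
        state, _ = engine.process_web_checkin(
            state, web(0, SE.SOMEWHAT, stressors={"school", "finances"})
        )
        state = self._to_web(engine, state, 7)
        state, actions = engine.process_web_checkin(
            state, web(7, SE.SOMEWHAT, stressors={"school"})
        )
        comparison = actions[0].payload["comparison"]
        assert comparison.stressors.resolved == {"finances"}
        assert comparison.stressors.persisting == {"school"}

    def test_positive_rating_resets_flag_count(self, engine):
        state, _ = enroll(engine)
        state = self._to_web(engine, state, 0)
        state, _ = engine.process_web_checkin(state, web(0, SE.SOMEWHAT))
        state, _ = engine.advance_clock(state, 7)
        state, _ = engine.process_text_reply(state, 7, "good")
        assert state.consecutive_flag_count == 0

    def test_web_checkin_without_outstanding_link_is_protocol_error(self, engine):
        state, _ = enroll(engine)
        with pytest.raises(ProtocolError):
            engine.process_web_checkin(state, web(0, SE.COMPLETELY))

    def test_unknown_checklist_token_is_validation_error(self):
        with pytest.raises(ValueError):
            WebCheckIn(day=0, stressors=frozenset({"weather"}), self_efficacy=SE.SOMEWHAT)


# ----------------------------------------------------------------------
# scheduling rule
# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "rating,se,day,expected",
    [
        (R.GOOD, None, 10, 40),
        (R.POOR, SE.NOT_AT_ALL, 10, 17),
        (R.FAIR, SE.COMPLETELY, 0, 30),
        (R.EXCELLENT, None, 0, 30),
        (R.FAIR, SE.SOMEWHAT, 5, 12),
    ],
)
def test_decide_next_checkin(rating, se, day, expected):
    assert decide_next_checkin(rating, se, day) == expected


def test_decide_next_checkin_inactive_returns_none():
    assert decide_next_checkin(R.GOOD, None, 10, active=False) is None


# ----------------------------------------------------------------------
# safety escalation
# ----------------------------------------------------------------------
class TestSafetyEscalation:
    def _state_with(self, records):
        state = ParticipantState("p", 0)
        state.history = list(records)
        return state

    def test_two_qualifying_weekly_checkins_escalate(self):
        state = self._state_with([record(0, R.POOR, SE.SOMEWHAT), record(7, R.POOR, SE.SOMEWHAT)])
        assert check_safety_escalation(state) is True

    def test_single_observation_cannot_be_in_a_row(self):
        state = self._state_with([record(0, R.POOR, SE.SOMEWHAT)])
        assert check_safety_escalation(state) is False

    def test_monthly_gap_is_not_consecutive(self):
        state = self._state_with([record(0, R.POOR, SE.SOMEWHAT), record(30, R.POOR, SE.SOMEWHAT)])
        assert check_safety_escalation(state) is False

    def test_brute_force_oracle_over_two_element_histories(self):
        """Exhaustive agreement with the definition: both of the last two
        check-ins suboptimal + low self-efficacy, <= 14 days apart."""

        def oracle(r1, s1, r2, s2, gap):
            def q(r, s):
                return r in (R.FAIR, R.POOR) and s is not None and s.is_low
            return q(r1, s1) and q(r2, s2) and gap <= 14

        ses = list(SE) + [None]
        for r1, s1, r2, s2 in itertools.product(R, ses, R, ses):
            for gap in (0, 7, 13, 14, 15, 21, 30):
                state = self._state_with([record(0, r1, s1), record(gap, r2, s2)])
                assert check_safety_escalation(state) == oracle(r1, s1, r2, s2, gap)

    def test_escalation_fires_at_most_once_per_qualifying_pair(self, engine):
        state, _ = enroll(engine)
        fired = []
        for day in (0, 7, 14):
            state, _ = engine.advance_clock(state, day)
            state, _ = engine.process_text_reply(state, day, "poor")
            state, actions = engine.process_web_checkin(state, web(day, SE.SOMEWHAT))
            fired += [a for a in actions if a.kind is ActionKind.SEND_SAFETY_CARE_PROMPT]
        # day-7 and day-14 check-ins each complete a new qualifying pair
        assert len(fired) == 2


# ----------------------------------------------------------------------
# comparison algebra
# ----------------------------------------------------------------------
class TestCompareCheckins:
    def test_resolved_persisting_new(self):
        c = compare_checkins(
            web(0, SE.SOMEWHAT, stressors={"school", "finances"}),
            web(7, SE.SOMEWHAT, stressors={"school"}),
        )
        assert c.stressors.resolved == {"finances"}
        assert c.stressors.persisting == {"school"}
        assert c.stressors.new == set()

    def test_identity_case(self):
        w = web(0, SE.SOMEWHAT, stressors={"school"}, effects={"poor_sleep"})
        c = compare_checkins(w, web(7, SE.SOMEWHAT, stressors={"school"}, effects={"poor_sleep"}))
        assert not c.stressors.resolved and not c.stressors.new
        assert not c.negative_effects.resolved and not c.negative_effects.new

    def test_empty_prior(self):
        c = compare_checkins(web(0, SE.SOMEWHAT), web(7, SE.SOMEWHAT, effects={"poor_sleep"}))
        assert c.negative_effects.new == {"poor_sleep"}

    def test_incomplete_checkin_is_error(self):
        with pytest.raises(ValueError):
            compare_checkins(WebCheckIn(day=0, completed=False), web(7, SE.SOMEWHAT))

    @given(
        prior=st.sets(st.sampled_from(STRESSORS)),
        current=st.sets(st.sampled_from(STRESSORS)),
    )
    @settings(max_examples=200, derandomize=True)
    def test_set_identities(self, prior, current):
        c = compare_checkins(
            web(0, SE.SOMEWHAT, stressors=prior), web(7, SE.SOMEWHAT, stressors=current)
        ).stressors
        assert c.resolved | c.persisting == frozenset(prior)
        assert c.new | c.persisting == frozenset(current)
        assert not (c.resolved & c.persisting or c.resolved & c.new or c.persisting & c.new)


# ----------------------------------------------------------------------
# clock
# ----------------------------------------------------------------------
class TestAdvanceClock:
    def test_scheduler_fires_on_due_day(self, engine):
        state, _ = enroll(engine)
        state, _ = engine.process_text_reply(state, 0, "good")
        state, actions = engine.advance_clock(state, 30)
        assert ActionKind.SEND_TEXT_CHECKIN in [a.kind for a in actions]

    def test_unanswered_prompt_gets_exactly_one_reprompt(self, engine):
        state, _ = enroll(engine)
        state, actions = engine.advance_clock(state, 6)
        reprompts = [a for a in actions if a.kind is ActionKind.REPROMPT]
        assert len(reprompts) == 1
        # missed check-in recorded, weekly retry scheduled
        assert state.history[-1].text.rating is None
        assert state.next_checkin_day == 7

    def test_time_reversal_rejected(self, engine):
        state, _ = enroll(engine)
        state, _ = engine.advance_clock(state, 10)
        with pytest.raises(TimeReversalError):
            engine.advance_clock(state, 5)

    def test_program_ends_at_horizon(self, engine):
        state, _ = enroll(engine)
        state, _ = engine.process_text_reply(state, 0, "good")
        for day in (30, 60):
            state, _ = engine.advance_clock(state, day)
            state, _ = engine.process_text_reply(state, day, "good")
        state, actions = engine.advance_clock(state, 95)
        assert not state.active and not state.quit
        assert state.next_checkin_day is None
        assert ActionKind.SEND_TEXT_CHECKIN not in [a.kind for a in actions]


# ----------------------------------------------------------------------
# stream-level properties
# ----------------------------------------------------------------------
def drive(replies, horizon=90):
    """Drive a fresh engine with a cyclic reply policy.

    Returns (actions, n_positive_replies, n_suboptimal_replies,
    n_high_se_webs): web check-ins alternate low/high self-efficacy.
    """
    engine = CheckInEngine()
    state, actions = engine.start_program("p", 0)
    all_actions = list(actions)
    i = n_pos = n_sub = n_high = 0
    for day in range(horizon):
        if not state.active:
            break
        state, acts = engine.advance_clock(state, day)
        all_actions += acts
        for a in acts:
            if a.kind is ActionKind.SEND_TEXT_CHECKIN:
                reply = replies[i % len(replies)]
                i += 1
                state, more = engine.process_text_reply(state, day, reply)
                all_actions += more
                if reply in ("fair", "poor"):
                    n_sub += 1
                else:
                    n_pos += 1
                for b in more:
                    if b.kind is ActionKind.SEND_WEB_LINK:
                        high = i % 2 == 0
                        n_high += high
                        se = SE.COMPLETELY if high else SE.SOMEWHAT
                        state, ws = engine.process_web_checkin(state, web(day, se))
                        all_actions += ws
    return all_actions, n_pos, n_sub, n_high


@given(st.lists(st.sampled_from(["excellent", "very good", "good", "fair", "poor"]),
                min_size=1, max_size=13))
@settings(max_examples=150, derandomize=True)
def test_rating_branching_invariant(replies):
    """Every suboptimal rating is followed by exactly one web link, every
    positive rating (or high-self-efficacy web check-in) by exactly one
    positive-feedback action; check-in counts stay in [3, 13]."""
    actions, n_pos, n_sub, n_high = drive(replies)
    n_checkins = sum(1 for a in actions if a.kind is ActionKind.SEND_TEXT_CHECKIN)
    n_web = sum(1 for a in actions if a.kind is ActionKind.SEND_WEB_LINK)
    n_feedback = sum(
        1 for a in actions if a.kind is ActionKind.SEND_POSITIVE_FEEDBACK_WITH_VIDEO
    )
    assert 3 <= n_checkins <= 13
    assert n_web == n_sub
    assert n_feedback == n_pos + n_high


def test_replaying_identical_stream_is_deterministic():
    """The engine is a pure function of (state, input, clock)."""
    replies = ["fair", "good", "poor", "poor", "very good"]
    a1, *_ = drive(replies)
    a2, *_ = drive(replies)
    assert [(a.kind, a.scheduled_day, repr(a.payload)) for a in a1] == [
        (a.kind, a.scheduled_day, repr(a.payload)) for a in a2
    ]
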