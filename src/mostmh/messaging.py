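"""Message templates and tailored-feedback rendering.

Message content is data, not logic: every outbound action kind maps to at
least one template with ``{placeholder}`` slots.  Feedback after a repeat
web check-in interpolates the comparison record — items no longer reported
are phrased as improvement, items reported both times as still unresolved.
The default skill library is a small illustrative set drawn from the
strategy families the program uses (positive psychology, cognitive
behavioral therapy, dialectical behavioral therapy); deployments replace
it through configuration.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Optional

from .config import Config
from .types import ActionKind, ComparisonRecord, EngineAction, ParticipantState


class RenderError(ValueError):
    """A template placeholder had no value at render time."""


class ConfigurationError(ValueError):
    """The message library is unusable (e.g., empty skill library)."""


@dataclass(frozen=True)
class MessageTemplate:
    """One library record: stable id, the action kind it serves, and the
    template text with named placeholders."""

    id: str
    kind: ActionKind
    text: str

    def placeholders(self) -> set[str]:
        return {
            field
            for _, field, _, _ in string.Formatter().parse(self.text)
            if field is not None
        }


DEFAULT_TEMPLATES: tuple[MessageTemplate, ...] = (
    MessageTemplate(
        "welcome",
        ActionKind.SEND_WELCOME,
        "Welcome to MoST-MH. Over the next 3 months we'll be checking in by "
        "text message. Set up a password on your phone and erase messages you "
        "do not want anyone to see after reading them.",
    ),
    MessageTemplate(
        "welcome_quit_info",
        ActionKind.SEND_WELCOME,
        "You can drop out of the MoST-MH program at any time by texting Quit.",
    ),
    MessageTemplate(
        "text_checkin",
        ActionKind.SEND_TEXT_CHECKIN,
        "How would you rate your emotional health this past week? "
        "(excellent / very good / good / fair / poor)",
    ),
    MessageTemplate(
        "positive_feedback",
        ActionKind.SEND_POSITIVE_FEEDBACK_WITH_VIDEO,
        "Great to hear! Keep doing what works for you. When you have 2 "
        "minutes, check out our mental health video library: {video_url}",
    ),
    MessageTemplate(
        "positive_feedback_comparison",
        ActionKind.SEND_POSITIVE_FEEDBACK_WITH_VIDEO,
        "Great to hear you feel on top of things. Improved since last time: "
        "{resolved_list}. Still on your plate: {persisting_list}. Videos that "
        "may help: {video_url}",
    ),
    MessageTemplate(
        "web_link",
        ActionKind.SEND_WEB_LINK,
        "Sorry to hear this week has been hard. Please take a minute to "
        "complete a short check-in so we can tailor support: {web_checkin_url}",
    ),
    MessageTemplate(
        "skill_comparison",
        ActionKind.SEND_SKILL_MESSAGE,
        "Since last time, improved: {resolved_list}; still unresolved: "
        "{persisting_list}. {skill_text} Videos: {video_url}",
    ),
    MessageTemplate(
        "skill_plain",
        ActionKind.SEND_SKILL_MESSAGE,
        "{skill_text} Videos that may help: {video_url}",
    ),
    MessageTemplate(
        "weekly_consent_ask",
        ActionKind.SEND_WEEKLY_CONSENT_ASK,
        "Is it ok if we check in with you again next week?",
    ),
    MessageTemplate(
        "care_prompt",
        ActionKind.SEND_CARE_PROMPT,
        "Your doctor or another health professional can help. Would you be "
        "willing to reach out to them to set up an appointment?",
    ),
    MessageTemplate(
        "safety_care_prompt",
        ActionKind.SEND_SAFETY_CARE_PROMPT,
        "You've had a rough couple of weeks. We strongly encourage you to "
        "reach out for formal mental health care. Your doctor or another "
        "health professional can help.",
    ),
    MessageTemplate(
        "reprompt_text_checkin",
        ActionKind.REPROMPT,
        "Just checking back: how would you rate your emotional health this "
        "past week? (excellent / very good / good / fair / poor)",
    ),
    MessageTemplate(
        "reprompt_web_link",
        ActionKind.REPROMPT,
        "When you get a chance, please complete your check-in: "
        "{web_checkin_url}",
    ),
    MessageTemplate("none", ActionKind.NONE, ""),
)

# Illustrative coping-skill texts; real deployments supply their own.
DEFAULT_SKILL_LIBRARY: tuple[MessageTemplate, ...] = (
    MessageTemplate(
        "skill_three_good_things",
        ActionKind.SEND_SKILL_MESSAGE,
        "Tonight, write down three things that went well today and why — "
        "small wins count.",
    ),
    MessageTemplate(
        "skill_thought_reframe",
        ActionKind.SEND_SKILL_MESSAGE,
        "Notice one stressful thought, ask what evidence supports it, and "
        "try writing a more balanced version.",
    ),
    MessageTemplate(
        "skill_opposite_action",
        ActionKind.SEND_SKILL_MESSAGE,
        "When an urge pulls you toward withdrawing, try one small opposite "
        "action — a short walk or a text to a friend.",
    ),
)


def _humanize(items: frozenset[str]) -> str:
    if not items:
        return "nothing"
    return ", ".join(sorted(items)).replace("_", " ")


def _as_comparison(value) -> ComparisonRecord:
    """Accept a ComparisonRecord or its JSON event-log dict form."""
    if isinstance(value, ComparisonRecord):
        return value
    from .types import SetComparison

    def sub(d: dict) -> SetComparison:
        return SetComparison(
            resolved=frozenset(d.get("resolved", ())),
            persisting=frozenset(d.get("persisting", ())),
            new=frozenset(d.get("new", ())),
        )

    return ComparisonRecord(
        stressors=sub(value.get("stressors", {})),
        negative_effects=sub(value.get("negative_effects", {})),
    )


def comparison_context(comparison: ComparisonRecord | dict) -> dict[str, str]:
    """Flatten a comparison record into renderable placeholder values,
    pooling stressors and negative effects per feedback sentence."""
    comparison = _as_comparison(comparison)
    resolved = comparison.stressors.resolved | comparison.negative_effects.resolved
    persisting = comparison.stressors.persisting | comparison.negative_effects.persisting
    new = comparison.stressors.new | comparison.negative_effects.new
    return {
        "resolved_list": _humanize(resolved),
        "persisting_list": _humanize(persisting | new),
        "new_list": _humanize(new),
    }


class MessageLibrary:
    """Template lookup plus skill-message rotation."""

    def __init__(self, config: Config | None = None) -> None:
        cfg = config or Config()
        templates = {t.id: t for t in DEFAULT_TEMPLATES}
        skills = list(DEFAULT_SKILL_LIBRARY)
        overrides = {}
        for spec in cfg.messages:
            overrides[spec.id] = MessageTemplate(spec.id, ActionKind(spec.kind), spec.text)
        for tid, tmpl in overrides.items():
            if tmpl.kind is ActionKind.SEND_SKILL_MESSAGE and tid not in templates:
                continue  # skill texts are picked up via skill_library below
            templates[tid] = tmpl
        if cfg.skill_library is not None:
            skills = []
            for tid in cfg.skill_library:
                if tid in overrides:
                    skills.append(overrides[tid])
                else:
                    match = next((s for s in DEFAULT_SKILL_LIBRARY if s.id == tid), None)
                    if match is None:
                        raise ConfigurationError(f"unknown skill template id {tid!r}")
                    skills.append(match)
        self.templates = templates
        self.skills: list[MessageTemplate] = skills
        self._video_url = cfg.engine.video_url
        self._web_url = cfg.engine.web_checkin_url

    # ------------------------------------------------------------------
    def next_skill_message(self, state: ParticipantState) -> MessageTemplate:
        """Round-robin over the skill library, deterministic in the number
        of skill messages already sent to this participant; the cycle
        restarts once the library is exhausted."""
        if not self.skills:
            raise ConfigurationError("skill library is empty")
        return self.skills[state.skill_cursor % len(self.skills)]

    def skill_at(self, index: int) -> MessageTemplate:
        if not self.skills:
            raise ConfigurationError("skill library is empty")
        return self.skills[index % len(self.skills)]

    # ------------------------------------------------------------------
    def render(
        self, action: EngineAction, context: Optional[ComparisonRecord] = None
    ) -> str:
        """Render one engine action to outbound text.

        ``context`` (the comparison record) may also travel inside
        ``action.payload["comparison"]``; an explicit argument wins.  A
        placeholder with no value raises :class:`RenderError` naming it.
        """
        payload = dict(action.payload)
        comparison = context if context is not None else payload.get("comparison")

        if action.kind is ActionKind.SEND_SKILL_MESSAGE:
            skill = self.skill_at(payload.get("skill_index", 0))
            template = self.templates[
                "skill_comparison" if comparison is not None else "skill_plain"
            ]
            payload["skill_text"] = skill.text
        elif action.kind is ActionKind.REPROMPT:
            template = self.templates["reprompt_" + payload.get("of", "text_checkin")]
        else:
            tid = payload.get("template")
            template = self.templates.get(tid) if tid else None
            if template is None:
                template = next(
                    (t for t in self.templates.values() if t.kind is action.kind), None
                )
            if template is None:
                raise RenderError(f"no template for action kind {action.kind.value}")

        values = {
            "video_url": payload.get("video_url", self._video_url),
            "web_checkin_url": payload.get("web_checkin_url", self._web_url),
        }
        values.update({k: v for k, v in payload.items() if isinstance(v, str)})
        if comparison is not None:
            values.update(comparison_context(comparison))
        needed = template.placeholders()
        missing = needed - values.keys()
        if missing:
            raise RenderError(
                f"template {template.id!r} is missing value(s) for: {sorted(missing)}"
            )
        return template.text.format(**{k: values[k] for k in needed})


def render(
    action: EngineAction,
    context: Optional[ComparisonRecord] = None,
    *,
    library: MessageLibrary | None = None,
) -> str:
    """Module-level convenience wrapper over :meth:`MessageLibrary.render`."""
    return (library or MessageLibrary()).render(action, context)


def next_skill_message(
    state: ParticipantState, library: list[MessageTemplate] | MessageLibrary
) -> MessageTemplate:
    """Next skill message for a participant under round-robin rotation."""
    if isinstance(library, MessageLibrary):
        return library.next_skill_message(state)
    if not library:
        raise ConfigurationError("skill library is empty")
    return library[state.skill_cursor % len(library)]
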