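"""JSONL event logs: the unit of replay, simulation output, and analytics.

One record per line: ``{"participant_id", "day", "event_kind", "payload"}``.
Event kinds are the engine's action kinds plus the inbound / bookkeeping
kinds ``enrolled``, ``text_reply``, ``web_checkin``, and ``send_video_link``
(the only content event the video-library-only control arm receives).
Reader and writer round-trip losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .types import ComparisonRecord, EngineAction


@dataclass
class Event:
    participant_id: str
    day: int
    event_kind: str
    payload: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "participant_id": self.participant_id,
                "day": self.day,
                "event_kind": self.event_kind,
                "payload": self.payload,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "Event":
        d = json.loads(line)
        return cls(d["participant_id"], d["day"], d["event_kind"], d.get("payload", {}))


@dataclass
class EventLog:
    """Ordered event stream for one participant."""

    participant_id: str
    events: list[Event] = field(default_factory=list)

    def append(self, day: int, event_kind: str, payload: dict | None = None) -> None:
        self.events.append(Event(self.participant_id, day, event_kind, payload or {}))

    def count(self, event_kind: str) -> int:
        return sum(1 for e in self.events if e.event_kind == event_kind)

    def of_kind(self, event_kind: str) -> list[Event]:
        return [e for e in self.events if e.event_kind == event_kind]


def _jsonable(value):
    if isinstance(value, ComparisonRecord):
        return {
            "stressors": {
                "resolved": sorted(value.stressors.resolved),
                "persisting": sorted(value.stressors.persisting),
                "new": sorted(value.stressors.new),
            },
            "negative_effects": {
                "resolved": sorted(value.negative_effects.resolved),
                "persisting": sorted(value.negative_effects.persisting),
                "new": sorted(value.negative_effects.new),
            },
        }
    if isinstance(value, (frozenset, set)):
        return sorted(value)
    return value


def action_payload(action: EngineAction) -> dict:
    """Engine action payload coerced to JSON-safe values."""
    return {k: _jsonable(v) for k, v in action.payload.items()}


def write_jsonl(path: str | Path, logs: Iterable[EventLog]) -> None:
    with open(path, "w") as fh:
        for log in logs:
            for event in log.events:
                fh.write(event.to_json() + "\n")


def iter_events(path: str | Path) -> Iterator[Event]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield Event.from_json(line)


def read_jsonl(path: str | Path) -> list[EventLog]:
    """Read a JSONL stream back into per-participant logs, preserving the
    within-participant event order and first-appearance participant order."""
    logs: dict[str, EventLog] = {}
    for event in iter_events(path):
        logs.setdefault(event.participant_id, EventLog(event.participant_id)).events.append(
            event
        )
    return list(logs.values())
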