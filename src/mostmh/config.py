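"""Declarative configuration for the check-in engine and simulator.

A single YAML file can override any field; everything has a documented
default so the package runs out of the box.  Schema (all keys optional):

.. code-block:: yaml

    engine:
      monthly_interval_days: 30   # step-down cadence after no-need outcomes
      weekly_interval_days: 7     # step-up cadence after low self-efficacy
      reprompt_after_days: 1      # one reprompt, 24 h after the prompt
      missing_after_days: 3       # unanswered 48 h after the reprompt -> missed
      missing_reschedule_days: 7  # missed check-in -> try again in a week
      escalation_window_days: 14  # "2 weeks in a row" consecutiveness window
      escalation_rating: suboptimal   # or "poor" (strict variant)
      horizon_days: 90            # program length (3 months)
      video_url: "https://videos.example/library"
      web_checkin_url: "https://checkin.example/web"
    messages:                     # template overrides / additions
      - {id: skill_xyz, kind: send_skill_message, text: "..."}
    skill_library: [skill_breathing, skill_reframe, skill_opposite_action]

The message-library records use the same ``{placeholder}`` grammar as the
defaults in :mod:`mostmh.messaging`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field


class EngineConfig(BaseModel):
    """Cadence, reprompt, escalation, and horizon parameters (whole days)."""

    monthly_interval_days: int = Field(30, ge=1)
    weekly_interval_days: int = Field(7, ge=1)
    reprompt_after_days: int = Field(1, ge=1)
    missing_after_days: int = Field(3, ge=2)
    missing_reschedule_days: int = Field(7, ge=1)
    escalation_window_days: int = Field(14, ge=1)
    escalation_rating: Literal["suboptimal", "poor"] = "suboptimal"
    horizon_days: int = Field(90, ge=1)
    video_url: str = "https://videos.example/library"
    web_checkin_url: str = "https://checkin.example/web"


class MessageSpec(BaseModel):
    """One message-library record: template id, action kind, template text."""

    id: str
    kind: str
    text: str


class Config(BaseModel):
    """Top-level configuration: engine parameters plus message overrides."""

    engine: EngineConfig = Field(default_factory=EngineConfig)
    messages: list[MessageSpec] = Field(default_factory=list)
    skill_library: Optional[list[str]] = None


DEFAULT_CONFIG = Config()


def load_config(path: str | Path | None) -> Config:
    """Load a YAML config file; ``None`` returns the defaults."""
    if path is None:
        return Config()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return Config.model_validate(raw)
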