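"""Descriptive engagement, endorsement, retention, and care-use summaries.

Everything here is deliberately descriptive — counts, integer-rounded
percentages (half-up, the style trial reports print), medians and ranges,
and per-cell mean/SD tables.  Inferential modelling of outcomes is out of
scope.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .engine import parse_reply
from .eventlog import EventLog
from .types import EmotionalRating, NEGATIVE_EFFECTS, STRESSORS

CARE_TYPES = ("any", "inpatient", "outpatient", "primary_care")


def pct(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half-up (87 for 45/52)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def _median_range(values: Sequence[int]) -> tuple[Optional[float], Optional[tuple[int, int]]]:
    if not values:
        return None, None
    return statistics.median(values), (min(values), max(values))


@dataclass
class EngagementSummary:
    """Prompt/completion counts per channel, cohort-level medians/ranges,
    and integer completion percentages.  Reprompts belong to the same
    check-in and are never counted as additional prompts."""

    n_participants: int = 0
    text_prompts: int = 0
    text_completions: int = 0
    web_prompts: int = 0
    web_completions: int = 0
    text_prompt_counts: list[int] = field(default_factory=list)
    web_prompt_counts: list[int] = field(default_factory=list)

    @property
    def text_completion_pct(self) -> Optional[int]:
        return pct(self.text_completions, self.text_prompts) if self.text_prompts else None

    @property
    def web_completion_pct(self) -> Optional[int]:
        return pct(self.web_completions, self.web_prompts) if self.web_prompts else None

    @property
    def text_median_range(self):
        return _median_range(self.text_prompt_counts)

    @property
    def web_median_range(self):
        """Median/range over participants who were prompted at least once."""
        return _median_range([c for c in self.web_prompt_counts if c > 0])


def _is_rating_reply(payload: dict) -> bool:
    parsed = parse_reply(payload.get("reply", ""))
    return isinstance(parsed, EmotionalRating)


def engagement_summary(logs: Sequence[EventLog]) -> EngagementSummary:
    """Tally prompts and completions over per-participant event logs.

    A text check-in counts as completed when a parseable rating reply is
    present; a web check-in when a completed submission is present.
    Participants with no check-in prompts (e.g. the control arm) do not
    enter the median/range statistics.
    """
    out = EngagementSummary()
    for log in logs:
        tp = log.count("send_text_checkin")
        tc = sum(1 for e in log.of_kind("text_reply") if _is_rating_reply(e.payload))
        wp = log.count("send_web_link")
        wc = sum(1 for e in log.of_kind("web_checkin") if e.payload.get("completed"))
        out.n_participants += 1
        out.text_prompts += tp
        out.text_completions += tc
        out.web_prompts += wp
        out.web_completions += wc
        if tp > 0:
            out.text_prompt_counts.append(tp)
        out.web_prompt_counts.append(wp)
    return out


@dataclass
class FrequencyTable:
    """Per-item endorsement counts and percentages of completed web
    check-ins, plus per-check-in endorsement-count order statistics."""

    denominator: int
    stressors: dict[str, tuple[int, int]] = field(default_factory=dict)
    negative_effects: dict[str, tuple[int, int]] = field(default_factory=dict)
    stressor_count_median: Optional[float] = None
    stressor_count_range: Optional[tuple[int, int]] = None
    effect_count_median: Optional[float] = None
    effect_count_range: Optional[tuple[int, int]] = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": "stressor", "item": k, "count": c, "percent": p}
            for k, (c, p) in self.stressors.items()
        ] + [
            {"category": "negative_effect", "item": k, "count": c, "percent": p}
            for k, (c, p) in self.negative_effects.items()
        ]
        return pd.DataFrame(rows, columns=["category", "item", "count", "percent"])


def endorsement_frequencies(logs: Sequence[EventLog]) -> FrequencyTable:
    """Item endorsement frequency among completed web check-ins."""
    completed = [
        e.payload
        for log in logs
        for e in log.of_kind("web_checkin")
        if e.payload.get("completed")
    ]
    n = len(completed)
    table = FrequencyTable(denominator=n)
    if n == 0:
        return table
    s_counts = {item: 0 for item in STRESSORS}
    e_counts = {item: 0 for item in NEGATIVE_EFFECTS}
    per_checkin_s, per_checkin_e = [], []
    for payload in completed:
        ss = payload.get("stressors", [])
        ee = payload.get("negative_effects", [])
        per_checkin_s.append(len(ss))
        per_checkin_e.append(len(ee))
        for item in ss:
            s_counts[item] += 1
        for item in ee:
            e_counts[item] += 1
    table.stressors = {k: (c, pct(c, n)) for k, c in s_counts.items()}
    table.negative_effects = {k: (c, pct(c, n)) for k, c in e_counts.items()}
    table.stressor_count_median, table.stressor_count_range = _median_range(per_checkin_s)
    table.effect_count_median, table.effect_count_range = _median_range(per_checkin_e)
    return table


def self_efficacy_split(logs: Sequence[EventLog]) -> Optional[tuple[int, int]]:
    """(high%, low%) of self-efficacy reports over completed web check-ins."""
    levels = [
        e.payload.get("self_efficacy")
        for log in logs
        for e in log.of_kind("web_checkin")
        if e.payload.get("completed")
    ]
    if not levels:
        return None
    high = sum(1 for s in levels if s == "completely")
    return pct(high, len(levels)), pct(len(levels) - high, len(levels))


def retention_rate(enrolled: int, completed_at_wave: int) -> int:
    """Integer percentage of enrollees completing an assessment wave."""
    if enrolled <= 0:
        raise ValueError("enrolled must be > 0")
    if not 0 <= completed_at_wave <= enrolled:
        raise ValueError("completed_at_wave must lie in [0, enrolled]")
    return pct(completed_at_wave, enrolled)


def care_use_table(records: pd.DataFrame, care_types: Sequence[str] = CARE_TYPES) -> pd.DataFrame:
    """Count and percentage of participants receiving each care type, by
    arm and assessment wave.

    ``records`` has one row per participant-wave with columns ``arm``,
    ``wave``, and one boolean column per care type; denominators are the
    wave-specific per-arm sample sizes (rows present at that wave).
    """
    unknown = set(care_types) - set(CARE_TYPES)
    if unknown:
        raise ValueError(f"unknown care type(s): {sorted(unknown)}")
    missing_cols = {"arm", "wave", *care_types} - set(records.columns)
    if missing_cols:
        raise ValueError(f"records missing column(s): {sorted(missing_cols)}")
    rows = []
    if records.empty:
        return pd.DataFrame(rows, columns=["arm", "wave", "care_type", "n", "count", "percent"])
    for (arm, wave), group in records.groupby(["arm", "wave"], sort=True):
        n = len(group)
        for care in care_types:
            count = int(group[care].astype(bool).sum())
            rows.append(
                {
                    "arm": arm,
                    "wave": wave,
                    "care_type": care,
                    "n": n,
                    "count": count,
                    "percent": pct(count, n),
                }
            )
    return pd.DataFrame(rows, columns=["arm", "wave", "care_type", "n", "count", "percent"])


def longitudinal_means(scores: pd.DataFrame) -> pd.DataFrame:
    """Per arm x wave (x optional subscale) mean and sample SD of scores.

    ``scores`` has columns ``arm``, ``wave``, ``score`` and optionally
    ``subscale``.  SD uses the n-1 denominator and is missing (NaN) for
    single-observation cells; empty cells simply do not appear.
    """
    required = {"arm", "wave", "score"} - set(scores.columns)
    if required:
        raise ValueError(f"scores missing column(s): {sorted(required)}")
    keys = ["arm", "wave"] + (["subscale"] if "subscale" in scores.columns else [])
    grouped = scores.groupby(keys, sort=True)["score"]
    out = grouped.agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1)).reset_index()
    return out
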