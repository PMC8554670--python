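"""Item-level scoring for the trial's three self-report instruments.

* CCAPS — 62-item college mental-health symptom inventory, items rated
  0-4, eight subscales (depression 13 items, generalized anxiety 9, social
  anxiety 7, academic distress 5, eating concerns 9, family distress 6,
  hostility 7, substance use 6); higher = more severe.
* MHSES — 6-item mental-health self-efficacy scale, items rated 1-10;
  higher = more confident.
* PSSUQ — 19-item post-study usability questionnaire, items rated 1-7;
  lower = more usable; subscales follow the published instrument (system
  usefulness items 1-8, information quality 9-15, interface quality 16-18,
  overall 1-19).

Scoring is the unweighted mean of answered items.  The CCAPS map here is
structural (subscale sizes and index blocks) — item text, reverse scoring,
and normative cut-points are out of scope.  A scale or subscale is scored
only when at least two-thirds of its items are answered; otherwise the
score is None.

Item responses travel as ordered vectors of integers with ``None`` for a
skipped item; :func:`read_responses_csv` / :func:`write_responses_csv`
round-trip wide one-row-per-occasion CSV files.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

MIN_ANSWERED_FRACTION = 2 / 3


class Instrument(str, enum.Enum):
    CCAPS = "CCAPS"
    MHSES = "MHSES"
    PSSUQ = "PSSUQ"


#: item count and inclusive rating range per instrument
INSTRUMENT_SPECS: dict[Instrument, tuple[int, int, int]] = {
    Instrument.CCAPS: (62, 0, 4),
    Instrument.MHSES: (6, 1, 10),
    Instrument.PSSUQ: (19, 1, 7),
}

# Contiguous 0-based index blocks; sizes follow the published instrument.
_CCAPS_SIZES = {
    "depression": 13,
    "generalized_anxiety": 9,
    "social_anxiety": 7,
    "academic_distress": 5,
    "eating_concerns": 9,
    "family_distress": 6,
    "hostility": 7,
    "substance_use": 6,
}


def _blocks(sizes: dict[str, int]) -> dict[str, tuple[int, ...]]:
    out, start = {}, 0
    for name, size in sizes.items():
        out[name] = tuple(range(start, start + size))
        start += size
    return out


CCAPS_SUBSCALES: dict[str, tuple[int, ...]] = _blocks(_CCAPS_SIZES)

PSSUQ_SUBSCALES: dict[str, tuple[int, ...]] = {
    "system_usefulness": tuple(range(0, 8)),
    "information_quality": tuple(range(8, 15)),
    "interface_quality": tuple(range(15, 18)),
    "overall": tuple(range(0, 19)),
}


@dataclass
class InstrumentResponse:
    """One respondent-occasion item vector; ``None`` marks a skipped item."""

    instrument: Instrument
    items: Sequence[Optional[int]]

    def __post_init__(self) -> None:
        n, lo, hi = INSTRUMENT_SPECS[self.instrument]
        self.items = list(self.items)
        if len(self.items) != n:
            raise ValueError(
                f"{self.instrument.value} expects {n} items, got {len(self.items)}"
            )
        for i, v in enumerate(self.items):
            if v is None:
                continue
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValueError(f"item {i}: rating must be an integer, got {v!r}")
            if not lo <= v <= hi:
                raise ValueError(
                    f"item {i}: rating {v} outside [{lo}, {hi}] for "
                    f"{self.instrument.value}"
                )


def _subscale_mean(items: Sequence[Optional[int]], idx: Sequence[int]) -> Optional[float]:
    answered = [items[i] for i in idx if items[i] is not None]
    if len(answered) < MIN_ANSWERED_FRACTION * len(idx):
        return None
    return sum(answered) / len(answered)


def score_ccaps(response: InstrumentResponse) -> dict[str, Optional[float]]:
    """Eight subscale means on the 0-4 severity scale."""
    if response.instrument is not Instrument.CCAPS:
        raise ValueError("score_ccaps requires a CCAPS response")
    return {
        name: _subscale_mean(response.items, idx)
        for name, idx in CCAPS_SUBSCALES.items()
    }


def score_mhses(response: InstrumentResponse) -> Optional[float]:
    """Overall self-efficacy mean on the 1-10 confidence scale."""
    if response.instrument is not Instrument.MHSES:
        raise ValueError("score_mhses requires a MHSES response")
    return _subscale_mean(response.items, range(len(response.items)))


def score_pssuq(response: InstrumentResponse) -> dict[str, Optional[float]]:
    """Overall plus three usability-factor means on the 1-7 scale
    (lower = more usable)."""
    if response.instrument is not Instrument.PSSUQ:
        raise ValueError("score_pssuq requires a PSSUQ response")
    return {
        name: _subscale_mean(response.items, idx)
        for name, idx in PSSUQ_SUBSCALES.items()
    }


def score(response: InstrumentResponse):
    """Dispatch to the instrument-specific scorer."""
    return {
        Instrument.CCAPS: score_ccaps,
        Instrument.MHSES: score_mhses,
        Instrument.PSSUQ: score_pssuq,
    }[response.instrument](response)


# ----------------------------------------------------------------------
# CSV round-trip: one row per respondent-occasion, wide item columns
# ----------------------------------------------------------------------
def write_responses_csv(
    path: str | Path, responses: list[tuple[str, InstrumentResponse]]
) -> None:
    """Write ``(respondent_id, response)`` pairs of one instrument as a wide
    CSV with columns ``respondent_id, item_1 .. item_n``."""
    if not responses:
        raise ValueError("nothing to write")
    instrument = responses[0][1].instrument
    n = INSTRUMENT_SPECS[instrument][0]
    rows = []
    for rid, resp in responses:
        if resp.instrument is not instrument:
            raise ValueError("mixed instruments in one file")
        rows.append({"respondent_id": rid, **{f"item_{i+1}": v for i, v in enumerate(resp.items)}})
    df = pd.DataFrame(rows, columns=["respondent_id"] + [f"item_{i+1}" for i in range(n)])
    df.to_csv(path, index=False)


def read_responses_csv(
    path: str | Path, instrument: Instrument
) -> list[tuple[str, InstrumentResponse]]:
    """Read a wide CSV written by :func:`write_responses_csv`."""
    n = INSTRUMENT_SPECS[instrument][0]
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        items = [
            None if pd.isna(row[f"item_{i+1}"]) else int(row[f"item_{i+1}"])
            for i in range(n)
        ]
        out.append((str(row["respondent_id"]), InstrumentResponse(instrument, items)))
    return out
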