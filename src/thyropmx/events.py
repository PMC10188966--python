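"""Dose events and regimen helpers."""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence


class Drug(str, Enum):
    CMZ = "CMZ"
    LT4 = "LT4"


@dataclass(frozen=True)
class DoseEvent:
    """One drug administration.

    ``amount`` is in mg for CMZ and mcg for LT4; ``time`` is in days since
    treatment start (t0 = 0).
    """

    drug: Drug
    amount: float
    time: float

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"dose amount must be nonnegative, got {self.amount}")
        if self.time < 0:
            raise ValueError(f"dose time must be nonnegative, got {self.time}")
        if not isinstance(self.drug, Drug):
            object.__setattr__(self, "drug", Drug(self.drug))


def tid_doses(total_daily_mg: float, day: float,
              offsets: Sequence[float] = (0.0, 1.0 / 3.0, 2.0 / 3.0)) -> list[DoseEvent]:
    """Split a total daily CMZ dose into equal parts at the given intra-day offsets.

    The default is three equal doses at 8-hour intervals starting at the top of
    the dosing day.
    """
    part = total_daily_mg / len(offsets)
    return [DoseEvent(Drug.CMZ, part, day + off) for off in offsets]


def split_by_drug(regimen: Iterable[DoseEvent]) -> tuple[list[DoseEvent], list[DoseEvent]]:
    """Separate a regimen into (CMZ events, LT4 events), each sorted by time."""
    cmz = sorted((e for e in regimen if e.drug is Drug.CMZ), key=lambda e: e.time)
    lt4 = sorted((e for e in regimen if e.drug is Drug.LT4), key=lambda e: e.time)
    return cmz, lt4


def aggregate_daily(events: Iterable[DoseEvent]) -> list[DoseEvent]:
    """Aggregate CMZ dose events into one total dose per dosing day.

    Used by the simplified one-compartment PK model, which takes a single
    total dose per day placed at the start of the dosing day.
    """
    totals: dict[float, float] = {}
    for e in events:
        if e.drug is not Drug.CMZ:
            raise ValueError("daily aggregation is defined for CMZ events only")
        day = float(math.floor(e.time))
        totals[day] = totals.get(day, 0.0) + e.amount
    return [DoseEvent(Drug.CMZ, amt, day) for day, amt in sorted(totals.items())]
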