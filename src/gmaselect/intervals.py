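"""Half-open time intervals, the unit of sequence selection and annotation."""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class TimeInterval:
    """A half-open span ``[start_s, end_s)`` in seconds from video start.

    Both automatic selections and expert annotations are expressed as
    ``TimeInterval``; half-open semantics make back-to-back one-minute
    sequences non-overlapping by construction.
    """

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.start_s) and math.isfinite(self.end_s)):
            raise ValueError("interval bounds must be finite")
        if self.start_s < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start_s}")
        if self.end_s <= self.start_s:
            raise ValueError(
                f"interval end must exceed start, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s
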