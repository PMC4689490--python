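"""Age-band partitions for stratified surveillance tables.

Strata are half-open age intervals ``[lower, upper)`` in years; the terminal
band may be open-ended (``upper=None``), in which case downstream numerics
truncate it at an explicit age cap. The default partition is the six bands
conventionally used in African epilepsy surveys: 0-5, 6-12, 13-18, 19-28,
29-49 and 50+.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True, order=True)
class AgeBand:
    """Half-open age interval ``[lower, upper)``; ``upper=None`` is open-ended."""

    lower: float
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValueError(f"band lower age must be >= 0, got {self.lower}")
        if self.upper is not None and not self.lower < self.upper:
            raise ValueError(f"band must satisfy lower < upper, got [{self.lower}, {self.upper})")

    @property
    def open_ended(self) -> bool:
        return self.upper is None

    def closed_upper(self, age_cap: float) -> float:
        """Upper bound with the open-ended band truncated at ``age_cap``."""
        return age_cap if self.upper is None else self.upper

    def midpoint(self, age_cap: float = 100.0) -> float:
        return 0.5 * (self.lower + self.closed_upper(age_cap))

    def contains(self, age: float) -> bool:
        return age >= self.lower and (self.upper is None or age < self.upper)

    @property
    def label(self) -> str:
        if self.upper is None:
            return f"{self.lower:g}+"
        # inclusive-year label convention for integer bounds: [0, 6) -> "0-5"
        if float(self.upper).is_integer() and float(self.lower).is_integer():
            return f"{self.lower:g}-{self.upper - 1:g}"
        return f"{self.lower:g}-{self.upper:g}"


#: 0-5, 6-12, 13-18, 19-28, 29-49, 50+ (half-open bounds)
DEFAULT_BANDS: tuple[AgeBand, ...] = (
    AgeBand(0, 6),
    AgeBand(6, 13),
    AgeBand(13, 19),
    AgeBand(19, 29),
    AgeBand(29, 50),
    AgeBand(50, None),
)


def validate_partition(bands: Sequence[AgeBand]) -> tuple[AgeBand, ...]:
    """Check bands are contiguous, non-overlapping and ordered; return as tuple."""
    bands = tuple(bands)
    if not bands:
        raise ValueError("at least one age band is required")
    for left, right in zip(bands, bands[1:]):
        if left.upper is None:
            raise ValueError("only the terminal band may be open-ended")
        if not math.isclose(left.upper, right.lower):
            raise ValueError(f"bands {left.label} and {right.label} do not tile contiguously")
    return bands


def band_index(bands: Sequence[AgeBand], age: float) -> int:
    """Index of the band containing ``age`` (ages past a bounded terminal band clamp to it)."""
    for k, band in enumerate(bands):
        if band.contains(age):
            return k
    if age >= bands[-1].lower:
        return len(bands) - 1
    raise ValueError(f"age {age} precedes the first band")


def parse_band(age_lo: float, age_hi: float | None) -> AgeBand:
    """Build an AgeBand from CSV cells where a blank/NaN upper bound means open-ended."""
    hi = None if age_hi is None or (isinstance(age_hi, float) and math.isnan(age_hi)) else float(age_hi)
    return AgeBand(float(age_lo), hi)
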