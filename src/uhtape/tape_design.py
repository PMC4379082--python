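"""Tri-zone tape construction and uterine-height classification.

A tape partitions the measurable uterine-height (UH) range into three
ordered zones by two cut-off lengths taken from a growth chart:

* ``low``  (displayed yellow) — UH below the week-24 anchor percentile,
  read as gestational age (GA) under 24.0 weeks;
* ``mid``  (displayed red) — UH between the anchors, read as GA in the
  24.0–36.0 week window where antenatal corticosteroids are indicated;
* ``high`` (displayed green) — UH above the week-36 anchor percentile,
  read as GA of 36.0 weeks or more.

The three standard variants (10–90, 50–50, 90–10) use the P10/P50/P90
of UH at 24 completed weeks for the lower boundary and at 36 completed
weeks for the upper one; they trade sensitivity against specificity.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Iterable

from .growth_chart import GrowthChart

VALID_PERCENTILES = (10, 50, 90)

#: Tie handling at the zone boundaries.  ``"upper-open"`` treats the mid
#: zone as [lower, upper): a measurement equal to the upper boundary is
#: read as the start of week 36 and therefore falls in the high zone,
#: mirroring the half-open GA bands.  ``"closed"`` keeps both boundaries
#: in the mid (refer/treat) zone.
BOUNDARY_CONVENTIONS = ("upper-open", "closed")

#: Resolution at which boundaries are printed on a physical tape.
TAPE_RESOLUTION_CM = 0.1


class Zone(enum.IntEnum):
    """Ordered tape zone; the value encodes the total order low < mid < high."""

    LOW = 0
    MID = 1
    HIGH = 2

    @property
    def color(self) -> str:
        """Display color on the physical tape (metadata only)."""
        return {Zone.LOW: "yellow", Zone.MID: "red", Zone.HIGH: "green"}[self]

    @property
    def label(self) -> str:
        return self.name.lower()


class DegenerateTapeError(ValueError):
    """Raised when the requested percentile pair yields lower >= upper."""


def _round_cm(x: float) -> float:
    return round(float(x), 1)


@dataclass(frozen=True)
class TapeSpec:
    """Two boundary lengths (cm) defining a tri-zone tape.

    Boundaries are stored at 0.1 cm resolution, the printing granularity
    of the physical tape.
    """

    name: str
    lower_cm: float
    upper_cm: float
    site: str = ""
    lower_percentile: int | None = None
    upper_percentile: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower_cm", _round_cm(self.lower_cm))
        object.__setattr__(self, "upper_cm", _round_cm(self.upper_cm))
        if not self.lower_cm < self.upper_cm:
            raise DegenerateTapeError(
                f"tape {self.name!r}: lower boundary {self.lower_cm} cm must be "
                f"below upper boundary {self.upper_cm} cm"
            )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "site": self.site,
            "lower_cm": self.lower_cm,
            "upper_cm": self.upper_cm,
            "lower_percentile": self.lower_percentile,
            "upper_percentile": self.upper_percentile,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "TapeSpec":
        return cls(**d)


def build_tape(
    chart: GrowthChart,
    lower_percentile: int,
    upper_percentile: int,
) -> TapeSpec:
    """Anchor a tape's boundaries on a growth chart.

    The lower boundary is the requested UH percentile at 24 completed
    weeks, the upper one the requested percentile at 36 completed weeks.
    Raises :class:`DegenerateTapeError` when the combination collapses the
    mid zone (possible for 90–10 on a noisy or flat chart).
    """
    for p in (lower_percentile, upper_percentile):
        if p not in VALID_PERCENTILES:
            raise ValueError(f"percentile must be one of {VALID_PERCENTILES}, got {p}")
    lower = chart.percentile(24, lower_percentile)
    upper = chart.percentile(36, upper_percentile)
    return TapeSpec(
        name=f"{lower_percentile}-{upper_percentile}",
        lower_cm=lower,
        upper_cm=upper,
        site=chart.site,
        lower_percentile=lower_percentile,
        upper_percentile=upper_percentile,
    )


def build_standard_set(chart: GrowthChart) -> tuple[TapeSpec, TapeSpec, TapeSpec]:
    """The three study tape variants: 10–90, 50–50 and 90–10.

    On any chart with non-crossing percentiles their mid zones nest:
    mid(90–10) ⊆ mid(50–50) ⊆ mid(10–90).
    """
    return (
        build_tape(chart, 10, 90),
        build_tape(chart, 50, 50),
        build_tape(chart, 90, 10),
    )


def classify_uh(
    tape: TapeSpec,
    uh_cm: float,
    boundary: str = "upper-open",
) -> Zone:
    """Map one UH measurement to a tape zone.

    The input is rounded to the 0.1 cm tape resolution before the exact
    comparison, so tie handling is well defined.  Total and monotone:
    every positive measurement maps to exactly one zone and a larger
    measurement never maps to a lower zone.
    """
    if boundary not in BOUNDARY_CONVENTIONS:
        raise ValueError(f"boundary must be one of {BOUNDARY_CONVENTIONS}")
    uh = _round_cm(uh_cm)
    if uh <= 0:
        raise ValueError(f"uterine height must be positive, got {uh_cm}")
    if uh < tape.lower_cm:
        return Zone.LOW
    at_upper_is_mid = boundary == "closed"
    if uh < tape.upper_cm or (at_upper_is_mid and uh == tape.upper_cm):
        return Zone.MID
    return Zone.HIGH


def classify_many(
    tape: TapeSpec, uh_cm: Iterable[float], boundary: str = "upper-open"
) -> list[Zone]:
    return [classify_uh(tape, u, boundary) for u in uh_cm]
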