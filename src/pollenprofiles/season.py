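"""Pollen-season delimitation and the APIn-tertile partition.

The main pollination period follows the European Aeroallergen Network
convention: the season starts on the first day on which the cumulative sum
of daily concentrations reaches 1% of the calendar-year total, and ends on
the first day on which it reaches 95%. The Annual Pollen Integral (APIn) is
the sum of daily mean concentrations over the closed season interval, in
pollen·day/m^3. Threshold crossings use >= (the day the quantile is
reached), and whole days only — no within-day interpolation.

The first of the three season partitions splits the season at the days on
which the within-season cumulative pollen sum reaches one third and two
thirds of the APIn; each cut day closes the section it ends.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np

from .errors import DegeneratePartitionError, NoSeasonError, ValidationError
from .io import PollenSeries
from .utils import ONE_DAY, inclusive_days

__all__ = [
    "SeasonDefinition",
    "SectionPartition",
    "define_season",
    "season_duration",
    "apin",
    "apin_tertile_partition",
]


@dataclasses.dataclass(frozen=True)
class SeasonDefinition:
    """One year's season: start/end dates (closed interval), duration in
    days and APIn."""

    year: int
    start_date: dt.date
    end_date: dt.date
    duration_days: int
    apin: float

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValidationError(
                f"season start {self.start_date} after end {self.end_date}"
            )
        expected = inclusive_days(self.start_date, self.end_date)
        if self.duration_days != expected:
            raise ValidationError(
                f"duration {self.duration_days} != closed-interval length {expected}"
            )
        if self.apin < 0:
            raise ValidationError(f"negative APIn {self.apin}")

    def contains(self, day: dt.date) -> bool:
        return self.start_date <= day <= self.end_date

    @property
    def days(self) -> list[dt.date]:
        from .utils import daterange

        return daterange(self.start_date, self.end_date)


@dataclasses.dataclass(frozen=True)
class SectionPartition:
    """A three-way split of a season into consecutive closed date intervals.

    Sections are [start, cut1], [cut1+1d, cut2], [cut2+1d, end]; the cut
    days belong to the section they close. Degenerate splits (fewer than
    three non-empty sections) are rejected.
    """

    method: str  # "apin" | "phenology" | "sli"
    season: SeasonDefinition
    cut1: dt.date
    cut2: dt.date

    def __post_init__(self) -> None:
        s, e = self.season.start_date, self.season.end_date
        if not (s <= self.cut1 < self.cut2 < e):
            raise DegeneratePartitionError(
                f"{self.method} partition degenerate: season [{s}, {e}], "
                f"cuts {self.cut1}, {self.cut2}"
            )

    @property
    def sections(self) -> tuple[tuple[dt.date, dt.date], ...]:
        return (
            (self.season.start_date, self.cut1),
            (self.cut1 + ONE_DAY, self.cut2),
            (self.cut2 + ONE_DAY, self.season.end_date),
        )

    def section_of(self, day: dt.date) -> int:
        """Section label (1-3) of an in-season day."""
        if not self.season.contains(day):
            raise ValueError(f"{day} outside season")
        if day <= self.cut1:
            return 1
        if day <= self.cut2:
            return 2
        return 3


def define_season(pollen: PollenSeries, year: int) -> SeasonDefinition:
    """Delimit the main pollination period of ``year`` by the 1%/95%
    cumulative-sum rule and compute its APIn.

    Raises :class:`NoSeasonError` when the calendar-year total is zero.
    """
    yearly = pollen.year_slice(year)
    total = float(yearly.concentrations.sum())
    if total <= 0:
        raise NoSeasonError(f"no pollen recorded in {year}; season undefined")
    csum = np.cumsum(yearly.concentrations)
    start_i = int(np.argmax(csum >= 0.01 * total))
    end_i = int(np.argmax(csum >= 0.95 * total))
    start, end = yearly.dates[start_i], yearly.dates[end_i]
    season_sum = float(
        yearly.concentrations[start_i : end_i + 1].sum()
    )
    return SeasonDefinition(
        year=year,
        start_date=start,
        end_date=end,
        duration_days=inclusive_days(start, end),
        apin=season_sum,
    )


def season_duration(start: dt.date, end: dt.date) -> int:
    """Season length in days, both endpoints included."""
    if start > end:
        raise ValidationError(f"start {start} after end {end}")
    return inclusive_days(start, end)


def apin(pollen: PollenSeries, season: SeasonDefinition) -> float:
    """Annual Pollen Integral: sum of daily means over the closed season."""
    window = pollen.window(season.start_date, season.end_date)
    return float(window.concentrations.sum())


def apin_tertile_partition(
    pollen: PollenSeries, season: SeasonDefinition
) -> SectionPartition:
    """Split the season where the within-season cumulative pollen sum first
    reaches one third and two thirds of the APIn."""
    window = pollen.window(season.start_date, season.end_date)
    total = float(window.concentrations.sum())
    if total <= 0:
        raise NoSeasonError("zero pollen within season; tertiles undefined")
    csum = np.cumsum(window.concentrations)
    cut1 = window.dates[int(np.argmax(csum >= total / 3))]
    cut2 = window.dates[int(np.argmax(csum >= 2 * total / 3))]
    return SectionPartition(method="apin", season=season, cut1=cut1, cut2=cut2)
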