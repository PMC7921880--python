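"""k-nearest-neighbour imputation of missing in-season daily scores.

The per-user SLI tertile split needs a score for every season day. Gaps
are filled from the user's own observed days using a Gower-style distance
over two numeric variables — day of season and same-day pollen
concentration — each range-normalised over the season:

    d(a, b) = |day_a - day_b| / range(day) + |c_a - c_b| / range(c)

A variable with zero range contributes nothing. The imputed value is the
median of the k nearest observed scores (k = 3 by default; the middle
order statistic for odd k, the mean of the two middle values for even k).
Distance ties break deterministically by earlier calendar day, then lower
score.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Mapping

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .io import PollenSeries
from .scoring import UserSeasonSeries

__all__ = ["ImputedSeries", "knn_impute"]


@dataclasses.dataclass(frozen=True)
class ImputedSeries:
    """A gap-free season of daily scores; imputed days are flagged."""

    user_id: str
    year: int
    daily_scores: Mapping[dt.date, float]  # every season day
    imputed_flags: Mapping[dt.date, bool]

    def __post_init__(self) -> None:
        if set(self.daily_scores) != set(self.imputed_flags):
            raise ValidationError("scores and flags cover different days")

    @property
    def days(self) -> list[dt.date]:
        return sorted(self.daily_scores)


def knn_impute(
    series: UserSeasonSeries, pollen: PollenSeries, k: int = 3
) -> ImputedSeries:
    """Fill every missing season day of one user's series.

    Requires at least k observed days; imputing an already-complete series
    returns it unchanged with all flags false.
    """
    season = series.season
    observed = series.observed_days
    if len(observed) < k:
        raise InsufficientDataError(
            f"user {series.user_id}: {len(observed)} observed days < k={k}"
        )
    season_days = season.days
    day_index = {d: i for i, d in enumerate(season_days)}
    conc = {d: pollen.concentration_on(d) for d in season_days}

    day_range = float(len(season_days) - 1)
    conc_vals = np.array([conc[d] for d in season_days])
    conc_range = float(np.ptp(conc_vals))

    def dist(a: dt.date, b: dt.date) -> float:
        d = 0.0
        if day_range > 0:
            d += abs(day_index[a] - day_index[b]) / day_range
        if conc_range > 0:
            d += abs(conc[a] - conc[b]) / conc_range
        return d

    scores: dict[dt.date, float] = {}
    flags: dict[dt.date, bool] = {}
    for day in season_days:
        if day in series.daily_scores:
            scores[day] = float(series.daily_scores[day])
            flags[day] = False
            continue
        ranked = sorted(
            observed,
            key=lambda o: (dist(day, o), o, series.daily_scores[o]),
        )
        neighbours = [series.daily_scores[o] for o in ranked[:k]]
        scores[day] = float(np.median(neighbours))
        flags[day] = True
    return ImputedSeries(
        user_id=series.user_id, year=series.year,
        daily_scores=scores, imputed_flags=flags,
    )
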