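"""Daily symptom-load scores and the allergy-sufferer filter.

Each diary entry collapses to one daily total — the Symptom Load Index
(SLI) contribution — as a weighted sum of the eye, nose, lung and
medication sub-scores (unit weights by default; the exact clinical score
formula is configurable, not hard-coded). Users qualify as grass-pollen
allergy sufferers when their in-season daily scores show a positive rank
correlation with same-day pollen concentrations at one-sided p below alpha
(default 0.05) and they logged at least ``min_entries`` (default 15)
in-season days. Rank (Spearman) correlation with midranks is the default
because the concentration-symptom relation saturates at a plateau;
Pearson is available through the configuration.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .io import DiaryEntry, PollenSeries, RunConfig
from .season import SeasonDefinition

__all__ = [
    "UserSeasonSeries",
    "CorrelationResult",
    "total_score",
    "build_user_series",
    "correlate_user",
    "filter_users",
]


@dataclasses.dataclass(frozen=True)
class UserSeasonSeries:
    """One user's observed in-season daily totals for one year."""

    user_id: str
    year: int
    season: SeasonDefinition
    daily_scores: Mapping[dt.date, float]  # observed days only

    def __post_init__(self) -> None:
        for day in self.daily_scores:
            if not self.season.contains(day):
                raise ValidationError(
                    f"user {self.user_id}: score on {day} outside season "
                    f"[{self.season.start_date}, {self.season.end_date}]"
                )

    @property
    def n_entries(self) -> int:
        return len(self.daily_scores)

    @property
    def observed_days(self) -> list[dt.date]:
        return sorted(self.daily_scores)


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    """Symptom-pollen association for one user-year; ``coefficient`` is NaN
    when the correlation is undefined (constant input), which fails the
    filter."""

    user_id: str
    year: int
    coefficient: float
    p_value: float
    n: int
    method: str

    @property
    def defined(self) -> bool:
        return not math.isnan(self.coefficient)


def total_score(entry: DiaryEntry, cfg: RunConfig | None = None) -> float:
    """Weighted daily total of the four sub-scores (default weights all 1)."""
    cfg = cfg or RunConfig()
    w = cfg.score_weights
    subs = (entry.eye_score, entry.nose_score, entry.lung_score, entry.medication_score)
    if any(s < 0 for s in subs):
        raise ValidationError(f"user {entry.user_id} on {entry.date}: negative sub-score")
    return float(sum(wi * si for wi, si in zip(w, subs)))


def build_user_series(
    entries: Iterable[DiaryEntry],
    season: SeasonDefinition,
    cfg: RunConfig | None = None,
) -> list[UserSeasonSeries]:
    """Group entries into per-user daily-score series, keeping in-season
    days only; users with no in-season entry are dropped."""
    cfg = cfg or RunConfig()
    per_user: dict[str, dict[dt.date, float]] = {}
    for e in entries:
        if season.contains(e.date):
            per_user.setdefault(e.user_id, {})[e.date] = total_score(e, cfg)
    return [
        UserSeasonSeries(
            user_id=uid, year=season.year, season=season, daily_scores=scores
        )
        for uid, scores in sorted(per_user.items())
    ]


def correlate_user(
    series: UserSeasonSeries,
    pollen: PollenSeries,
    cfg: RunConfig | None = None,
) -> CorrelationResult:
    """Correlate daily scores with same-day (or lagged) pollen
    concentrations, one-sided for positive association.

    Constant scores or constant pollen over the observed days leave the
    coefficient undefined (NaN, p = 1), which downstream treats as a
    filter failure.
    """
    cfg = cfg or RunConfig()
    days = series.observed_days
    if len(days) < 3:
        raise InsufficientDataError(
            f"user {series.user_id}: {len(days)} entries < 3, correlation undefined"
        )
    scores = np.array([series.daily_scores[d] for d in days], dtype=float)
    lag = dt.timedelta(days=cfg.lag_days)
    conc = np.array([pollen.concentration_on(d - lag) for d in days], dtype=float)
    if np.ptp(scores) == 0 or np.ptp(conc) == 0:
        return CorrelationResult(
            user_id=series.user_id, year=series.year,
            coefficient=float("nan"), p_value=1.0,
            n=len(days), method=cfg.correlation_method,
        )
    if cfg.correlation_method == "spearman":
        res = stats.spearmanr(conc, scores, alternative="greater")
    else:
        res = stats.pearsonr(conc, scores, alternative="greater")
    return CorrelationResult(
        user_id=series.user_id,
        year=series.year,
        coefficient=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(days),
        method=cfg.correlation_method,
    )


def filter_users(
    series: Iterable[UserSeasonSeries],
    pollen: PollenSeries,
    cfg: RunConfig | None = None,
) -> list[UserSeasonSeries]:
    """Keep users with >= min_entries in-season days and a positive,
    significant symptom-pollen correlation."""
    cfg = cfg or RunConfig()
    kept = []
    for s in series:
        if s.n_entries < cfg.min_entries:
            continue
        corr = correlate_user(s, pollen, cfg)
        if corr.defined and corr.coefficient > 0 and corr.p_value < cfg.alpha:
            kept.append(s)
    return kept
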