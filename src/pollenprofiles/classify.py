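"""Phenology and per-user SLI partitions, section assignment, and the
confirmatory one-way ANOVA.

Three ways of cutting the season into an early, a main and a late section:

* ``apin``       — cumulative-pollen tertiles (see :mod:`.season`);
* ``phenology``  — calendar cuts at the flowering onset of the main-season
  grasses (Arrhenatherum elatius, Festuca sp., Lolium perenne) and of the
  late-flowering grasses (Phleum pratense, Cynodon dactylon); the early
  section is defined by Poa pratensis and Dactylis glomerata;
* ``sli``        — per-user tertiles of the user's own cumulative symptom
  load (requires a gap-free, i.e. imputed, series).

Each user-year is then assigned to the section of highest symptom
severity: for the calendar-based methods the default severity statistic is
the MEAN daily score per section (sections have unequal lengths, so a sum
would bias toward long sections; sum and peak are available); for the SLI
method it is the mean daily score over the user's own tertile segments,
i.e. the segment where symptom load accumulates fastest. Ties go to the
earliest section.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    ConfigError,
    DegeneratePartitionError,
    InsufficientDataError,
    ValidationError,
)
from .impute import ImputedSeries
from .io import PhenologyPeriod, RunConfig
from .scoring import UserSeasonSeries
from .season import SeasonDefinition, SectionPartition
from .utils import ONE_DAY

__all__ = [
    "SectionAssignment",
    "AnovaResult",
    "phenology_partition",
    "sli_tertile_sections",
    "assign_section",
    "anova_sections",
]


@dataclasses.dataclass(frozen=True)
class SectionAssignment:
    """A user-year's section of peak severity under one partition method,
    with the per-section severity summaries that produced it."""

    user_id: str
    year: int
    method: str
    section: int
    per_section_summary: tuple[float, float, float]

    def __post_init__(self) -> None:
        best = max(self.per_section_summary)
        expected = 1 + min(
            i for i, v in enumerate(self.per_section_summary) if v == best
        )
        if self.section != expected:
            raise ValidationError(
                f"section {self.section} is not the earliest argmax of "
                f"{self.per_section_summary}"
            )


@dataclasses.dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA of daily scores grouped by section.

    ``degenerate`` marks zero variance both between and within groups,
    where F is undefined.
    """

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False


def phenology_partition(
    periods: Iterable[PhenologyPeriod],
    season: SeasonDefinition,
    cfg: RunConfig | None = None,
) -> SectionPartition:
    """Cut the season at the earliest flowering onset of the main-season
    group and of the late group; cuts are clamped to the season interval.

    The flowering onset (start of the flowering period, not of full
    flowering) defines each boundary, since a section starts "with the
    beginning" of its defining grasses.
    """
    cfg = cfg or RunConfig()
    by_taxon = {p.taxon: p for p in periods}

    def earliest_start(group: Sequence[str], name: str) -> dt.date:
        matched = [by_taxon[t] for t in group if t in by_taxon]
        if not matched:
            raise ConfigError(
                f"{name} taxa group {list(group)} matches no phenology record"
            )
        return min(p.flowering_start for p in matched)

    earliest_start(cfg.early_taxa, "early")  # presence check only
    main_start = earliest_start(cfg.main_taxa, "main")
    late_start = earliest_start(cfg.late_taxa, "late")
    if late_start <= main_start:
        raise DegeneratePartitionError(
            f"late group starts {late_start}, not after main group {main_start}"
        )
    cut1 = min(max(main_start - ONE_DAY, season.start_date), season.end_date)
    cut2 = min(max(late_start - ONE_DAY, season.start_date), season.end_date)
    return SectionPartition(method="phenology", season=season, cut1=cut1, cut2=cut2)


def sli_tertile_sections(
    series: ImputedSeries, season: SeasonDefinition
) -> SectionPartition:
    """Split the season at the days where this user's cumulative daily
    score first reaches one third and two thirds of their season total."""
    days = series.days
    scores = np.array([series.daily_scores[d] for d in days], dtype=float)
    total = float(scores.sum())
    if total <= 0:
        raise ValidationError(
            f"user {series.user_id}: all-zero scores, SLI tertiles undefined"
        )
    csum = np.cumsum(scores)
    cut1 = days[int(np.argmax(csum >= total / 3))]
    cut2 = days[int(np.argmax(csum >= 2 * total / 3))]
    return SectionPartition(method="sli", season=season, cut1=cut1, cut2=cut2)


def _section_values(
    series: UserSeasonSeries | ImputedSeries, partition: SectionPartition
) -> list[list[float]]:
    groups: list[list[float]] = [[], [], []]
    for day, score in series.daily_scores.items():
        groups[partition.section_of(day) - 1].append(float(score))
    return groups


def assign_section(
    series: UserSeasonSeries | ImputedSeries,
    partition: SectionPartition,
    statistic: str = "mean",
) -> SectionAssignment:
    """Label one user-year with the section of peak severity under
    ``partition``.

    ``statistic`` summarises the daily scores of each section: "mean"
    (default), "sum" or "peak" (maximum single day). With "mean", an
    empty section is an error directing the caller to impute first; with
    "sum"/"peak" an empty section counts 0. For an "sli" partition the
    series must be the same user's gap-free series the tertiles were
    derived from, so sections are never empty.
    """
    groups = _section_values(series, partition)
    summaries = []
    for i, vals in enumerate(groups, start=1):
        if not vals:
            if statistic == "mean":
                raise InsufficientDataError(
                    f"user {series.user_id}: no observed day in section {i}; "
                    "impute the series before assigning with the mean statistic"
                )
            summaries.append(0.0)
        elif statistic == "mean":
            summaries.append(float(np.mean(vals)))
        elif statistic == "sum":
            summaries.append(float(np.sum(vals)))
        elif statistic == "peak":
            summaries.append(float(np.max(vals)))
        else:
            raise ConfigError(f"unknown severity statistic {statistic!r}")
    best = max(summaries)
    section = 1 + min(i for i, v in enumerate(summaries) if v == best)
    return SectionAssignment(
        user_id=series.user_id,
        year=series.year,
        method=partition.method,
        section=section,
        per_section_summary=tuple(summaries),
    )


def anova_sections(
    series: ImputedSeries, partition: SectionPartition
) -> AnovaResult:
    """One-way ANOVA of a user's daily scores grouped by season section:
    F on (2, n-3) degrees of freedom. Every section needs >= 2 days."""
    groups = _section_values(series, partition)
    for i, g in enumerate(groups, start=1):
        if len(g) < 2:
            raise InsufficientDataError(
                f"section {i} has {len(g)} days < 2; ANOVA undefined"
            )
    n = sum(len(g) for g in groups)
    flat = np.concatenate([np.array(g) for g in groups])
    if np.ptp(flat) == 0:
        return AnovaResult(
            f_statistic=float("nan"), p_value=1.0,
            df_between=2, df_within=n - 3, degenerate=True,
        )
    res = stats.f_oneway(*groups)
    return AnovaResult(
        f_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df_between=2,
        df_within=n - 3,
    )
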