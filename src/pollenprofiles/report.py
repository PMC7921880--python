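"""Cohort-level reporting: section count tables, cross-year profile
stability, and cumulative SLI-vs-APIn profile curves.

Percentages use round-half-up: one decimal for section tables, whole
percent for the stability summary. A "robust" profile is a user assigned
to the same section in every study year; the stability summary also
records whether any all-years user ever carries both section 1 and
section 3 (non-successive sections) among their yearly labels.

A profile curve tracks, day by day through the season, the fraction of
the APIn accumulated (x) against the fraction of the user's total symptom
load accumulated (y); users above the cohort-mean curve at mid-APIn
(x = 0.5) are fast reactors, users below are slow reactors.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .classify import SectionAssignment
from .impute import ImputedSeries
from .io import PollenSeries
from .season import SeasonDefinition
from .utils import round_half_up

__all__ = [
    "SectionTable",
    "StabilitySummary",
    "ProfileCurve",
    "ProfileCurveSet",
    "section_table",
    "stability",
    "profile_curves",
]


@dataclasses.dataclass(frozen=True)
class SectionTable:
    """Counts and percentages of user-years per season section for one
    partition method (pooled years or a single year)."""

    method: str
    scope: str  # "pooled" or the year as text
    counts: tuple[int, int, int]
    percentages: tuple[float, float, float]  # half-up, 1 decimal

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclasses.dataclass(frozen=True)
class StabilitySummary:
    """Cross-year profile stability of users present in every study year."""

    method: str
    n_users_all_years: int
    same_all_years: int
    same_two_of_three: int
    variable_all_years: int
    nonadjacent_pairs_present: bool
    percentages: tuple[int, int, int]  # half-up, whole percent

    def __post_init__(self) -> None:
        total = self.same_all_years + self.same_two_of_three + self.variable_all_years
        if total != self.n_users_all_years:
            raise ValidationError(
                f"stability categories sum to {total} != {self.n_users_all_years}"
            )


@dataclasses.dataclass(frozen=True)
class ProfileCurve:
    """One user-year's cumulative profile: per season day the pair
    (cumulative pollen fraction, cumulative score fraction)."""

    user_id: str
    year: int
    points: np.ndarray  # shape (n_days, 2); both columns non-decreasing
    assigned_section: int | None


@dataclasses.dataclass(frozen=True)
class ProfileCurveSet:
    """All user curves over one season plus their pointwise mean and the
    fast/slow reactor call at mid-APIn."""

    curves: tuple[ProfileCurve, ...]
    mean_curve: np.ndarray  # shape (n_days, 2)
    reactor: dict[str, str]  # user_id -> "fast" | "slow"


def section_table(
    assignments: Iterable[SectionAssignment],
    method: str,
    scope: str = "pooled",
) -> SectionTable:
    """Tabulate how many user-years peak in each section under ``method``.

    ``scope`` is "pooled" for all years together or a year as text.
    """
    selected = [
        a
        for a in assignments
        if a.method == method and (scope == "pooled" or str(a.year) == scope)
    ]
    if not selected:
        raise ValidationError(f"no assignments for method={method}, scope={scope}")
    counts = tuple(sum(1 for a in selected if a.section == s) for s in (1, 2, 3))
    total = sum(counts)
    percentages = tuple(round_half_up(100.0 * c / total, 1) for c in counts)
    return SectionTable(method=method, scope=scope, counts=counts, percentages=percentages)


def classify_label_triple(labels: Sequence[int]) -> str:
    """Category of one user's across-year section labels: 'same_all' (one
    distinct section), 'variable' (a different section every year), else
    'same_two'."""
    distinct = len(set(labels))
    if distinct == 1:
        return "same_all"
    if distinct == len(labels):
        return "variable"
    return "same_two"


def stability(
    assignments: Iterable[SectionAssignment], method: str
) -> StabilitySummary:
    """Classify every user present in all study years by the stability of
    their yearly section labels under ``method``."""
    selected = [a for a in assignments if a.method == method]
    years = sorted({a.year for a in selected})
    by_user: dict[str, dict[int, int]] = {}
    for a in selected:
        by_user.setdefault(a.user_id, {})[a.year] = a.section
    all_years_users = {
        uid: [labels[y] for y in years]
        for uid, labels in by_user.items()
        if set(labels) == set(years)
    }
    if not all_years_users:
        raise ValidationError(f"no user assigned in all years under {method}")
    tally = {"same_all": 0, "same_two": 0, "variable": 0}
    nonadjacent = False
    for labels in all_years_users.values():
        tally[classify_label_triple(labels)] += 1
        if 1 in labels and 3 in labels:
            nonadjacent = True
    n = len(all_years_users)
    pct = tuple(
        int(round_half_up(100.0 * tally[c] / n))
        for c in ("same_all", "same_two", "variable")
    )
    return StabilitySummary(
        method=method,
        n_users_all_years=n,
        same_all_years=tally["same_all"],
        same_two_of_three=tally["same_two"],
        variable_all_years=tally["variable"],
        nonadjacent_pairs_present=nonadjacent,
        percentages=pct,
    )


def profile_curves(
    imputed: Iterable[ImputedSeries],
    pollen: PollenSeries,
    season: SeasonDefinition,
    assignments: Iterable[SectionAssignment] = (),
) -> ProfileCurveSet:
    """Cumulative score-fraction vs pollen-fraction curve per user, the
    cohort pointwise-mean curve, and the fast/slow reactor call.

    Users with zero total score are excluded with a warning. The reactor
    call compares each user's curve with the mean curve at the first day
    on which the cumulative pollen fraction reaches 0.5.
    """
    days = season.days
    conc = np.array([pollen.concentration_on(d) for d in days], dtype=float)
    total_pollen = conc.sum()
    if total_pollen <= 0:
        raise ValidationError("zero pollen over the season; curves undefined")
    x = np.cumsum(conc) / total_pollen
    section_by_user = {(a.user_id, a.year): a.section for a in assignments}

    curves = []
    for series in imputed:
        scores = np.array([series.daily_scores[d] for d in days], dtype=float)
        total = scores.sum()
        if total <= 0:
            warnings.warn(
                f"user {series.user_id}: zero total score, excluded from curves"
            )
            continue
        y = np.cumsum(scores) / total
        curves.append(
            ProfileCurve(
                user_id=series.user_id,
                year=series.year,
                points=np.column_stack([x, y]),
                assigned_section=section_by_user.get((series.user_id, series.year)),
            )
        )
    if not curves:
        raise ValidationError("no user with positive total score")
    mean_curve = np.column_stack(
        [x, np.mean([c.points[:, 1] for c in curves], axis=0)]
    )
    mid = int(np.argmax(x >= 0.5))
    reactor = {
        c.user_id: ("fast" if c.points[mid, 1] >= mean_curve[mid, 1] else "slow")
        for c in curves
    }
    return ProfileCurveSet(curves=tuple(curves), mean_curve=mean_curve, reactor=reactor)
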