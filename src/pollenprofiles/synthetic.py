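"""Synthetic pollen seasons and diary cohorts with known ground truth.

The generator emulates the structure of a Central-European grass pollen
season and of a crowd-sourced symptom diary, so that every downstream
stage (season delimitation, user filtering, imputation, classification,
stability reporting) can be exercised against a known answer:

* the aggregate airborne Poaceae curve is a sum of per-taxon Gaussian
  bumps, staggered into early (Poa pratensis, Dactylis glomerata), main
  (Arrhenatherum elatius, Festuca sp., Lolium perenne) and late (Phleum
  pratense, Cynodon dactylon) flowering, with an optional late rebloom
  bump and optional multiplicative lognormal day-to-day noise;
* each simulated user carries a hidden ``true_section`` (1-3). Their
  daily symptom response follows the field's described dose-response:
  linear in the same-day concentration up to a hard saturation plateau,
  with the dose-response slope (sensitivity) strictly highest inside the
  true section; Gaussian reporting noise is added and the result is
  discretised onto the diary's integer score range;
* diary adherence is Bernoulli per day: each in-season day is recorded
  with probability ``adherence``, emulating users who do not enter data
  every day.

Everything is reproducible from the seed; changing only the seed changes
noise and missingness, never the underlying mean curves.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io import DiaryEntry, PhenologyPeriod, PollenSeries
from .season import SectionPartition, SeasonDefinition

__all__ = [
    "TaxonCurveSpec",
    "UserSpec",
    "SyntheticTruth",
    "DEFAULT_TAXA",
    "gen_pollen_year",
    "default_phenology",
    "make_users",
    "gen_cohort",
    "gen_null_cohort",
]


@dataclasses.dataclass(frozen=True)
class TaxonCurveSpec:
    """One taxon's contribution to the airborne curve: a Gaussian bump at
    ``peak_day`` (day of year) with SD ``spread_days`` and height
    ``amplitude`` grains/m^3, plus an optional rebloom bump."""

    taxon: str
    peak_day: int
    spread_days: float
    amplitude: float
    rebloom: tuple[int, float, float] | None = None  # (peak_day, spread, amplitude)

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValidationError(f"{self.taxon}: amplitude must be > 0")
        if self.spread_days <= 0:
            raise ValidationError(f"{self.taxon}: spread must be > 0")

    def mean_on(self, doy: np.ndarray) -> np.ndarray:
        out = self.amplitude * np.exp(
            -((doy - self.peak_day) ** 2) / (2 * self.spread_days**2)
        )
        if self.rebloom is not None:
            p, s, a = self.rebloom
            out = out + a * np.exp(-((doy - p) ** 2) / (2 * s**2))
        return out


# Staggered early/main/late flowering of the most abundant grass taxa of a
# Viennese-style season; amplitudes give an APIn of a few thousand
# pollen.day/m^3 and a season of roughly three months.
DEFAULT_TAXA: tuple[TaxonCurveSpec, ...] = (
    TaxonCurveSpec("Poa pratensis", peak_day=140, spread_days=8.0, amplitude=14.0),
    TaxonCurveSpec("Dactylis glomerata", peak_day=146, spread_days=9.0, amplitude=20.0),
    TaxonCurveSpec("Arrhenatherum elatius", peak_day=163, spread_days=9.0, amplitude=26.0),
    TaxonCurveSpec("Festuca sp.", peak_day=167, spread_days=10.0, amplitude=18.0),
    TaxonCurveSpec("Lolium perenne", peak_day=172, spread_days=11.0, amplitude=22.0),
    TaxonCurveSpec(
        "Phleum pratense", peak_day=196, spread_days=9.0, amplitude=12.0,
        rebloom=(228, 8.0, 4.0),
    ),
    TaxonCurveSpec("Cynodon dactylon", peak_day=203, spread_days=10.0, amplitude=8.0),
)


def gen_pollen_year(
    specs: Sequence[TaxonCurveSpec],
    year: int,
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> PollenSeries:
    """Daily aggregate Poaceae series for one calendar year: the sum of the
    per-taxon bumps, optionally multiplied by lognormal(0, noise_sigma)
    day-to-day noise. Deterministic under a fixed seed."""
    if not specs:
        raise ValidationError("at least one taxon curve spec required")
    n_days = (dt.date(year, 12, 31) - dt.date(year, 1, 1)).days + 1
    doy = np.arange(1, n_days + 1, dtype=float)
    mean = np.zeros(n_days)
    for spec in specs:
        mean += spec.mean_on(doy)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        mean = mean * rng.lognormal(0.0, noise_sigma, size=n_days)
    start = dt.date(year, 1, 1)
    dates = tuple(start + dt.timedelta(days=i) for i in range(n_days))
    return PollenSeries(
        station_id="synthetic", taxon="Poaceae",
        dates=dates, concentrations=mean,
    )


def default_phenology(
    year: int, specs: Sequence[TaxonCurveSpec] = DEFAULT_TAXA
) -> list[PhenologyPeriod]:
    """Flowering intervals consistent with the airborne curve specs:
    flowering spans peak +/- 2 SD, full flowering peak +/- 1 SD."""
    jan1 = dt.date(year, 1, 1)

    def day(doy: float) -> dt.date:
        return jan1 + dt.timedelta(days=int(round(doy)) - 1)

    return [
        PhenologyPeriod(
            taxon=s.taxon,
            flowering_start=day(s.peak_day - 2 * s.spread_days),
            full_flowering_start=day(s.peak_day - s.spread_days),
            full_flowering_end=day(s.peak_day + s.spread_days),
            flowering_end=day(s.peak_day + 2 * s.spread_days),
        )
        for s in specs
    ]


@dataclasses.dataclass(frozen=True)
class UserSpec:
    """One simulated diary user.

    ``sensitivity_weights`` are the per-section dose-response slopes
    (score units per grain/m^3), strictly maximal at ``true_section``;
    ``plateau`` is the saturation score; ``adherence`` the daily
    probability of entering the diary; ``noise_sd`` the SD of the
    Gaussian reporting noise in score units.
    """

    user_id: str
    true_section: int
    sensitivity_weights: tuple[float, float, float]
    plateau: float
    adherence: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.true_section not in (1, 2, 3):
            raise ValidationError(f"true_section must be 1-3, got {self.true_section}")
        w = self.sensitivity_weights
        if any(x < 0 for x in w):
            raise ValidationError(f"user {self.user_id}: negative weight")
        if all(x == 0 for x in w):
            raise ValidationError(f"user {self.user_id}: all-zero weights")
        best = w[self.true_section - 1]
        if any(x >= best for i, x in enumerate(w) if i != self.true_section - 1):
            raise ValidationError(
                f"user {self.user_id}: weight not strictly maximal at "
                f"true_section {self.true_section}: {w}"
            )
        if not 0.0 <= self.adherence <= 1.0:
            raise ValidationError(f"user {self.user_id}: adherence outside [0,1]")
        if self.plateau <= 0:
            raise ValidationError(f"user {self.user_id}: plateau must be > 0")
        if self.noise_sd < 0:
            raise ValidationError(f"user {self.user_id}: negative noise_sd")


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated cohort: hidden section labels, which
    days each user recorded or missed, and the generator provenance."""

    true_sections: Mapping[str, int]
    observed_days: Mapping[str, tuple[dt.date, ...]]
    missing_days: Mapping[str, tuple[dt.date, ...]]
    seed: int
    params: Mapping[str, object]


def make_users(
    n_users: int,
    pollen: PollenSeries,
    partition: SectionPartition,
    seed: int = 0,
    section_probs: tuple[float, float, float] = (0.22, 0.60, 0.18),
    plateau: float = 8.0,
    noise_sd: float = 4.0,
    adherence: float = 0.7,
    off_section_response: float = 0.35,
) -> list[UserSpec]:
    """Draw a cohort of user specifications against one season partition.

    Hidden section labels follow ``section_probs`` (default mirrors the
    early/main/late prevalence of a grass-allergy cohort, with the
    majority peaking in the main season). Each user's dose-response slope
    is scaled so that the response saturates (reaches twice the plateau
    at the section's peak concentration) inside the true section, while
    the off-section peak response stays at ``off_section_response`` of
    the plateau. Defaults: plateau 8 on the 0-12 score scale, reporting
    noise SD at half the plateau, 70% daily adherence.
    """
    rng = np.random.default_rng(seed)
    peak_by_section = {}
    for s, (lo, hi) in enumerate(partition.sections, start=1):
        window = pollen.window(lo, hi)
        if len(window) == 0 or window.concentrations.max() <= 0:
            raise ValidationError(f"section {s} carries no pollen")
        peak_by_section[s] = float(window.concentrations.max())
    users = []
    for i in range(n_users):
        true = 1 + int(rng.choice(3, p=np.asarray(section_probs) / sum(section_probs)))
        weights = tuple(
            (2.0 * plateau if s == true else off_section_response * plateau)
            / peak_by_section[s]
            for s in (1, 2, 3)
        )
        users.append(
            UserSpec(
                user_id=f"u{i:04d}",
                true_section=true,
                sensitivity_weights=weights,
                plateau=plateau,
                adherence=adherence,
                noise_sd=noise_sd,
            )
        )
    return users


def _split_subscores(total: int, max_subscore: int) -> tuple[int, int, int, int]:
    """Distribute an integer daily total over the four sub-scores
    round-robin (nose, eye, lung, medication), capping each at the
    sub-score maximum. Deterministic; downstream only uses the total."""
    order = [0, 0, 0, 0]  # nose, eye, lung, medication
    i = 0
    remaining = total
    while remaining > 0:
        if order[i % 4] < max_subscore:
            order[i % 4] += 1
            remaining -= 1
        i += 1
    nose, eye, lung, medication = order
    return eye, nose, lung, medication


def gen_cohort(
    users: Sequence[UserSpec],
    pollen: PollenSeries,
    partition: SectionPartition,
    seed: int = 0,
    max_subscore: int = 3,
) -> tuple[list[DiaryEntry], SyntheticTruth]:
    """Generate one season of diary entries for a cohort.

    Per user and in-season day the latent score is
    ``min(plateau, weight[section(day)] * concentration(day)) +
    N(0, noise_sd)``, discretised onto the integer range
    [0, 4*max_subscore] and split across the organ sub-scores; the day is
    recorded with probability ``adherence``.
    """
    season = partition.season
    days = season.days
    conc = np.array([pollen.concentration_on(d) for d in days])
    sections = np.array([partition.section_of(d) for d in days])
    max_total = 4 * max_subscore
    rng = np.random.default_rng(seed)
    entries: list[DiaryEntry] = []
    observed: dict[str, tuple[dt.date, ...]] = {}
    missing: dict[str, tuple[dt.date, ...]] = {}
    for user in users:
        w = np.array(user.sensitivity_weights)[sections - 1]
        latent = np.minimum(user.plateau, w * conc)
        if user.noise_sd > 0:
            latent = latent + rng.normal(0.0, user.noise_sd, size=len(days))
        scores = np.clip(np.rint(latent), 0, max_total).astype(int)
        recorded = rng.random(len(days)) < user.adherence
        obs, miss = [], []
        for day, score, rec in zip(days, scores, recorded):
            if not rec:
                miss.append(day)
                continue
            obs.append(day)
            eye, nose, lung, medication = _split_subscores(int(score), max_subscore)
            entries.append(
                DiaryEntry(
                    user_id=user.user_id, date=day,
                    eye_score=eye, nose_score=nose,
                    lung_score=lung, medication_score=medication,
                )
            )
        observed[user.user_id] = tuple(obs)
        missing[user.user_id] = tuple(miss)
    truth = SyntheticTruth(
        true_sections={u.user_id: u.true_section for u in users},
        observed_days=observed,
        missing_days=missing,
        seed=seed,
        params={
            "n_users": len(users),
            "partition_method": partition.method,
            "max_subscore": max_subscore,
        },
    )
    return entries, truth


def gen_null_cohort(
    n_users: int,
    season: SeasonDefinition,
    seed: int = 0,
    adherence: float = 0.7,
    max_subscore: int = 3,
) -> list[DiaryEntry]:
    """Diary entries with scores independent of pollen (uniform on the
    integer score range), for studying the false-positive rate of the
    allergy-sufferer filter."""
    days = season.days
    max_total = 4 * max_subscore
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_users):
        recorded = rng.random(len(days)) < adherence
        scores = rng.integers(0, max_total + 1, size=len(days))
        for day, score, rec in zip(days, scores, recorded):
            if rec:
                eye, nose, lung, medication = _split_subscores(int(score), max_subscore)
                entries.append(
                    DiaryEntry(
                        user_id=f"null{i:04d}", date=day,
                        eye_score=eye, nose_score=nose,
                        lung_score=lung, medication_score=medication,
                    )
                )
    return entries
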