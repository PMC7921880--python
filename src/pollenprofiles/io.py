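"""Domain types and CSV/YAML readers and writers.

The pipeline exchanges three plain-text formats:

* pollen CSV      — columns ``date,taxon,concentration`` (daily mean
  grains/m^3 from a volumetric Hirst-type trap);
* diary CSV       — columns ``user_id,date,eye,nose,lung,medication[,zip]``
  (one row per user-day of a symptom diary);
* phenology CSV   — columns ``taxon,flowering_start,full_start,full_end,
  flowering_end`` (field-observed flowering intervals per grass taxon).

Dates are ISO-8601 calendar dates; day-of-year is always derived, never
stored. All date intervals in this package are closed (both endpoints
included). Validation errors name the offending line and field.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ParseError, ValidationError

__all__ = [
    "PollenSeries",
    "DiaryEntry",
    "PhenologyPeriod",
    "RunConfig",
    "read_pollen_csv",
    "write_pollen_csv",
    "read_diary_csv",
    "write_diary_csv",
    "read_phenology_csv",
    "write_phenology_csv",
    "load_config",
    "iso_week_monday",
]


def _parse_date(text: str, line_no: int, field: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text.strip())
    except ValueError as exc:
        raise ParseError(
            f"line {line_no}: field '{field}': malformed date {text!r}"
        ) from exc


@dataclasses.dataclass(frozen=True)
class PollenSeries:
    """Daily mean airborne pollen concentrations for one taxon and station.

    ``dates`` are strictly increasing, duplicate-free calendar dates and
    ``concentrations`` are the matching non-negative daily means.
    """

    station_id: str
    taxon: str
    dates: tuple[dt.date, ...]
    concentrations: np.ndarray  # float64, same length as dates

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        if len(self.dates) != len(conc):
            raise ValidationError("dates and concentrations differ in length")
        for i in range(1, len(self.dates)):
            if self.dates[i] <= self.dates[i - 1]:
                raise ValidationError(
                    f"dates not strictly increasing at position {i}: "
                    f"{self.dates[i - 1]} then {self.dates[i]}"
                )
        bad = np.nonzero(conc < 0)[0]
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"negative concentration {conc[i]} on {self.dates[i]}"
            )

    def __len__(self) -> int:
        return len(self.dates)

    def as_series(self) -> pd.Series:
        """The record as a pandas Series indexed by calendar date."""
        return pd.Series(self.concentrations, index=list(self.dates), name=self.taxon)

    def year_slice(self, year: int) -> "PollenSeries":
        keep = [i for i, d in enumerate(self.dates) if d.year == year]
        return PollenSeries(
            station_id=self.station_id,
            taxon=self.taxon,
            dates=tuple(self.dates[i] for i in keep),
            concentrations=self.concentrations[keep],
        )

    def window(self, start: dt.date, end: dt.date) -> "PollenSeries":
        """Restrict to the closed interval [start, end]."""
        keep = [i for i, d in enumerate(self.dates) if start <= d <= end]
        return PollenSeries(
            station_id=self.station_id,
            taxon=self.taxon,
            dates=tuple(self.dates[i] for i in keep),
            concentrations=self.concentrations[keep],
        )

    def concentration_on(self, day: dt.date) -> float:
        """Concentration on ``day``; days absent from the record count as 0."""
        try:
            i = self.dates.index(day)
        except ValueError:
            return 0.0
        return float(self.concentrations[i])

    @classmethod
    def from_mapping(
        cls, values: Mapping[dt.date, float], taxon: str = "Poaceae",
        station_id: str = "synthetic",
    ) -> "PollenSeries":
        days = sorted(values)
        return cls(
            station_id=station_id,
            taxon=taxon,
            dates=tuple(days),
            concentrations=np.array([values[d] for d in days], dtype=float),
        )


@dataclasses.dataclass(frozen=True)
class DiaryEntry:
    """One user-day record of a symptom diary: eye, nose and lung severity
    sub-scores plus a medication-use score."""

    user_id: str
    date: dt.date
    eye_score: int
    nose_score: int
    lung_score: int
    medication_score: int
    zip_code: str | None = None

    def __post_init__(self) -> None:
        for field in ("eye_score", "nose_score", "lung_score", "medication_score"):
            v = getattr(self, field)
            if v < 0:
                raise ValidationError(
                    f"user {self.user_id} on {self.date}: negative {field} ({v})"
                )

    def validate_maxima(self, max_subscore: int) -> None:
        for field in ("eye_score", "nose_score", "lung_score", "medication_score"):
            v = getattr(self, field)
            if v > max_subscore:
                raise ValidationError(
                    f"user {self.user_id} on {self.date}: {field}={v} exceeds "
                    f"configured maximum {max_subscore}"
                )


@dataclasses.dataclass(frozen=True)
class PhenologyPeriod:
    """Flowering interval of one grass taxon: onset, full-flowering window
    and end, with onset <= full start <= full end <= end."""

    taxon: str
    flowering_start: dt.date
    full_flowering_start: dt.date
    full_flowering_end: dt.date
    flowering_end: dt.date

    def __post_init__(self) -> None:
        seq = (
            self.flowering_start,
            self.full_flowering_start,
            self.full_flowering_end,
            self.flowering_end,
        )
        if any(a > b for a, b in zip(seq, seq[1:])):
            raise ValidationError(
                f"taxon {self.taxon}: phenology dates out of order: "
                f"{', '.join(str(d) for d in seq)}"
            )


@dataclasses.dataclass
class RunConfig:
    """Tunable pipeline parameters with the defaults used throughout.

    ``score_weights`` weight the four diary sub-scores in the daily total;
    ``max_subscore`` caps each sub-score; the user filter keeps users with a
    positive ``correlation_method`` coefficient at one-sided p < ``alpha``
    and at least ``min_entries`` in-season days; ``k`` is the
    nearest-neighbour count of the imputer; ``severity_statistic`` summarises
    daily scores per section for the assignment step.
    """

    score_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    max_subscore: int = 3
    correlation_method: str = "spearman"
    alpha: float = 0.05
    min_entries: int = 15
    k: int = 3
    severity_statistic: str = "mean"
    lag_days: int = 0
    seed: int = 0
    early_taxa: tuple[str, ...] = ("Poa pratensis", "Dactylis glomerata")
    main_taxa: tuple[str, ...] = ("Arrhenatherum elatius", "Festuca sp.", "Lolium perenne")
    late_taxa: tuple[str, ...] = ("Phleum pratense", "Cynodon dactylon")

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        if self.min_entries < 1:
            raise ConfigError(f"min_entries must be >= 1, got {self.min_entries}")
        if self.correlation_method not in ("spearman", "pearson"):
            raise ConfigError(f"unknown correlation method {self.correlation_method!r}")
        if self.severity_statistic not in ("mean", "sum", "peak"):
            raise ConfigError(f"unknown severity statistic {self.severity_statistic!r}")


def load_config(path: str | Path) -> RunConfig:
    """Read a :class:`RunConfig` from a YAML file; absent keys keep defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("score_weights", "early_taxa", "main_taxa", "late_taxa"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def iso_week_monday(year: int, week: int) -> dt.date:
    """Monday of ISO week ``week`` of ``year`` — the convention for turning
    calendar-week phenology sources into dates."""
    return dt.date.fromisocalendar(year, week, 1)


# ---------------------------------------------------------------------------
# pollen CSV

def read_pollen_csv(path: str | Path, station_id: str = "") -> PollenSeries:
    """Read a pollen CSV (columns date,taxon,concentration) into a validated
    :class:`PollenSeries`, sorted by date.

    Raises :class:`ParseError` on malformed dates or numbers and
    :class:`ValidationError` on negative concentrations or duplicate dates,
    naming the offending line.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"date", "taxon", "concentration"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    rows = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        day = _parse_date(row["date"], line_no, "date")
        try:
            conc = float(row["concentration"])
        except ValueError as exc:
            raise ParseError(
                f"line {line_no}: field 'concentration': not a number "
                f"{row['concentration']!r}"
            ) from exc
        if conc < 0:
            raise ValidationError(
                f"line {line_no}: negative concentration {conc}"
            )
        rows.append((day, str(row["taxon"]), conc))
    rows.sort(key=lambda r: r[0])
    for (a, _, _), (b, _, _) in zip(rows, rows[1:]):
        if a == b:
            raise ValidationError(f"duplicate date {a}")
    taxa = {t for _, t, _ in rows}
    if len(taxa) > 1:
        raise ValidationError(f"multiple taxa in one file: {sorted(taxa)}")
    return PollenSeries(
        station_id=station_id,
        taxon=rows[0][1] if rows else "Poaceae",
        dates=tuple(r[0] for r in rows),
        concentrations=np.array([r[2] for r in rows], dtype=float),
    )


def write_pollen_csv(series: PollenSeries, path: str | Path) -> None:
    """Write the canonical pollen CSV (ISO dates, date-sorted)."""
    df = pd.DataFrame(
        {
            "date": [d.isoformat() for d in series.dates],
            "taxon": series.taxon,
            "concentration": series.concentrations,
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# diary CSV

_DIARY_COLS = ("user_id", "date", "eye", "nose", "lung", "medication")


def read_diary_csv(
    path: str | Path, cfg: RunConfig | None = None
) -> list[DiaryEntry]:
    """Read diary entries, rejecting duplicate (user, day) rows and
    sub-scores above the configured maximum."""
    cfg = cfg or RunConfig()
    df = pd.read_csv(path, dtype=str)
    missing = set(_DIARY_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    entries: list[DiaryEntry] = []
    seen: set[tuple[str, dt.date]] = set()
    for idx, row in df.iterrows():
        line_no = int(idx) + 2
        day = _parse_date(row["date"], line_no, "date")
        try:
            scores = [int(row[c]) for c in ("eye", "nose", "lung", "medication")]
        except ValueError as exc:
            raise ParseError(f"line {line_no}: non-integer sub-score") from exc
        key = (str(row["user_id"]), day)
        if key in seen:
            raise ValidationError(
                f"line {line_no}: duplicate entry for user {key[0]} on {day}"
            )
        seen.add(key)
        zip_code = row.get("zip")
        entry = DiaryEntry(
            user_id=key[0],
            date=day,
            eye_score=scores[0],
            nose_score=scores[1],
            lung_score=scores[2],
            medication_score=scores[3],
            zip_code=None if zip_code is None or pd.isna(zip_code) else str(zip_code),
        )
        entry.validate_maxima(cfg.max_subscore)
        entries.append(entry)
    return entries


def write_diary_csv(entries: Iterable[DiaryEntry], path: str | Path) -> None:
    entries = sorted(entries, key=lambda e: (e.user_id, e.date))
    df = pd.DataFrame(
        {
            "user_id": [e.user_id for e in entries],
            "date": [e.date.isoformat() for e in entries],
            "eye": [e.eye_score for e in entries],
            "nose": [e.nose_score for e in entries],
            "lung": [e.lung_score for e in entries],
            "medication": [e.medication_score for e in entries],
            "zip": [e.zip_code or "" for e in entries],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# phenology CSV

_PHEN_COLS = ("taxon", "flowering_start", "full_start", "full_end", "flowering_end")


def read_phenology_csv(path: str | Path) -> list[PhenologyPeriod]:
    """Read per-taxon flowering intervals, enforcing date ordering."""
    df = pd.read_csv(path, dtype=str)
    missing = set(_PHEN_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    periods = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2
        dates = [_parse_date(row[c], line_no, c) for c in _PHEN_COLS[1:]]
        periods.append(
            PhenologyPeriod(
                taxon=str(row["taxon"]),
                flowering_start=dates[0],
                full_flowering_start=dates[1],
                full_flowering_end=dates[2],
                flowering_end=dates[3],
            )
        )
    return periods


def write_phenology_csv(
    periods: Sequence[PhenologyPeriod], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "taxon": [p.taxon for p in periods],
            "flowering_start": [p.flowering_start.isoformat() for p in periods],
            "full_start": [p.full_flowering_start.isoformat() for p in periods],
            "full_end": [p.full_flowering_end.isoformat() for p in periods],
            "flowering_end": [p.flowering_end.isoformat() for p in periods],
        }
    )
    df.to_csv(path, index=False)
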