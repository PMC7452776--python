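"""Study data model and delimited-file I/O.

The package consumes four UTF-8 comma-separated tables with headers:

``hens.csv``
    hen_id, year, age_class, weight_kg, available_april1, nested
``nests.csv``
    nest_id, hen_id, year, attempt, start_date, end_date, fate, cover_type,
    vor_mean, total_cover_mean, dist_road_m, x_m, y_m, clutch_size,
    eggs_hatched
``broods.csv``
    brood_id, hen_id, year, hen_age_class, hatch_date, n_initial, count_d7,
    count_d14, count_d28, hen_death_day
``weather.csv``
    station_id, x_m, y_m, date, precip_mm, temp_c

Dates are ordinal day-of-year integers (1 = 1 January).  Coordinates are
planar meters in a projected system; distance-to-road is consumed as a
precomputed covariate.  Missing values are written as empty fields.

Daily nest survival indicators are reconstructed from (start_date, end_date,
fate): a nest incubated from ``start_date`` and met its fate during the day
ending at ``end_date``, giving ``end_date - start_date`` exposure days.  The
survival vector is absorbing: a failed nest is all ones followed by a single
terminal zero; a hatched nest is all ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGE_CLASSES",
    "COVER_TYPES",
    "FAILURE_FATES",
    "FATES",
    "CENSOR_FATES",
    "HenYear",
    "WeatherStation",
    "NestHistory",
    "BroodSeries",
    "FailureTable",
    "StudyData",
    "SchemaError",
    "ValidationError",
    "load_study_tables",
    "write_study_tables",
    "assign_weather",
    "build_nest_histories",
    "summarize_failure_causes",
    "center_covariates",
]

AGE_CLASSES = ("yearling", "adult")
COVER_TYPES = ("grassland", "pasture", "agriculture", "forest")
FAILURE_FATES = ("abandoned", "hen_died", "hayed", "depredated", "trampled")
CENSOR_FATES = ("censored_interference", "censored_access")
FATES = ("hatched",) + FAILURE_FATES + CENSOR_FATES

#: Census day indices posthatch (hatch day is t = 1): counts at 7, 14 and
#: 28 days posthatch correspond to t = 8, 15, 29.
CENSUS_INDICES = (8, 15, 29)


class SchemaError(ValueError):
    """A required column is missing or has the wrong dtype."""


class ValidationError(ValueError):
    """A row violates a data-model invariant."""


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class HenYear:
    """One hen monitored in one study year."""

    hen_id: str
    year: int
    age_class: str
    weight_kg: float
    available_april1: bool
    nested: bool | None = None

    def validate(self) -> None:
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(
                f"hen {self.hen_id}/{self.year}: unknown age_class {self.age_class!r}"
            )
        if not self.weight_kg > 0:
            raise ValidationError(
                f"hen {self.hen_id}/{self.year}: weight_kg must be > 0"
            )


@dataclass
class WeatherStation:
    """A precipitation/temperature monitoring station with a daily series."""

    station_id: str
    x_m: float
    y_m: float
    dates: np.ndarray  # ordinal dates, strictly increasing, gap-free
    precip_mm: np.ndarray
    temp_c: np.ndarray

    def validate(self) -> None:
        d = np.asarray(self.dates)
        if d.size and not np.all(np.diff(d) == 1):
            raise ValidationError(
                f"station {self.station_id}: dates must be gap-free and increasing"
            )
        if np.any(np.asarray(self.precip_mm) < 0):
            raise ValidationError(f"station {self.station_id}: precip_mm < 0")

    def series(self, dates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dates = np.asarray(dates)
        if dates.size == 0:
            return np.empty(0), np.empty(0)
        if dates.min() < self.dates[0] or dates.max() > self.dates[-1]:
            raise ValidationError(
                f"station {self.station_id} does not cover dates "
                f"{dates.min()}..{dates.max()}"
            )
        idx = dates - self.dates[0]
        return self.precip_mm[idx], self.temp_c[idx]


@dataclass
class NestHistory:
    """Per-nest daily survival indicators with covariates and fate."""

    nest_id: str
    hen_id: str
    year: int
    attempt: int
    start_date: int
    survival: np.ndarray  # binary, absorbing
    fate: str
    cover_type: str
    vor_mean: float | None
    total_cover_mean: float | None
    dist_road_m: float
    x_m: float
    y_m: float
    clutch_size: int | None = None
    eggs_hatched: int | None = None
    precip_mm: np.ndarray | None = None  # per exposure day
    temp_c: np.ndarray | None = None

    @property
    def n_days(self) -> int:
        return int(len(self.survival))

    @property
    def end_date(self) -> int:
        return self.start_date + self.n_days

    @property
    def failed(self) -> bool:
        return self.fate in FAILURE_FATES

    @property
    def censored(self) -> bool:
        return self.fate in CENSOR_FATES

    def validate(self) -> None:
        if self.fate not in FATES:
            raise ValidationError(f"nest {self.nest_id}: unknown fate {self.fate!r}")
        if self.cover_type not in COVER_TYPES:
            raise ValidationError(
                f"nest {self.nest_id}: unknown cover_type {self.cover_type!r}"
            )
        if self.attempt not in (1, 2, 3):
            raise ValidationError(f"nest {self.nest_id}: attempt must be 1, 2 or 3")
        y = np.asarray(self.survival)
        if y.size == 0:
            raise ValidationError(
                f"nest {self.nest_id}: terminal event precedes incubation onset"
            )
        if np.any((y != 0) & (y != 1)):
            raise ValidationError(f"nest {self.nest_id}: survival must be binary")
        zeros = np.flatnonzero(y == 0)
        if zeros.size > 1 or (zeros.size == 1 and zeros[0] != y.size - 1):
            raise ValidationError(
                f"nest {self.nest_id}: survival vector must be absorbing"
            )
        if self.fate == "hatched" and zeros.size:
            raise ValidationError(f"nest {self.nest_id}: hatched nest with a failure day")
        if self.fate in FAILURE_FATES and not zeros.size:
            raise ValidationError(
                f"nest {self.nest_id}: failed nest without a failure day"
            )
        missing_vor = _is_missing(self.vor_mean)
        missing_cov = _is_missing(self.total_cover_mean)
        if (missing_vor or missing_cov) and self.fate == "hatched":
            raise ValidationError(
                f"nest {self.nest_id}: vegetation covariates may be missing only "
                "for failed nests"
            )
        if _is_missing(self.dist_road_m) or self.dist_road_m < 0:
            raise ValidationError(f"nest {self.nest_id}: dist_road_m must be >= 0")
        if not missing_cov and not 0.0 <= self.total_cover_mean <= 1.0:
            raise ValidationError(
                f"nest {self.nest_id}: total_cover_mean must lie in [0, 1]"
            )


@dataclass
class BroodSeries:
    """Initial poult count plus censuses at 7/14/28 days posthatch.

    ``counts`` maps census day index t in {8, 15, 29} to the observed count;
    ``hen_death_day`` is the day-posthatch index (1..28) on which the
    brood-rearing hen died, if she did.
    """

    brood_id: str
    hen_id: str
    year: int
    hen_age_class: str
    hatch_date: int
    n_initial: int
    counts: dict[int, int]
    hen_death_day: int | None = None
    precip_mm: np.ndarray | None = None  # days posthatch 1..28
    temp_c: np.ndarray | None = None

    def validate(self) -> None:
        if self.hen_age_class not in AGE_CLASSES:
            raise ValidationError(
                f"brood {self.brood_id}: unknown age class {self.hen_age_class!r}"
            )
        if self.n_initial < 0:
            raise ValidationError(f"brood {self.brood_id}: n_initial < 0")
        prev = self.n_initial
        for t in CENSUS_INDICES:
            if t not in self.counts:
                continue
            c = self.counts[t]
            if c < 0 or c > prev:
                raise ValidationError(
                    f"brood {self.brood_id}: counts must be non-increasing and "
                    f"bounded by n_initial (census t={t})"
                )
            if (
                self.hen_death_day is not None
                and t - 1 >= self.hen_death_day
                and c != 0
            ):
                raise ValidationError(
                    f"brood {self.brood_id}: census after hen death must be 0"
                )
            prev = c


@dataclass
class FailureTable:
    """Counts and integer percentages of failed nest attempts by cause."""

    counts: dict[str, int]
    total_failed: int

    @property
    def percentages(self) -> dict[str, int]:
        if self.total_failed == 0:
            return {cause: 0 for cause in self.counts}
        return {
            cause: int(round(100.0 * n / self.total_failed))
            for cause, n in self.counts.items()
        }

    @property
    def proportions(self) -> dict[str, float]:
        if self.total_failed == 0:
            return {cause: 0.0 for cause in self.counts}
        return {c: n / self.total_failed for c, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "cause": list(self.counts),
                "count": list(self.counts.values()),
                "percentage": [pct[c] for c in self.counts],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class StudyData:
    """All study tables, typed and validated."""

    hens: list[HenYear]
    nests: list[NestHistory]
    broods: list[BroodSeries]
    stations: list[WeatherStation]

    def validate(self) -> None:
        for h in self.hens:
            h.validate()
        for n in self.nests:
            n.validate()
        for b in self.broods:
            b.validate()
        for s in self.stations:
            s.validate()
        self._check_age_transitions()

    def _check_age_transitions(self) -> None:
        by_hen: dict[str, list[HenYear]] = {}
        for h in self.hens:
            by_hen.setdefault(h.hen_id, []).append(h)
        for hen_id, rows in by_hen.items():
            rows = sorted(rows, key=lambda r: r.year)
            for a, b in zip(rows, rows[1:]):
                if a.age_class == "adult" and b.age_class == "yearling":
                    raise ValidationError(
                        f"hen {hen_id}: age class may never revert adult -> yearling"
                    )


# ---------------------------------------------------------------------------
# weather assignment
# ---------------------------------------------------------------------------

def assign_weather(
    x_m: float,
    y_m: float,
    stations: Sequence[WeatherStation],
    dates: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Daily (precip_mm, temp_c) from the nearest monitoring station.

    The station minimizing Euclidean distance to (x_m, y_m) supplies the
    whole series; exact distance ties are broken by the smallest station_id,
    which makes the result independent of station ordering in the input.
    """
    if not stations:
        raise ValidationError("no weather stations supplied")
    best = min(
        stations,
        key=lambda s: ((s.x_m - x_m) ** 2 + (s.y_m - y_m) ** 2, str(s.station_id)),
    )
    return best.series(np.asarray(dates))


# ---------------------------------------------------------------------------
# encounter histories
# ---------------------------------------------------------------------------

def build_nest_histories(attempts: Iterable[NestHistory]) -> list[NestHistory]:
    """Select the nest attempts retained for survival analysis.

    Attempts censored for investigator interference or lack of site access
    are excluded; hen death while incubating is already encoded as a failure
    day with fate ``hen_died``.  Retained count + censored count equals the
    input count.
    """
    retained = []
    for nest in attempts:
        nest.validate()
        if not nest.censored:
            retained.append(nest)
    return retained


def summarize_failure_causes(histories: Iterable[NestHistory]) -> FailureTable:
    """Tabulate causes of failure among non-censored nest attempts.

    Percentages are counts over total failures, rounded to the nearest
    integer percent.  Zero failed attempts yield an empty table.
    """
    counts = {cause: 0 for cause in FAILURE_FATES}
    total = 0
    for nest in histories:
        if nest.censored:
            raise ValidationError(
                "failure summary expects censored attempts to be excluded first"
            )
        if nest.failed:
            counts[nest.fate] += 1
            total += 1
    return FailureTable(counts=counts, total_failed=total)


def center_covariates(
    frame: pd.DataFrame, names: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Subtract sample means from continuous covariates.

    Missing values are excluded from each mean and stay missing in the
    output.  The means are returned for back-transforming prediction curves
    to natural covariate scales.
    """
    out = frame.copy()
    means: dict[str, float] = {}
    for name in names:
        col = pd.to_numeric(out[name], errors="coerce")
        if col.notna().sum() == 0:
            raise ValidationError(f"covariate {name!r} is entirely missing")
        mu = float(col.mean())
        out[name] = col - mu
        means[name] = mu
    return out, means


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_HEN_COLS = ["hen_id", "year", "age_class", "weight_kg", "available_april1", "nested"]
_NEST_COLS = [
    "nest_id", "hen_id", "year", "attempt", "start_date", "end_date", "fate",
    "cover_type", "vor_mean", "total_cover_mean", "dist_road_m", "x_m", "y_m",
    "clutch_size", "eggs_hatched",
]
_BROOD_COLS = [
    "brood_id", "hen_id", "year", "hen_age_class", "hatch_date", "n_initial",
    "count_d7", "count_d14", "count_d28", "hen_death_day",
]
_WEATHER_COLS = ["station_id", "x_m", "y_m", "date", "precip_mm", "temp_c"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    for col in cols:
        if col not in df.columns:
            raise SchemaError(f"{table}: missing required column {col!r}")


def _opt_int(x) -> int | None:
    return None if _is_missing(x) else int(x)


def _opt_float(x) -> float | None:
    return None if _is_missing(x) else float(x)


def _opt_bool(x) -> bool | None:
    if _is_missing(x) or x == "":
        return None
    if isinstance(x, str):
        return x.strip().lower() in ("true", "1", "yes")
    return bool(x)


def load_study_tables(directory) -> StudyData:
    """Read the four study CSVs from ``directory`` into validated records.

    Nest survival vectors are reconstructed from start/end dates and fate;
    daily weather is attached to every nest (incubation window) and brood
    (28-day posthatch window) from the nearest monitoring station.
    """
    directory = Path(directory)
    hens_df = pd.read_csv(directory / "hens.csv")
    nests_df = pd.read_csv(directory / "nests.csv")
    broods_df = pd.read_csv(directory / "broods.csv")
    weather_df = pd.read_csv(directory / "weather.csv")
    _require_columns(hens_df, _HEN_COLS, "hens.csv")
    _require_columns(nests_df, _NEST_COLS, "nests.csv")
    _require_columns(broods_df, _BROOD_COLS, "broods.csv")
    _require_columns(weather_df, _WEATHER_COLS, "weather.csv")

    stations = []
    for sid, grp in weather_df.groupby("station_id", sort=True):
        grp = grp.sort_values("date")
        stations.append(
            WeatherStation(
                station_id=str(sid),
                x_m=float(grp["x_m"].iloc[0]),
                y_m=float(grp["y_m"].iloc[0]),
                dates=grp["date"].to_numpy(dtype=int),
                precip_mm=grp["precip_mm"].to_numpy(dtype=float),
                temp_c=grp["temp_c"].to_numpy(dtype=float),
            )
        )

    hens = []
    for i, row in hens_df.iterrows():
        try:
            hens.append(
                HenYear(
                    hen_id=str(row["hen_id"]),
                    year=int(row["year"]),
                    age_class=str(row["age_class"]),
                    weight_kg=float(row["weight_kg"]),
                    available_april1=bool(_opt_bool(row["available_april1"])),
                    nested=_opt_bool(row["nested"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"hens.csv row {i}: {exc}") from exc

    nests = []
    for i, row in nests_df.iterrows():
        start, end = int(row["start_date"]), int(row["end_date"])
        if end <= start:
            raise ValidationError(
                f"nests.csv row {i} (nest {row['nest_id']}): terminal event "
                "must come after incubation onset"
            )
        n_days = end - start
        fate = str(row["fate"])
        y = np.ones(n_days, dtype=np.int8)
        if fate in FAILURE_FATES:
            y[-1] = 0
        nests.append(
            NestHistory(
                nest_id=str(row["nest_id"]),
                hen_id=str(row["hen_id"]),
                year=int(row["year"]),
                attempt=int(row["attempt"]),
                start_date=start,
                survival=y,
                fate=fate,
                cover_type=str(row["cover_type"]),
                vor_mean=_opt_float(row["vor_mean"]),
                total_cover_mean=_opt_float(row["total_cover_mean"]),
                dist_road_m=float(row["dist_road_m"]),
                x_m=float(row["x_m"]),
                y_m=float(row["y_m"]),
                clutch_size=_opt_int(row["clutch_size"]),
                eggs_hatched=_opt_int(row["eggs_hatched"]),
            )
        )

    broods = []
    for i, row in broods_df.iterrows():
        counts = {}
        for t, col in zip(CENSUS_INDICES, ("count_d7", "count_d14", "count_d28")):
            c = _opt_int(row[col])
            if c is not None:
                counts[t] = c
        broods.append(
            BroodSeries(
                brood_id=str(row["brood_id"]),
                hen_id=str(row["hen_id"]),
                year=int(row["year"]),
                hen_age_class=str(row["hen_age_class"]),
                hatch_date=int(row["hatch_date"]),
                n_initial=int(row["n_initial"]),
                counts=counts,
                hen_death_day=_opt_int(row["hen_death_day"]),
            )
        )

    study = StudyData(hens=hens, nests=nests, broods=broods, stations=stations)
    study.validate()
    attach_weather(study)
    return study


def attach_weather(study: StudyData) -> None:
    """Fill per-day weather series on nests and broods from nearest stations."""
    if not study.stations:
        return
    for nest in study.nests:
        dates = nest.start_date + np.arange(nest.n_days)
        nest.precip_mm, nest.temp_c = assign_weather(
            nest.x_m, nest.y_m, study.stations, dates
        )
    hen_nest_xy = {}
    for n in study.nests:
        if n.fate == "hatched":
            hen_nest_xy[(n.hen_id, n.year)] = (n.x_m, n.y_m)
    for brood in study.broods:
        xy = hen_nest_xy.get((brood.hen_id, brood.year))
        if xy is None:
            # brood without a matching hatched nest: use study centroid
            xy = (
                float(np.mean([s.x_m for s in study.stations])),
                float(np.mean([s.y_m for s in study.stations])),
            )
        dates = brood.hatch_date + np.arange(28)
        brood.precip_mm, brood.temp_c = assign_weather(
            xy[0], xy[1], study.stations, dates
        )


def write_study_tables(study: StudyData, directory) -> None:
    """Write the four study CSVs; a read back reproduces identical records."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "hen_id": h.hen_id,
                "year": h.year,
                "age_class": h.age_class,
                "weight_kg": h.weight_kg,
                "available_april1": h.available_april1,
                "nested": "" if h.nested is None else h.nested,
            }
            for h in study.hens
        ],
        columns=_HEN_COLS,
    ).to_csv(directory / "hens.csv", index=False)

    pd.DataFrame(
        [
            {
                "nest_id": n.nest_id,
                "hen_id": n.hen_id,
                "year": n.year,
                "attempt": n.attempt,
                "start_date": n.start_date,
                "end_date": n.end_date,
                "fate": n.fate,
                "cover_type": n.cover_type,
                "vor_mean": n.vor_mean,
                "total_cover_mean": n.total_cover_mean,
                "dist_road_m": n.dist_road_m,
                "x_m": n.x_m,
                "y_m": n.y_m,
                "clutch_size": n.clutch_size,
                "eggs_hatched": n.eggs_hatched,
            }
            for n in study.nests
        ],
        columns=_NEST_COLS,
    ).to_csv(directory / "nests.csv", index=False)

    pd.DataFrame(
        [
            {
                "brood_id": b.brood_id,
                "hen_id": b.hen_id,
                "year": b.year,
                "hen_age_class": b.hen_age_class,
                "hatch_date": b.hatch_date,
                "n_initial": b.n_initial,
                "count_d7": b.counts.get(8),
                "count_d14": b.counts.get(15),
                "count_d28": b.counts.get(29),
                "hen_death_day": b.hen_death_day,
            }
            for b in study.broods
        ],
        columns=_BROOD_COLS,
    ).to_csv(directory / "broods.csv", index=False)

    rows = []
    for s in study.stations:
        for d, p, t in zip(s.dates, s.precip_mm, s.temp_c):
            rows.append(
                {
                    "station_id": s.station_id,
                    "x_m": s.x_m,
                    "y_m": s.y_m,
                    "date": int(d),
                    "precip_mm": float(p),
                    "temp_c": float(t),
                }
            )
    pd.DataFrame(rows, columns=_WEATHER_COLS).to_csv(
        directory / "weather.csv", index=False
    )
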