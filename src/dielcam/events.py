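"""Detection-record ingest: independence filtering, station retention and
diel classification.

Raw camera-trap data arrive as one row per photo (site, station, species,
local timestamp, number of individuals).  Three rules turn photos into
independent detection events:

* repeat captures of the same species at the same station within a fixed
  window (default 1 h) collapse onto the first retained capture;
* a photo of several conspecific individuals is one event;
* a photo containing two species contributes one event per species (such
  photos arrive as two rows sharing a timestamp/station).

Each event's clock time is then mapped onto the 24-h circle and classified
against a solar schedule into diurnal / nocturnal, with a crepuscular
(twilight) window of +-1 h around sunrise and sunset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import (
    HOURS_PER_CYCLE,
    TWO_PI,
    hours_to_radians,
    radians_to_hours,
    round_half_up,
)

log = logging.getLogger(__name__)

#: canonical input column order for detection CSVs
RECORD_COLUMNS = ["site", "station", "species", "datetime", "count"]

DIEL_CATEGORIES = (
    "strongly_diurnal",
    "mostly_diurnal",
    "cathemeral",
    "mostly_nocturnal",
    "strongly_nocturnal",
)


class EmptyResultError(ValueError):
    """Raised when a filtering step leaves nothing to analyse."""


@dataclass(frozen=True)
class SolarSchedule:
    """Sunrise/sunset anchors for the diel partition.

    Times are clock hours; the defaults (06:00 / 18:00) are the study-area
    averages appropriate near the equator.  ``twilight_halfwidth`` is the
    half-width (hours) of the crepuscular windows around both anchors.
    """

    sunrise: float = 6.0
    sunset: float = 18.0
    twilight_halfwidth: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.sunrise < self.sunset < HOURS_PER_CYCLE:
            raise ValueError("require 0 <= sunrise < sunset < 24")
        if self.twilight_halfwidth <= 0:
            raise ValueError("twilight_halfwidth must be positive")
        day = self.sunset - self.sunrise
        if 2 * self.twilight_halfwidth >= day or 2 * self.twilight_halfwidth >= HOURS_PER_CYCLE - day:
            raise ValueError("twilight windows overlap each other")

    def is_diurnal(self, hours) -> np.ndarray:
        """Half-open day interval [sunrise, sunset)."""
        h = np.asarray(hours, dtype=float) % HOURS_PER_CYCLE
        return (h >= self.sunrise) & (h < self.sunset)

    def is_twilight(self, hours) -> np.ndarray:
        h = np.asarray(hours, dtype=float) % HOURS_PER_CYCLE
        out = np.zeros(h.shape, dtype=bool)
        for anchor in (self.sunrise, self.sunset):
            d = np.abs((h - anchor + HOURS_PER_CYCLE / 2) % HOURS_PER_CYCLE - HOURS_PER_CYCLE / 2)
            out |= d < self.twilight_halfwidth
        return out


@dataclass
class EventSeries:
    """Independent events of one species as angles on the 24-h circle."""

    species: str
    times: np.ndarray  # radians in [0, 2*pi)
    station_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float) % TWO_PI
        if self.station_ids is None:
            self.station_ids = np.full(self.times.shape, "", dtype=object)
        else:
            self.station_ids = np.asarray(self.station_ids, dtype=object)
        if self.station_ids.shape != self.times.shape:
            raise ValueError("times and station_ids must be parallel")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def hours(self) -> np.ndarray:
        return radians_to_hours(self.times)


@dataclass(frozen=True)
class DielSummary:
    """Day/night/twilight tally of one species' events.

    ``n_twilight`` may overlap both day and night counts because the
    crepuscular windows straddle the sunrise/sunset boundaries; percentages
    are reported against the total.
    """

    species: str
    n_total: int
    n_diurnal: int
    n_nocturnal: int
    n_twilight: int

    def __post_init__(self):
        if self.n_total <= 0:
            raise ValueError("diel category undefined for an empty series")
        if self.n_diurnal + self.n_nocturnal != self.n_total:
            raise ValueError("diurnal + nocturnal must equal total")

    @classmethod
    def from_counts(cls, species, n_total, n_diurnal=None, n_nocturnal=None, n_twilight=0):
        if n_diurnal is None and n_nocturnal is None:
            raise ValueError("supply n_diurnal or n_nocturnal")
        if n_diurnal is None:
            n_diurnal = n_total - n_nocturnal
        if n_nocturnal is None:
            n_nocturnal = n_total - n_diurnal
        return cls(species, int(n_total), int(n_diurnal), int(n_nocturnal), int(n_twilight))

    @property
    def frac_nocturnal(self) -> float:
        return self.n_nocturnal / self.n_total

    @property
    def pct_diurnal(self) -> float:
        """Percentage of events in daylight, rounded half-up to an integer."""
        return float(round_half_up(100.0 * self.n_diurnal / self.n_total))

    @property
    def pct_nocturnal(self) -> float:
        return float(round_half_up(100.0 * self.n_nocturnal / self.n_total))

    @property
    def pct_twilight(self) -> float:
        return float(round_half_up(100.0 * self.n_twilight / self.n_total))

    @property
    def category(self) -> str:
        # Bands on the unrounded nocturnal fraction p_n.  The boundary
        # fractions honour the inclusive "at least 90%" reading on both
        # tails: p_n = 0.10 is still strongly diurnal, 0.90 strongly
        # nocturnal.
        p = self.frac_nocturnal
        if p <= 0.10:
            return "strongly_diurnal"
        if p < 0.30:
            return "mostly_diurnal"
        if p < 0.70:
            return "cathemeral"
        if p < 0.90:
            return "mostly_nocturnal"
        return "strongly_nocturnal"


# ---------------------------------------------------------------------------
# ingest


def read_detections(path) -> pd.DataFrame:
    """Read a detection CSV (site,station,species,datetime,count).

    Rows whose timestamp does not parse are rejected with a logged warning
    rather than silently dropped.
    """
    df = pd.read_csv(path, dtype={"site": str, "station": str, "species": str})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detection file missing columns: {missing}")
    ts = pd.to_datetime(df["datetime"], errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.any():
        log.warning("rejected %d records with unparseable timestamps", int(bad.sum()))
        df = df.loc[~bad]
        ts = ts.loc[~bad]
    df = df.assign(datetime=ts)
    if (df["count"] < 1).any():
        raise ValueError("n_individuals must be >= 1")
    return df.reset_index(drop=True)


def filter_independent_events(records: pd.DataFrame, window_minutes: float = 60.0) -> pd.DataFrame:
    """Greedy forward scan keeping records >= ``window_minutes`` after the
    previous *retained* record of the same (station, species).

    One row per photo means multi-individual photos already collapse to a
    single candidate event, and a two-species photo (two rows) yields one
    candidate per species.  Returns the retained rows, one per independent
    event, sorted by (station, species, datetime).
    """
    if window_minutes < 0:
        raise ValueError("window must be non-negative")
    df = records.sort_values(["station", "species", "datetime"], kind="mergesort")
    if df.empty:
        return df.reset_index(drop=True)
    window = pd.Timedelta(minutes=window_minutes)

    def _scan(group: pd.DataFrame) -> np.ndarray:
        keep = np.zeros(len(group), dtype=bool)
        last = None
        for i, t in enumerate(group["datetime"].to_numpy()):
            if last is None or t - last >= window:
                keep[i] = True
                last = t
        return keep

    mask = np.concatenate(
        [_scan(g) for _, g in df.groupby(["station", "species"], sort=False)]
    )
    return df.loc[mask].reset_index(drop=True)


def event_series(events: pd.DataFrame) -> dict[str, EventSeries]:
    """Split an event table into per-species circular time series."""
    out: dict[str, EventSeries] = {}
    for sp, g in events.groupby("species", sort=True):
        hours = (
            g["datetime"].dt.hour
            + g["datetime"].dt.minute / 60.0
            + g["datetime"].dt.second / 3600.0
        ).to_numpy()
        out[str(sp)] = EventSeries(str(sp), hours_to_radians(hours), g["station"].to_numpy(object))
    return out


def retain_informative_stations(
    events: pd.DataFrame, deployed_stations: Iterable[str] | int | None = None
) -> tuple[list[str], float]:
    """Stations with at least one identifiable event, plus the retention
    percentage (1 decimal) relative to the deployed total.

    ``deployed_stations`` may be the full deployment list or simply its
    size; by default the stations present in ``events`` are assumed to be
    the full deployment.
    """
    kept = sorted(events["station"].dropna().unique().tolist())
    if not kept:
        raise EmptyResultError("no station captured an identifiable species")
    if deployed_stations is None:
        n_deployed = len(kept)
    elif isinstance(deployed_stations, int):
        n_deployed = deployed_stations
    else:
        n_deployed = len(set(deployed_stations))
    if n_deployed < len(kept):
        raise ValueError("more stations kept than deployed")
    fraction = float(round_half_up(100.0 * len(kept) / n_deployed, 1))
    return kept, fraction


def classify_diel(series: EventSeries, solar: SolarSchedule | None = None) -> DielSummary:
    """Tally one species' events into the diel partition."""
    if series.n == 0:
        raise EmptyResultError(f"no events for {series.species}: diel category undefined")
    solar = solar or SolarSchedule()
    hours = series.hours
    day = solar.is_diurnal(hours)
    twi = solar.is_twilight(hours)
    return DielSummary(
        species=series.species,
        n_total=series.n,
        n_diurnal=int(day.sum()),
        n_nocturnal=int((~day).sum()),
        n_twilight=int(twi.sum()),
    )


def diel_summary_table(
    series: Mapping[str, EventSeries], solar: SolarSchedule | None = None
) -> pd.DataFrame:
    rows = []
    for sp in sorted(series):
        s = classify_diel(series[sp], solar)
        rows.append(
            {
                "species": sp,
                "n_total": s.n_total,
                "n_diurnal": s.n_diurnal,
                "n_nocturnal": s.n_nocturnal,
                "n_twilight": s.n_twilight,
                "pct_diurnal": s.pct_diurnal,
                "pct_nocturnal": s.pct_nocturnal,
                "pct_twilight": s.pct_twilight,
                "category": s.category,
            }
        )
    return pd.DataFrame(rows)
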