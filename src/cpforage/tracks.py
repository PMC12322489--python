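"""From raw GPS fixes to the analyzable trip set.

The processing chain mirrors standard colony-based biologging practice:
fixes are subsampled to a common cadence, foraging trips are delineated as
maximal runs of fixes farther than a distance threshold from the colony that
last at least a minimum duration, trips dominated by on-land locations are
discarded, and truncated (battery-failure) trips are retained only when the
bird had already covered most of the return leg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import GeoPoint, StudyArea, classify_trip, haversine_km_vec, points_in_polygon

__all__ = [
    "Trip",
    "Deployment",
    "subsample",
    "delineate_trips",
    "compute_land_fraction",
    "exclude_land_trips",
    "filter_incomplete",
    "trip_metrics",
    "individual_max_range",
    "process_deployments",
    "trips_to_frame",
    "read_fixes_csv",
    "read_deployments_csv",
]

log = logging.getLogger(__name__)


@dataclass
class Deployment:
    """One logger deployment on one bird."""

    bird_id: str
    colony_id: str
    year: int
    capture_time: np.datetime64
    recapture_time: np.datetime64
    fixes: pd.DataFrame  # columns: timestamp, lon, lat (sorted)

    def __post_init__(self):
        if not self.capture_time < self.recapture_time:
            raise ValueError("capture_time must precede recapture_time")


@dataclass
class Trip:
    """A delineated foraging excursion with its summary metrics."""

    bird_id: str
    colony_id: str
    year: int
    t: np.ndarray  # datetime64[ns], strictly increasing
    lon: np.ndarray
    lat: np.ndarray
    complete: bool
    max_range_km: float = np.nan
    duration_h: float = np.nan
    land_fraction: float = np.nan
    label: str = ""
    deployment_id: str = ""
    deployment_start: np.datetime64 = None
    trip_index: int = -1

    def lon_lat_arrays(self):
        return self.lon, self.lat

    @property
    def n_fixes(self) -> int:
        return len(self.t)


def subsample(fixes: pd.DataFrame, interval_min: float = 10.0) -> pd.DataFrame:
    """Greedy forward subsampling to a standard cadence.

    Keeps the first fix, then each subsequent fix whose gap from the last
    *kept* fix is at least ``interval_min`` minutes.  The output is a subset
    of the input in the original order; no positions are interpolated.
    """
    t = fixes["timestamp"].to_numpy()
    if len(t) == 0:
        return fixes
    if np.any(np.diff(t) <= np.timedelta64(0, "s")):
        raise ValueError("fix timestamps must be strictly increasing")
    gap = np.timedelta64(int(round(interval_min * 60)), "s")
    keep = np.zeros(len(t), dtype=bool)
    last = t[0]
    keep[0] = True
    for i in range(1, len(t)):
        if t[i] - last >= gap:
            keep[i] = True
            last = t[i]
    return fixes.iloc[keep].reset_index(drop=True)


def trip_metrics(trip: Trip, colony: GeoPoint) -> tuple:
    """(max range from the colony in km, first-to-last-fix duration in hours)."""
    d = haversine_km_vec(trip.lon, trip.lat, colony.lon, colony.lat)
    max_range = float(np.max(d))
    duration_h = float((trip.t[-1] - trip.t[0]) / np.timedelta64(1, "h"))
    return max_range, duration_h


def delineate_trips(
    fixes: pd.DataFrame,
    colony: GeoPoint,
    *,
    min_dist_km: float = 0.2,
    min_duration_min: float = 50.0,
    bird_id: str = "",
    colony_id: str = "",
    year: int = 0,
    deployment_id: str = "",
    deployment_start=None,
) -> list:
    """Split a (subsampled) fix series into foraging trips.

    A trip is a maximal run of consecutive fixes farther than ``min_dist_km``
    from the colony; it qualifies iff the elapsed time from its first to its
    last fix is at least ``min_duration_min`` minutes.  Colony-attendance
    fixes are not part of trips.  A trip is ``complete`` when the fix
    immediately after the run exists and lies back within ``min_dist_km`` of
    the colony (otherwise the track was truncated mid-trip).
    """
    if len(fixes) == 0:
        return []
    t = fixes["timestamp"].to_numpy()
    lon = fixes["lon"].to_numpy(dtype=float)
    lat = fixes["lat"].to_numpy(dtype=float)
    away = haversine_km_vec(lon, lat, colony.lon, colony.lat) > min_dist_km

    trips = []
    n = len(away)
    i = 0
    idx = 0
    min_dur = np.timedelta64(int(round(min_duration_min * 60)), "s")
    while i < n:
        if not away[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and away[j + 1]:
            j += 1
        if t[j] - t[i] >= min_dur:
            complete = j + 1 < n  # next fix is back at the colony by construction
            trip = Trip(
                bird_id=bird_id,
                colony_id=colony_id,
                year=year,
                t=t[i : j + 1],
                lon=lon[i : j + 1],
                lat=lat[i : j + 1],
                complete=complete,
                deployment_id=deployment_id,
                deployment_start=deployment_start,
                trip_index=idx,
            )
            trip.max_range_km, trip.duration_h = trip_metrics(trip, colony)
            trips.append(trip)
            idx += 1
        i = j + 1
    return trips


def compute_land_fraction(trip: Trip, area: StudyArea) -> float:
    """Fraction of trip fixes falling inside any land polygon."""
    if trip.n_fixes == 0:
        raise ValueError("trip has no fixes")
    if not area.land:
        return 0.0
    on_land = np.zeros(trip.n_fixes, dtype=bool)
    for region in area.land:
        on_land |= points_in_polygon(trip.lon, trip.lat, region)
    return float(np.mean(on_land))


def exclude_land_trips(trips: list, area: StudyArea) -> list:
    """Drop trips with strictly more than 50% of their fixes on land."""
    kept = []
    for trip in trips:
        if np.isnan(trip.land_fraction):
            trip.land_fraction = compute_land_fraction(trip, area)
        if trip.land_fraction <= 0.5:
            kept.append(trip)
    return kept


def filter_incomplete(trips: list, colony_lookup=None, return_fraction: float = 0.75) -> list:
    """Retain complete trips, plus truncated trips whose return leg covered at
    least ``return_fraction`` of the maximum range (final fix within
    ``1 - return_fraction`` of max range from the colony)."""
    kept = []
    for trip in trips:
        if trip.complete:
            kept.append(trip)
            continue
        if colony_lookup is None:
            raise ValueError("colony_lookup is required when incomplete trips are present")
        colony = colony_lookup[trip.colony_id]
        d_last = float(
            haversine_km_vec(trip.lon[-1:], trip.lat[-1:], colony.lon, colony.lat)[0]
        )
        if d_last <= (1.0 - return_fraction) * trip.max_range_km:
            kept.append(trip)
    return kept


def individual_max_range(
    trips: list, first_deployment_only: bool = True, birds=None
) -> pd.DataFrame:
    """One maximum-range value per individual and year.

    The per-individual value is the maximum over all that bird's retained
    trips; when a bird was deployed more than once in a year, only its first
    deployment contributes (avoids pseudo-replication in the bimodality test).
    """
    rows = []
    by_key = {}
    for trip in trips:
        by_key.setdefault((trip.bird_id, trip.year), []).append(trip)
    for (bird, year), group in by_key.items():
        if first_deployment_only:
            first = min(t.deployment_start for t in group)
            group = [t for t in group if t.deployment_start == first]
        rows.append(
            {
                "bird_id": bird,
                "year": year,
                "max_range_km": max(t.max_range_km for t in group),
                "n_trips": len(group),
            }
        )
    if birds is not None:
        missing = set(birds) - {r["bird_id"] for r in rows}
        for b in sorted(missing):
            log.warning("bird %s has no retained trips; excluded from range sample", b)
    return pd.DataFrame(rows, columns=["bird_id", "year", "max_range_km", "n_trips"])


def process_deployments(
    fixes: pd.DataFrame,
    deployments: pd.DataFrame,
    area: StudyArea,
    *,
    interval_min: float = 10.0,
    min_dist_km: float = 0.2,
    min_duration_min: float = 50.0,
    return_fraction: float = 0.75,
) -> tuple:
    """Full segmentation chain for a whole study; returns (trips, counts).

    ``counts`` logs how many trips each filter removed, so analyses can report
    the effect of the land and incomplete-trip rules.
    """
    trips = []
    for k, dep in deployments.reset_index(drop=True).iterrows():
        sub = fixes[fixes["bird_id"] == dep["bird_id"]]
        sub = sub[
            (sub["timestamp"] >= dep["capture_time"])
            & (sub["timestamp"] <= dep["recapture_time"])
        ].sort_values("timestamp")
        sub = subsample(sub.reset_index(drop=True), interval_min)
        colony = area.colonies[dep["colony_id"]]
        dep_id = dep.get("deployment_id", f"{dep['bird_id']}-{k}")
        trips.extend(
            delineate_trips(
                sub,
                colony,
                min_dist_km=min_dist_km,
                min_duration_min=min_duration_min,
                bird_id=dep["bird_id"],
                colony_id=dep["colony_id"],
                year=int(dep["year"]),
                deployment_id=dep_id,
                deployment_start=dep["capture_time"],
            )
        )
    counts = {"delineated": len(trips)}
    trips = exclude_land_trips(trips, area)
    counts["after_land_filter"] = len(trips)
    trips = filter_incomplete(trips, colony_lookup=area.colonies, return_fraction=return_fraction)
    counts["after_incomplete_filter"] = len(trips)
    for trip in trips:
        trip.label = classify_trip(trip, area)
    counts["outside"] = sum(t.label == "outside" for t in trips)
    log.info("segmentation: %s", counts)
    return trips, counts


def trips_to_frame(trips: list) -> pd.DataFrame:
    """Summarise trips as the standard trip table."""
    rows = [
        {
            "bird_id": t.bird_id,
            "colony_id": t.colony_id,
            "year": t.year,
            "deployment_id": t.deployment_id,
            "deployment_start": t.deployment_start,
            "trip_index": t.trip_index,
            "start": t.t[0],
            "end": t.t[-1],
            "n_fixes": t.n_fixes,
            "max_range_km": t.max_range_km,
            "duration_h": t.duration_h,
            "land_fraction": t.land_fraction,
            "complete": t.complete,
            "label": t.label,
        }
        for t in trips
    ]
    return pd.DataFrame(rows)


def read_fixes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return df[["bird_id", "timestamp", "lon", "lat"]]


def read_deployments_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["capture_time", "recapture_time"])
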