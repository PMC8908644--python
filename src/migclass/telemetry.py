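"""Telemetry ingestion, projection, and screening to daily trajectories.

Raw GPS-collar tables (delimited text with an animal id, a timestamp and
either geographic lon/lat or already-planar x/y in km) are read, projected
to a planar coordinate system in kilometres, screened to at most one fix
per calendar day, and cut into 365-day animal-years anchored at a
biologically meaningful start date.  All planar math downstream assumes km
so that net squared displacement is natively in km².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088  # IUGG mean earth radius


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Fix:
    """A single timestamped location.

    Timestamps are timezone-naive local time by convention; ``x``/``y`` are
    planar km (NaN until projected), ``lon``/``lat`` degrees when the source
    was geographic, ``elevation`` metres above sea level (NaN if absent).
    """

    animal_id: str
    timestamp: datetime
    x: float = math.nan
    y: float = math.nan
    lon: float = math.nan
    lat: float = math.nan
    elevation: float = math.nan

    @property
    def has_elevation(self) -> bool:
        return math.isfinite(self.elevation)


@dataclass
class Trajectory:
    """Daily-resolution fix sequence for one animal (post screening)."""

    animal_id: str
    fixes: list[Fix] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def has_elevation(self) -> bool:
        return any(f.has_elevation for f in self.fixes)

    def xy(self) -> np.ndarray:
        return np.array([[f.x, f.y] for f in self.fixes], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "date": [f.timestamp.date().isoformat() for f in self.fixes],
                "x_km": [f.x for f in self.fixes],
                "y_km": [f.y for f in self.fixes],
                "elev_m": [f.elevation for f in self.fixes],
            }
        )


@dataclass
class AnimalYear:
    """One animal's fixes within a half-open 365-day window."""

    animal_id: str
    year_label: int
    start_date: date
    fixes: list[Fix]

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)


@dataclass
class RejectLog:
    """Counts and reasons for rows/windows dropped during screening."""

    records: list[tuple[str, str]] = field(default_factory=list)

    def add(self, item: str, reason: str) -> None:
        self.records.append((item, reason))

    @property
    def n(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# projection: azimuthal equidistant on a spherical earth
# ---------------------------------------------------------------------------

def aeqd_forward(
    lon: np.ndarray, lat: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to azimuthal-equidistant x/y in km.

    Distances from the projection centre are exact great-circle distances;
    azimuths from the centre are preserved.
    """
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    dlam = lam - lam0
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    az = np.arctan2(
        np.sin(dlam) * np.cos(phi),
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam),
    )
    rho = EARTH_RADIUS_KM * c
    return rho * np.sin(az), rho * np.cos(az)


def aeqd_inverse(
    x: np.ndarray, y: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Invert :func:`aeqd_forward`; returns lon/lat in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    rho = np.hypot(x, y)
    c = rho / EARTH_RADIUS_KM
    az = np.arctan2(x, y)
    with np.errstate(invalid="ignore"):
        phi = np.arcsin(np.cos(c) * math.sin(phi0) + np.sin(c) * math.cos(phi0) * np.cos(az))
        lam = lam0 + np.arctan2(
            np.sin(az) * np.sin(c) * math.cos(phi0),
            np.cos(c) - math.sin(phi0) * np.sin(phi),
        )
    # centre point: azimuth undefined, position is the centre itself
    at_centre = rho == 0
    phi = np.where(at_centre, phi0, phi)
    lam = np.where(at_centre, lam0, lam)
    return np.degrees(lam), np.degrees(phi)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (spherical earth)."""
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = (
        np.sin((phi2 - phi1) / 2) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def project_to_planar(
    fixes: Sequence[Fix],
    centre: Optional[tuple[float, float]] = None,
    log: Optional[RejectLog] = None,
) -> tuple[list[Fix], tuple[float, float]]:
    """Populate planar ``x``/``y`` (km) from lon/lat.

    The projection is azimuthal equidistant centred on ``centre``
    (lon, lat); when ``centre`` is None it defaults to the centroid of the
    input coordinates, recorded in the returned tuple so a run is
    reproducible.  Rows with latitude outside [-90, 90] are rejected.
    """
    log = log if log is not None else RejectLog()
    valid = []
    for f in fixes:
        if not (math.isfinite(f.lon) and math.isfinite(f.lat)):
            log.add(f"{f.animal_id}@{f.timestamp}", "missing lon/lat")
        elif not -90.0 <= f.lat <= 90.0:
            log.add(f"{f.animal_id}@{f.timestamp}", f"latitude {f.lat} outside [-90, 90]")
        else:
            valid.append(f)
    if not valid:
        return [], centre if centre is not None else (math.nan, math.nan)
    lon = np.array([f.lon for f in valid])
    lat = np.array([f.lat for f in valid])
    if centre is None:
        centre = (float(lon.mean()), float(lat.mean()))
    x, y = aeqd_forward(lon, lat, centre[0], centre[1])
    return [replace(f, x=float(xi), y=float(yi)) for f, xi, yi in zip(valid, x, y)], centre


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA = {
    "id": "animal_id",
    "timestamp": "timestamp",
    "x": "x_km",
    "y": "y_km",
    "lon": "lon",
    "lat": "lat",
    "elevation": "elev_m",
}


def read_telemetry(
    path,
    schema: Optional[dict] = None,
    sep: str = ",",
    log: Optional[RejectLog] = None,
) -> dict[str, list[Fix]]:
    """Read a delimited telemetry table into fixes grouped by animal.

    ``schema`` maps the logical fields (id, timestamp, and either x/y in km
    or lon/lat in degrees; optional elevation) to column names in the file.
    Malformed rows (unparseable timestamp, non-numeric coordinates) are
    rejected and counted in ``log``; a missing required column raises.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    log = log if log is not None else RejectLog()
    df = pd.read_csv(path, sep=sep, dtype=str)
    for key in ("id", "timestamp"):
        if schema[key] not in df.columns:
            raise KeyError(f"required column {schema[key]!r} (field {key!r}) not in {list(df.columns)}")
    has_xy = schema["x"] in df.columns and schema["y"] in df.columns
    has_ll = schema["lon"] in df.columns and schema["lat"] in df.columns
    if not (has_xy or has_ll):
        raise KeyError("telemetry file needs either planar x/y or geographic lon/lat columns")
    has_elev = schema["elevation"] in df.columns

    out: dict[str, list[Fix]] = {}
    for i, row in df.iterrows():
        ts = pd.to_datetime(row[schema["timestamp"]], errors="coerce")
        if pd.isna(ts):
            log.add(f"row {i}", f"unparseable timestamp {row[schema['timestamp']]!r}")
            continue
        vals = {}
        ok = True
        for key, present in (("x", has_xy), ("y", has_xy), ("lon", has_ll), ("lat", has_ll)):
            if present:
                v = pd.to_numeric(row[schema[key]], errors="coerce")
                if pd.isna(v):
                    log.add(f"row {i}", f"non-numeric {key}")
                    ok = False
                    break
                vals[key] = float(v)
        if not ok:
            continue
        elev = math.nan
        if has_elev:
            e = pd.to_numeric(row[schema["elevation"]], errors="coerce")
            if not pd.isna(e):
                elev = float(e)
        fix = Fix(
            animal_id=str(row[schema["id"]]),
            timestamp=ts.to_pydatetime().replace(tzinfo=None),
            x=vals.get("x", math.nan),
            y=vals.get("y", math.nan),
            lon=vals.get("lon", math.nan),
            lat=vals.get("lat", math.nan),
            elevation=elev,
        )
        out.setdefault(fix.animal_id, []).append(fix)
    for fixes in out.values():
        fixes.sort(key=lambda f: f.timestamp)
    return out


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def screen_to_daily(fixes: Iterable[Fix], animal_id: Optional[str] = None) -> Trajectory:
    """Retain one fix per calendar day: the fix nearest 12:00, ties earlier.

    Days without fixes remain gaps.  Idempotent: already-daily input passes
    through unchanged.  An empty input yields an empty trajectory.
    """
    fixes = sorted(fixes, key=lambda f: f.timestamp)
    if animal_id is None:
        animal_id = fixes[0].animal_id if fixes else ""
    by_day: dict[date, Fix] = {}
    noon = time(12, 0)

    def noon_offset(f: Fix) -> float:
        return abs(
            (f.timestamp - datetime.combine(f.timestamp.date(), noon)).total_seconds()
        )

    for f in fixes:
        d = f.timestamp.date()
        cur = by_day.get(d)
        if cur is None or noon_offset(f) < noon_offset(cur):
            by_day[d] = f  # ties keep the earlier (first seen) fix
    return Trajectory(animal_id, [by_day[d] for d in sorted(by_day)])


def _anchor_on_or_before(d: date, anchor: tuple[int, int]) -> date:
    month, day = anchor
    cand = date(d.year, month, day)
    return cand if cand <= d else date(d.year - 1, month, day)


def split_animal_years(
    traj: Trajectory,
    start_anchor: tuple[int, int],
    min_fixes: int = 180,
    log: Optional[RejectLog] = None,
) -> list[AnimalYear]:
    """Cut a daily trajectory into consecutive half-open 365-day windows.

    Windows are anchored at the (month, day) ``start_anchor`` occurrence on
    or before the first fix and advance by exactly 365 days (leap days fold
    into the day-count index).  Windows with fewer than ``min_fixes`` fixes
    are dropped and logged; no fix lands in two windows.
    """
    log = log if log is not None else RejectLog()
    if not traj.fixes:
        return []
    start = _anchor_on_or_before(traj.fixes[0].timestamp.date(), start_anchor)
    last = traj.fixes[-1].timestamp.date()
    out = []
    while start <= last:
        end = start + timedelta(days=365)
        window = [f for f in traj.fixes if start <= f.timestamp.date() < end]
        if window:
            ay = AnimalYear(traj.animal_id, start.year, start, window)
            if ay.n_fixes >= min_fixes:
                out.append(ay)
            else:
                log.add(
                    f"{traj.animal_id}/{start.isoformat()}",
                    f"only {ay.n_fixes} fixes < min_fixes={min_fixes}",
                )
        start = end
    return out
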