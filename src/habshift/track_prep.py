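"""Track regularisation and movement-parameter extraction.

Raw archival-tag tracks arrive as irregular time-stamped lon/lat series.
Downstream stages need (a) fixes on a fixed 12-h lattice and (b) the
empirical movement parameters — per-step speeds, turning angles, trip
duration and maximum displacement from the colony — that drive the
constrained null-track simulation.

Positions between raw fixes are obtained by great-circle (spherical
linear) interpolation; this is a deliberate, documented stand-in for a
state-space observation model, which addresses geolocation error that
synthetic or pre-filtered tracks do not carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sphere import (great_circle_distance, initial_bearing, signed_turn,
                     slerp, wrap_lon)

__all__ = [
    "Track",
    "MovementSummary",
    "regularize_track",
    "movement_summary",
    "great_circle_distance",
]


@dataclass
class Track:
    """One individual's ordered lon/lat fixes tied to a colony and taxon.

    ``data`` columns: ``timestamp`` (datetime64, strictly increasing),
    ``lon`` in [-180, 180), ``lat`` in [-90, 90].
    """

    individual_id: str
    colony_id: str
    taxon: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True).copy()
        if len(df) < 2:
            raise ValueError("a track needs at least 2 fixes")
        ts = pd.to_datetime(df["timestamp"])
        if ts.duplicated().any():
            raise ValueError("duplicate timestamps in track "
                             f"{self.individual_id!r}")
        if not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        df["timestamp"] = ts
        df["lon"] = wrap_lon(df["lon"].to_numpy(float))
        lat = df["lat"].to_numpy(float)
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude outside [-90, 90]")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def lon(self) -> np.ndarray:
        return self.data["lon"].to_numpy(float)

    @property
    def lat(self) -> np.ndarray:
        return self.data["lat"].to_numpy(float)

    @property
    def timestamps(self) -> pd.Series:
        return self.data["timestamp"]


@dataclass
class MovementSummary:
    """Empirical movement parameters of one regularised track."""

    duration_days: float
    speeds_kmh: np.ndarray          # one per step
    turning_angles_deg: np.ndarray  # one per interior fix; may be empty
    max_distance_km: float
    start: pd.Timestamp
    end: pd.Timestamp
    turning_angles_flagged: bool = field(default=False)


def regularize_track(raw: Track, interval_hours: float = 12.0,
                     max_gap_hours: float = 168.0) -> Track:
    """Resample a track onto an exact ``interval_hours`` lattice anchored at
    the first fix.

    Positions are great-circle interpolated between the bracketing raw
    fixes.  The first and last raw fixes are always preserved (the last one
    even when it falls off the lattice).  Interpolated fixes that fall
    inside a raw gap longer than ``max_gap_hours`` are kept but flagged in
    a boolean ``gap_flag`` column rather than silently fabricated.
    Already-regular tracks are returned unchanged (idempotence).
    """
    df = raw.data
    ts = df["timestamp"]
    t0, t_end = ts.iloc[0], ts.iloc[-1]
    step = pd.Timedelta(hours=interval_hours)

    n_full = int(np.floor((t_end - t0) / step))
    lattice = t0 + step * np.arange(n_full + 1)

    raw_sec = (ts - t0).dt.total_seconds().to_numpy()
    lat_sec = (pd.Series(lattice) - t0).dt.total_seconds().to_numpy()

    already = (len(lattice) == len(ts)
               and np.array_equal(lat_sec, raw_sec))
    out_times = list(lattice)
    if lattice[-1] != t_end:
        out_times.append(t_end)
        lat_sec = np.append(lat_sec, raw_sec[-1])
        already = False

    # bracketing raw interval for each lattice time
    idx = np.searchsorted(raw_sec, lat_sec, side="right") - 1
    idx = np.clip(idx, 0, len(raw_sec) - 2)
    t_lo, t_hi = raw_sec[idx], raw_sec[idx + 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(t_hi > t_lo, (lat_sec - t_lo) / (t_hi - t_lo), 0.0)
    frac = np.clip(frac, 0.0, 1.0)

    lon_r, lat_r = raw.lon, raw.lat
    lon_i, lat_i = slerp(lon_r[idx], lat_r[idx], lon_r[idx + 1], lat_r[idx + 1], frac)

    gap = (t_hi - t_lo) > max_gap_hours * 3600.0
    interior = (frac > 0.0) & (frac < 1.0)
    gap_flag = gap & interior

    # snap exact lattice hits to the raw coordinates to keep identity exact
    exact = np.isin(lat_sec, raw_sec)
    match = np.searchsorted(raw_sec, lat_sec)
    lon_i = np.where(exact, lon_r[np.clip(match, 0, len(lon_r) - 1)], lon_i)
    lat_i = np.where(exact, lat_r[np.clip(match, 0, len(lat_r) - 1)], lat_i)

    if already and not gap_flag.any():
        out = df.copy()
        out["gap_flag"] = False
        return Track(raw.individual_id, raw.colony_id, raw.taxon, out)

    out = pd.DataFrame({"timestamp": out_times, "lon": lon_i, "lat": lat_i,
                        "gap_flag": gap_flag})
    return Track(raw.individual_id, raw.colony_id, raw.taxon, out)


def movement_summary(track: Track, colony_lonlat: tuple[float, float]) -> MovementSummary:
    """Speeds, signed turning angles, duration and maximum colony distance
    of a regularised track.

    Speeds are successive great-circle distances divided by the elapsed
    interval; turning angles are the signed change in initial great-circle
    bearing between successive steps (positive = clockwise).  Tracks with
    fewer than 3 fixes get an empty, flagged turning-angle sample.
    """
    lon, lat = track.lon, track.lat
    ts = track.timestamps
    dt_h = ts.diff().dt.total_seconds().to_numpy()[1:] / 3600.0
    d_km = great_circle_distance(lon[:-1], lat[:-1], lon[1:], lat[1:])
    speeds = d_km / dt_h

    flagged = len(track) < 3
    if flagged:
        turns = np.empty(0)
    else:
        brg = initial_bearing(lon[:-1], lat[:-1], lon[1:], lat[1:])
        turns = np.asarray(signed_turn(brg[:-1], brg[1:]), dtype=float)
        # zero-length steps have undefined bearings; treat as straight ahead
        zero = (d_km[:-1] == 0.0) | (d_km[1:] == 0.0)
        turns[zero] = 0.0

    clon, clat = colony_lonlat
    dist = great_circle_distance(lon, lat, clon, clat)
    duration = (ts.iloc[-1] - ts.iloc[0]).total_seconds() / 86400.0
    return MovementSummary(
        duration_days=duration,
        speeds_kmh=np.asarray(speeds, float),
        turning_angles_deg=turns,
        max_distance_km=float(np.max(dist)),
        start=ts.iloc[0],
        end=ts.iloc[-1],
        turning_angles_flagged=flagged,
    )
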