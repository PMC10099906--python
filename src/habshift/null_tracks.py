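"""Constrained null-track simulation (the case-control background).

For each observed track we simulate ``n`` (default 50) null tracks that
keep the observed dates, fix count, speeds and turning-angle structure
but take a uniformly random initial bearing — a sample of where an
animal with the same movement capacity could have been with no habitat
preference.  Null fixes are constrained to sea cells, equatorward of the
>80% ice-concentration edge, poleward of 30S, and within 5% of the
observed maximum displacement from the start point.

(Speed, turning-angle) pairs are resampled jointly from the observed
track so the within-track autocorrelation of step lengths survives into
the availability sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .sphere import destination, great_circle_distance, initial_bearing
from .track_prep import MovementSummary, Track

__all__ = ["ConstraintSet", "point_allowed", "simulate_null_tracks",
           "tracks_to_frame"]

LAT_EQUATORWARD_LIMIT = -30.0
MAX_DISTANCE_SLACK = 1.05


@dataclass
class ConstraintSet:
    """Geographic constraints on null tracks.

    ``land_mask`` / ``ice_mask``: boolean (lat, lon) grids, True where
    disallowed (land, or ice concentration > 80%).  Points off-grid or
    equatorward of ``lat_limit`` are disallowed.  ``max_distance_km``
    optionally caps displacement from the track start (enforced with 5%
    slack by the simulator, not by :func:`point_allowed`).
    """

    land_mask: xr.DataArray
    ice_mask: xr.DataArray
    lat_limit: float = LAT_EQUATORWARD_LIMIT
    max_distance_km: float | None = None

    def __post_init__(self) -> None:
        if self.land_mask.shape != self.ice_mask.shape:
            raise ValueError("land and ice masks must share the grid")
        self._lats = self.land_mask["lat"].to_numpy().astype(float)
        self._lons = self.land_mask["lon"].to_numpy().astype(float)
        self._blocked = self.land_mask.to_numpy() | self.ice_mask.to_numpy()


def point_allowed(lon, lat, c: ConstraintSet):
    """True where a point is at sea, ice-free (<=80% concentration), and
    poleward of the latitude limit.  Off-grid points are disallowed."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    iy = np.rint(lat - c._lats[0]).astype(int)
    ix = np.rint(lon - c._lons[0]).astype(int)
    inside = ((iy >= 0) & (iy < len(c._lats)) & (ix >= 0) & (ix < len(c._lons)))
    iy_c = np.clip(iy, 0, len(c._lats) - 1)
    ix_c = np.clip(ix, 0, len(c._lons) - 1)
    return inside & (lat <= c.lat_limit) & ~c._blocked[iy_c, ix_c]


def _joint_pairs(summary: MovementSummary) -> np.ndarray:
    """(speed, turn) pairs aligned so each pair describes one step relative
    to the previous one."""
    speeds = summary.speeds_kmh
    turns = summary.turning_angles_deg
    m = min(len(speeds) - 1, len(turns))
    if m <= 0:
        # degenerate 2-fix track: fall back to speed-only resampling
        return np.column_stack([speeds, np.zeros_like(speeds)])
    return np.column_stack([speeds[1:1 + m], turns[:m]])


def simulate_null_tracks(obs: Track, summary: MovementSummary,
                         c: ConstraintSet, n: int = 50,
                         seed: int | None = None,
                         retries_per_step: int = 100) -> list[Track]:
    """Simulate ``n`` constrained null tracks for one observed track.

    Each null track starts at the observed start point, reuses the
    observed timestamps element-wise, draws a uniform random initial
    bearing, and then builds steps by jointly resampling (speed, turn)
    pairs from the observed track.  A step whose end point violates the
    constraints is redrawn up to ``retries_per_step`` times (with heading
    reflected toward the start when the distance cap would be breached);
    when a step exhausts its budget the simulator backtracks one step.
    A track that cannot be completed raises, naming the observed track.
    """
    rng = np.random.default_rng(seed)
    ts = obs.timestamps
    dt_h = ts.diff().dt.total_seconds().to_numpy()[1:] / 3600.0
    n_steps = len(obs) - 1
    start_lon, start_lat = float(obs.lon[0]), float(obs.lat[0])
    if not bool(point_allowed(start_lon, start_lat, c)):
        raise ValueError(f"observed start point of {obs.individual_id!r} "
                         "violates the constraint set")

    pairs = _joint_pairs(summary)
    speeds0 = summary.speeds_kmh
    cap = summary.max_distance_km * MAX_DISTANCE_SLACK \
        if c.max_distance_km is None else c.max_distance_km * MAX_DISTANCE_SLACK

    out: list[Track] = []
    for rep in range(n):
        lons = np.empty(n_steps + 1)
        lats = np.empty(n_steps + 1)
        lons[0], lats[0] = start_lon, start_lat
        headings = np.empty(n_steps)
        step = 0
        budget = np.zeros(n_steps, dtype=int)
        total_backtracks = 0
        while step < n_steps:
            ok = False
            while budget[step] < retries_per_step:
                budget[step] += 1
                if step == 0:
                    hdg = float(rng.uniform(0.0, 360.0))
                    spd = float(speeds0[rng.integers(len(speeds0))])
                else:
                    spd, turn = pairs[rng.integers(len(pairs))]
                    hdg = (headings[step - 1] + float(turn)) % 360.0
                d = float(spd) * dt_h[step]
                lon2, lat2 = destination(lons[step], lats[step], hdg, d)
                if summary.max_distance_km > 0 and float(great_circle_distance(
                        lon2, lat2, start_lon, start_lat)) > cap:
                    # reflect inward: aim back toward the start, keep the turn
                    inward = float(initial_bearing(lons[step], lats[step],
                                                   start_lon, start_lat))
                    jitter = float(turn) if step > 0 else 0.0
                    hdg = (inward + jitter) % 360.0
                    lon2, lat2 = destination(lons[step], lats[step], hdg, d)
                    if float(great_circle_distance(lon2, lat2, start_lon,
                                                   start_lat)) > cap:
                        continue
                if not bool(point_allowed(lon2, lat2, c)):
                    continue
                lons[step + 1], lats[step + 1] = float(lon2), float(lat2)
                headings[step] = hdg
                ok = True
                break
            if ok:
                step += 1
            else:
                budget[step] = 0
                total_backtracks += 1
                if step == 0 or total_backtracks > 20 * n_steps:
                    raise RuntimeError(
                        "null-track simulation failed for observed track "
                        f"{obs.individual_id!r} (replicate {rep + 1})")
                step -= 1

        df = pd.DataFrame({"timestamp": ts.to_numpy(), "lon": lons, "lat": lats})
        out.append(Track(individual_id=obs.individual_id,
                         colony_id=obs.colony_id, taxon=obs.taxon, data=df))
    return out


def tracks_to_frame(observed: Track, nulls: list[Track]) -> pd.DataFrame:
    """Stack one observed track (label 1, replicate 0) with its null tracks
    (label 0, replicate 1..n) in the shared track-table dialect."""
    frames = []
    base = observed.data[["timestamp", "lon", "lat"]].copy()
    base.insert(0, "individual_id", observed.individual_id)
    base.insert(1, "colony_id", observed.colony_id)
    base.insert(2, "taxon", observed.taxon)
    base["label"] = 1
    base["replicate"] = 0
    frames.append(base)
    for i, t in enumerate(nulls, start=1):
        f = t.data[["timestamp", "lon", "lat"]].copy()
        f.insert(0, "individual_id", t.individual_id)
        f.insert(1, "colony_id", t.colony_id)
        f.insert(2, "taxon", t.taxon)
        f["label"] = 0
        f["replicate"] = i
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
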