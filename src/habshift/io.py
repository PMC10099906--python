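"""Plain-text readers/writers for the pipeline's exchange formats.

Tracks travel as CSV with columns ``individual_id, colony_id, taxon,
timestamp, lon, lat`` (ISO-8601 UTC timestamps); null-track tables add
``label`` (1 observed / 0 simulated) and ``replicate`` (0 for observed,
1..n for nulls).  Colonies are CSV ``colony_id, lon, lat, population``.
Gridded layers go through :class:`~habshift.env_match.EnvStack`'s
NetCDF round trip; regions through GeoJSON.
"""

from __future__ import annotations

import pandas as pd

from .synthetic_world import Colony
from .track_prep import Track

TIME_FMT = "%Y-%m-%dT%H:%M:%S"

__all__ = ["write_tracks", "read_tracks", "write_colonies", "read_colonies",
           "frame_to_csv"]


def _track_frame(track: Track) -> pd.DataFrame:
    df = track.data[["timestamp", "lon", "lat"]].copy()
    df.insert(0, "individual_id", track.individual_id)
    df.insert(1, "colony_id", track.colony_id)
    df.insert(2, "taxon", track.taxon)
    return df


def frame_to_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "timestamp" in out:
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(TIME_FMT)
    out.to_csv(path, index=False)


def write_tracks(tracks: list[Track], path) -> None:
    frame_to_csv(pd.concat([_track_frame(t) for t in tracks],
                           ignore_index=True), path)


def read_tracks(path) -> list[Track]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for (ind, col, taxon), grp in df.groupby(
            ["individual_id", "colony_id", "taxon"], sort=False):
        out.append(Track(individual_id=str(ind), colony_id=str(col),
                         taxon=str(taxon),
                         data=grp[["timestamp", "lon", "lat"]]))
    return out


def write_colonies(colonies, path) -> None:
    pd.DataFrame([{"colony_id": c.colony_id, "lon": c.lon, "lat": c.lat,
                   "population": c.population} for c in colonies]
                 ).to_csv(path, index=False)


def read_colonies(path) -> tuple[Colony, ...]:
    df = pd.read_csv(path)
    return tuple(Colony(str(r.colony_id), float(r.lon), float(r.lat),
                        int(r.population)) for r in df.itertuples())
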