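"""Self-contained synthetic Southern-Ocean world with known ground truth.

The generator produces everything the pipeline consumes — gridded
covariates (daily and climatological), land and ice masks, colonies,
habitat-biased tracks, and warmed future climates — from a closed-form
"true" preference function, so every downstream stage can be tested
against a known answer without any external downloads.

The stated world: a 1-degree grid poleward of 30S; SST and SSH decline
linearly poleward (zonal bands) with spatial and daily noise; a winter
(April-September) season; tracks are correlated random walks departing
from and returning to their colony, biased toward cells of higher true
preference; future climates are the current fields uniformly warmed by
a configurable delta-T, with per-representation noise mimicking
inter-model spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from .env_match import EnvStack, bathymetry_gradient, build_climatology
from .sphere import destination, great_circle_distance, initial_bearing
from .track_prep import Track

__all__ = [
    "Colony",
    "PreferenceParams",
    "WorldConfig",
    "SyntheticWorld",
    "make_world",
    "true_preference",
    "simulate_tracks",
    "make_future_climate",
]


@dataclass(frozen=True)
class Colony:
    colony_id: str
    lon: float
    lat: float
    population: int = 10000


@dataclass(frozen=True)
class PreferenceParams:
    """Gaussian niche: optimum and tolerance in SST (degC) and SSH (m)."""

    mu_sst: float = 8.0
    sigma_sst: float = 1.0
    mu_ssh: float = 0.22
    sigma_ssh: float = 0.30

    def __post_init__(self) -> None:
        if self.sigma_sst <= 0 or self.sigma_ssh <= 0:
            raise ValueError("preference tolerances must be positive")


def _default_colonies() -> tuple[Colony, ...]:
    # two "islands" inside the preferred band (SST optimum sits near 54S
    # with the default 0.5 degC/deg gradient)
    return (Colony("col_A", 20.5, -52.5, 30000),
            Colony("col_B", 60.5, -53.5, 10000))


@dataclass
class WorldConfig:
    """Complete description of the synthetic world.

    The grid extent must lie poleward of 30S; a fixed seed gives
    bit-identical worlds.  Gradients are signed so that SST/SSH decrease
    toward the pole (value at 30S plus gradient * (lat + 30)).
    """

    lon_min: float = 0.0
    lon_max: float = 90.0
    lat_min: float = -68.0
    lat_max: float = -35.0
    year: int = 2019                      # season runs Apr 1 - Sep 30
    sst_at_30s: float = 20.0
    sst_gradient: float = 0.5             # degC per degree latitude
    ssh_at_30s: float = 0.7
    ssh_gradient: float = 0.02            # m per degree latitude
    noise_sst: float = 0.3                # static spatial noise sd, degC
    noise_ssh: float = 0.02
    daily_noise_sst: float = 0.2          # day-to-day noise sd, degC
    daily_noise_ssh: float = 0.01
    land_fraction: float = 0.05
    ice_edge_lat: float = -58.0           # 0% ice here, ramping poleward
    ice_ramp: float = 20.0                # % per degree latitude
    colonies: tuple[Colony, ...] = field(default_factory=_default_colonies)
    preference: PreferenceParams = field(default_factory=PreferenceParams)
    taxon: str = "synthetic_eudyptes"
    n_individuals: int = 12
    trip_days: float = 120.0
    mean_speed_kmh: float = 5.0
    turn_concentration: float = 1.0       # von Mises kappa of the candidate-heading fan
    habitat_bias: float = 15.0            # softmax weight on destination preference
    delta_t: float = 1.0                  # future warming, degC
    n_representations: int = 4
    rep_noise_sd: float = 0.1             # per-representation SST noise, degC
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lat_max > -30.0:
            raise ValueError("world extent must lie poleward of 30S "
                             f"(lat_max={self.lat_max})")
        if self.lat_min >= self.lat_max or self.lon_min >= self.lon_max:
            raise ValueError("degenerate grid extent")

    @property
    def lats(self) -> np.ndarray:
        return np.arange(self.lat_min + 0.5, self.lat_max, 1.0)

    @property
    def lons(self) -> np.ndarray:
        return np.arange(self.lon_min + 0.5, self.lon_max, 1.0)

    @property
    def season(self) -> pd.DatetimeIndex:
        return pd.date_range(f"{self.year}-04-01", f"{self.year}-09-30", freq="D")


@dataclass
class SyntheticWorld:
    config: WorldConfig
    daily: EnvStack
    clim: EnvStack
    future: dict[str, EnvStack]
    land_mask: xr.DataArray
    ice_mask: xr.DataArray
    colonies: tuple[Colony, ...]
    true_pref: xr.DataArray

    def true_preferred_mask(self, q: float = 90.0) -> xr.DataArray:
        """Ground-truth current preferred habitat: top (100-q)% of the
        true-preference surface over sea cells."""
        return _threshold_mask(self.true_pref, q)


def true_preference(covariates, params: PreferenceParams):
    """Closed-form habitat preference, a product of Gaussian responses:

    p = exp(-(SST-mu_T)^2 / 2 sigma_T^2) * exp(-(SSH-mu_H)^2 / 2 sigma_H^2)

    ``covariates`` is any mapping with ``sst`` and ``ssh`` entries (dict,
    xarray Dataset, DataFrame row ...).  Values lie in [0, 1] with the
    peak 1.0 at (mu_T, mu_H), symmetric about the optimum.
    """
    if "sst" not in covariates:
        raise KeyError("missing covariate: sst")
    ssh_key = "ssh" if "ssh" in covariates else "sea_surface_height"
    if ssh_key not in covariates:
        raise KeyError("missing covariate: ssh")
    sst = np.asarray(covariates["sst"], dtype=float)
    ssh = np.asarray(covariates[ssh_key], dtype=float)
    return (np.exp(-((sst - params.mu_sst) ** 2) / (2.0 * params.sigma_sst ** 2))
            * np.exp(-((ssh - params.mu_ssh) ** 2) / (2.0 * params.sigma_ssh ** 2)))


def _threshold_mask(pref: xr.DataArray, q: float) -> xr.DataArray:
    vals = pref.to_numpy()
    thr = np.nanpercentile(vals, q)
    return xr.DataArray((vals > thr) & np.isfinite(vals),
                        coords=pref.coords, dims=pref.dims)


def make_world(config: WorldConfig) -> SyntheticWorld:
    """Build the synthetic world deterministically from ``config.seed``."""
    for col in config.colonies:
        if not (config.lon_min <= col.lon <= config.lon_max
                and config.lat_min <= col.lat <= config.lat_max):
            raise ValueError(f"colony {col.colony_id!r} lies outside the "
                             "grid extent")
    rng = np.random.default_rng(config.seed)
    lats, lons = config.lats, config.lons
    ny, nx = len(lats), len(lons)
    lat2d = lats[:, None] * np.ones((1, nx))

    sst_base = config.sst_at_30s + config.sst_gradient * (lat2d + 30.0)
    sst_base = sst_base + rng.normal(0.0, config.noise_sst, (ny, nx)) \
        if config.noise_sst > 0 else sst_base
    ssh_base = config.ssh_at_30s + config.ssh_gradient * (lat2d + 30.0)
    ssh_base = ssh_base + rng.normal(0.0, config.noise_ssh, (ny, nx)) \
        if config.noise_ssh > 0 else ssh_base

    ssh_anom = rng.normal(0.0, 0.05, (ny, nx))
    chl = np.exp(rng.normal(np.log(0.3), 0.5, (ny, nx)))
    eke = np.exp(rng.normal(np.log(80.0), 0.6, (ny, nx)))
    mld = np.clip(80.0 - 0.8 * (lat2d + 50.0) + rng.normal(0, 10, (ny, nx)),
                  5.0, None)

    rough = ndimage.gaussian_filter(rng.normal(0, 1, (ny, nx)), sigma=2.0)
    rough = (rough - rough.mean()) / (rough.std() or 1.0)
    bathy = -4000.0 + 900.0 * rough

    # land: the highest cells of the smoothed relief, colonies kept at sea
    land = np.zeros((ny, nx), dtype=bool)
    if config.land_fraction > 0:
        thr = np.quantile(rough, 1.0 - config.land_fraction)
        land = rough > thr
    for col in config.colonies:
        iy, ix = _cell_index(lons, lats, col.lon, col.lat)
        # keep a 3x3 sea neighbourhood so every colony has sea access
        land[max(iy - 1, 0):iy + 2, max(ix - 1, 0):ix + 2] = False
    bathy = np.where(land, 200.0, bathy)

    ice = np.clip((config.ice_edge_lat - lat2d) * config.ice_ramp, 0.0, 100.0)

    coords = {"lat": lats, "lon": lons}
    statics = {
        "bathymetry": bathy,
        "ice_concentration": ice,
    }
    dyn_base = {
        "sst": sst_base, "sea_surface_height": ssh_base, "ssh_anomaly": ssh_anom,
        "chlorophyll_a": chl, "eddy_kinetic_energy": eke, "mixed_layer_depth": mld,
    }
    daily_sd = {
        "sst": config.daily_noise_sst, "sea_surface_height": config.daily_noise_ssh,
        "ssh_anomaly": 0.01, "chlorophyll_a": 0.02,
        "eddy_kinetic_energy": 5.0, "mixed_layer_depth": 2.0,
    }

    season = config.season
    nt = len(season)
    data = {}
    for name, base in dyn_base.items():
        sd = daily_sd[name]
        noise = rng.normal(0.0, sd, (nt, 1, 1)) if sd > 0 else np.zeros((nt, 1, 1))
        cube = base[None, :, :] + noise
        if name in ("chlorophyll_a", "eddy_kinetic_energy", "mixed_layer_depth"):
            cube = np.clip(cube, 1e-6, None)
        data[name] = (("time", "lat", "lon"), cube)
    for name, arr in statics.items():
        data[name] = (("time", "lat", "lon"), np.broadcast_to(
            arr[None, :, :], (nt, ny, nx)).copy())

    ds = xr.Dataset(data, coords={"time": season, **coords})
    grad = bathymetry_gradient(ds["bathymetry"].isel(time=0, drop=True))
    ds["bathymetry_gradient"] = (("time", "lat", "lon"), np.broadcast_to(
        grad.to_numpy()[None, :, :], (nt, ny, nx)).copy())

    land_da = xr.DataArray(land, coords=coords, dims=("lat", "lon"))
    ds = ds.where(~land_da)
    # ice concentration is defined (0/100) everywhere at sea; keep land NaN
    daily = EnvStack(ds)
    clim = build_climatology(daily)

    pref = true_preference(clim.ds, config.preference)
    true_pref = xr.DataArray(np.asarray(pref), coords=coords, dims=("lat", "lon"))

    ice_mask = xr.DataArray((ice > 80.0) & ~land, coords=coords, dims=("lat", "lon"))

    future = {}
    for i in range(config.n_representations):
        fut, _, _ = make_future_climate_fields(
            clim, config.preference, config.delta_t,
            rep_noise_sd=config.rep_noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)))
        future[f"rep{i + 1}"] = fut

    return SyntheticWorld(config=config, daily=daily, clim=clim, future=future,
                          land_mask=land_da, ice_mask=ice_mask,
                          colonies=tuple(config.colonies), true_pref=true_pref)


def make_future_climate_fields(clim: EnvStack, params: PreferenceParams,
                               delta_t: float, rep_noise_sd: float = 0.0,
                               seed: int = 0, q: float = 90.0,
                               ) -> tuple[EnvStack, xr.DataArray, xr.DataArray]:
    """Warm a climatology by ``delta_t`` degC (SST only, plus optional
    per-representation noise) and derive the ground-truth future
    preference surface and its top-(100-q)% preferred mask."""
    if delta_t < 0:
        raise ValueError("delta_t must be >= 0")
    rng = np.random.default_rng(seed)
    ds = clim.ds.copy(deep=True)
    noise = (rng.normal(0.0, rep_noise_sd, ds["sst"].shape)
             if rep_noise_sd > 0 else 0.0)
    ds["sst"] = ds["sst"] + delta_t + noise
    fut = EnvStack(ds)
    pref = true_preference(ds, params)
    pref_da = xr.DataArray(np.asarray(pref), coords=ds["sst"].coords,
                           dims=ds["sst"].dims)
    return fut, pref_da, _threshold_mask(pref_da, q)


def make_future_climate(world: SyntheticWorld, delta_t: float,
                        rep_noise_sd: float = 0.0, seed: int = 0,
                        q: float = 90.0) -> tuple[EnvStack, xr.DataArray]:
    """Future climatology for the world plus the ground-truth future
    preferred mask (see :func:`make_future_climate_fields`)."""
    fut, _, mask = make_future_climate_fields(
        world.clim, world.config.preference, delta_t,
        rep_noise_sd=rep_noise_sd, seed=seed, q=q)
    return fut, mask


def _cell_index(lons: np.ndarray, lats: np.ndarray, lon: float, lat: float):
    return (int(np.argmin(np.abs(lats - lat))), int(np.argmin(np.abs(lons - lon))))


def _make_lookup(world: SyntheticWorld):
    """Fast nearest-cell lookup of (true preference, allowed) on the grid."""
    lats, lons = world.config.lats, world.config.lons
    pref = np.nan_to_num(world.true_pref.to_numpy(), nan=0.0)
    allowed = (~world.land_mask.to_numpy()) & (~world.ice_mask.to_numpy())
    lat0, lon0 = lats[0], lons[0]

    def lookup(lon, lat):
        iy = np.rint(np.asarray(lat) - lat0).astype(int)
        ix = np.rint(np.asarray(lon) - lon0).astype(int)
        inside = ((iy >= 0) & (iy < len(lats)) & (ix >= 0) & (ix < len(lons))
                  & (np.asarray(lat) <= -30.0))
        iy_c, ix_c = np.clip(iy, 0, len(lats) - 1), np.clip(ix, 0, len(lons) - 1)
        ok = inside & allowed[iy_c, ix_c]
        return np.where(ok, pref[iy_c, ix_c], 0.0), ok

    return lookup


def simulate_tracks(world: SyntheticWorld, n: int | None = None,
                    seed: int | None = None) -> list[Track]:
    """Habitat-biased correlated random walks from and back to the colony.

    Every 12 h the walker draws a speed around the configured mean and a
    fan of candidate headings around its previous heading (von Mises
    turns); a destination is chosen by softmax over the true preference of
    the candidate cells, with land/ice/30S-disallowed candidates excluded.
    Over the final 20% of the trip the heading fan is re-centred on the
    bearing to the colony and speed is boosted when needed so that the walk
    closes the loop; the final fix is placed within one grid cell of the
    colony.  Raises after bounded retries if a colony is walled in.
    """
    cfg = world.config
    n = cfg.n_individuals if n is None else n
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    lookup = _make_lookup(world)
    n_steps = int(round(cfg.trip_days * 2))
    shape = 4.0  # gamma shape of step speeds

    tracks: list[Track] = []
    for i in range(n):
        col = world.colonies[i % len(world.colonies)]
        start_day = int(rng.integers(0, max(1, len(cfg.season) - int(cfg.trip_days) - 1)))
        t0 = cfg.season[start_day]
        times = pd.date_range(t0, periods=n_steps + 1, freq="12h")

        lon, lat = float(col.lon), float(col.lat)
        heading = float(rng.uniform(0.0, 360.0))
        lons_out, lats_out = [lon], [lat]
        return_from = int(np.ceil(0.8 * n_steps))
        for step in range(n_steps):
            speed = float(rng.gamma(shape, cfg.mean_speed_kmh / shape))
            returning = step >= return_from
            if returning:
                center = float(initial_bearing(lon, lat, col.lon, col.lat))
                kappa = 10.0
                rem_h = (n_steps - step) * 12.0
                rem_d = float(great_circle_distance(lon, lat, col.lon, col.lat))
                speed = max(speed, 1.15 * rem_d / rem_h)
                # do not overshoot the colony on the way in
                dist = min(speed * 12.0, max(rem_d, 1.0))
            else:
                center, kappa = heading, cfg.turn_concentration
                dist = speed * 12.0
            placed = False
            for _ in range(50):
                cand = center + np.degrees(rng.vonmises(0.0, kappa, size=15))
                clon, clat = destination(lon, lat, cand, dist)
                p, ok = lookup(clon, clat)
                if not ok.any():
                    dist *= 0.7  # shrink the step and retry
                    continue
                w = np.where(ok, np.exp(cfg.habitat_bias * p), 0.0)
                j = int(rng.choice(len(cand), p=w / w.sum()))
                heading = float(cand[j] % 360.0)
                lon, lat = float(clon[j]), float(clat[j])
                placed = True
                break
            if not placed:
                if step == 0:
                    raise RuntimeError(
                        f"track simulation stuck at colony {col.colony_id}: "
                        "no allowed destination after bounded retries")
                # walled-in corner: loiter at the current (valid) position
            lons_out.append(lon)
            lats_out.append(lat)
        # close the loop: final fix within one grid cell of the colony,
        # redrawn until it lands on an allowed cell
        for _ in range(100):
            end_lon, end_lat = destination(col.lon, col.lat,
                                           float(rng.uniform(0, 360)),
                                           float(rng.uniform(0, 40)))
            if bool(lookup(end_lon, end_lat)[1]):
                break
        else:
            end_lon, end_lat = col.lon, col.lat
        lons_out[-1], lats_out[-1] = float(end_lon), float(end_lat)

        tracks.append(Track(
            individual_id=f"sim_{i:03d}", colony_id=col.colony_id,
            taxon=cfg.taxon,
            data=pd.DataFrame({"timestamp": times, "lon": lons_out,
                               "lat": lats_out})))
    return tracks
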