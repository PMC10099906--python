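"""Environmental covariate stacks: matching, derivation, climatology.

The covariate vocabulary is fixed (units in brackets): sea_surface_height
[m], ssh_anomaly [m], bathymetry [m, negative below sea level],
bathymetry_gradient [degrees of slope], sst [degC], chlorophyll_a
[mg m-3], eddy_kinetic_energy [cm2 s-2], mixed_layer_depth [m],
ice_concentration [%].  Stacks live on a shared 1-degree, cell-centre
registered lon/lat grid, either as daily slices or a single climatology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .sphere import EARTH_RADIUS_KM

COVARIATE_NAMES = (
    "sea_surface_height",
    "ssh_anomaly",
    "bathymetry",
    "bathymetry_gradient",
    "sst",
    "chlorophyll_a",
    "eddy_kinetic_energy",
    "mixed_layer_depth",
    "ice_concentration",
)

#: covariates offered to the preference model (ice only constrains tracks)
MODEL_COVARIATES = tuple(n for n in COVARIATE_NAMES if n != "ice_concentration")

METERS_PER_DEGREE = EARTH_RADIUS_KM * 1000.0 * np.pi / 180.0

__all__ = [
    "COVARIATE_NAMES",
    "MODEL_COVARIATES",
    "EnvStack",
    "extract_covariates",
    "bathymetry_gradient",
    "build_climatology",
]


@dataclass
class EnvStack:
    """Named covariate layers on a shared grid (thin xarray wrapper).

    ``ds`` dims: (lat, lon) or (time, lat, lon); every variable name must
    come from :data:`COVARIATE_NAMES`.
    """

    ds: xr.Dataset

    def __post_init__(self) -> None:
        unknown = set(self.ds.data_vars) - set(COVARIATE_NAMES)
        if unknown:
            raise ValueError(f"unknown covariate layers: {sorted(unknown)}")
        if "lat" not in self.ds.coords or "lon" not in self.ds.coords:
            raise ValueError("EnvStack requires lat/lon coordinates")
        if "ice_concentration" in self.ds:
            ice = self.ds["ice_concentration"]
            if float(ice.min(skipna=True)) < 0 or float(ice.max(skipna=True)) > 100:
                raise ValueError("ice_concentration must lie in [0, 100]")

    @property
    def lats(self) -> np.ndarray:
        return self.ds["lat"].to_numpy()

    @property
    def lons(self) -> np.ndarray:
        return self.ds["lon"].to_numpy()

    @property
    def layers(self) -> tuple[str, ...]:
        return tuple(self.ds.data_vars)

    @property
    def has_time(self) -> bool:
        return "time" in self.ds.dims

    def to_netcdf(self, path) -> None:
        self.ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EnvStack":
        return cls(xr.load_dataset(path, engine="scipy"))


#: canonical column order of a case-control table (before covariates)
CASE_CONTROL_ID_COLS = ("individual_id", "colony_id", "taxon", "label",
                        "replicate", "timestamp", "lon", "lat")


def extract_covariates(points: pd.DataFrame, stack: EnvStack,
                       covariates: tuple[str, ...] | None = None,
                       ) -> tuple[pd.DataFrame, dict]:
    """Attach covariates to points by nearest-cell (and, for daily stacks,
    same-day) lookup — a pure lookup, no interpolation.

    ``points`` needs ``lon``, ``lat`` and (for daily stacks) ``timestamp``
    columns; any identifier columns are carried through.  Rows left with a
    missing covariate (e.g. over land) are dropped listwise; the returned
    report counts drops per covariate and in total.

    Raises ``ValueError`` listing offending dates when any point falls
    outside the stack's time range.
    """
    covariates = tuple(covariates or stack.layers)
    missing_layers = set(covariates) - set(stack.layers)
    if missing_layers:
        raise KeyError(f"covariate layer(s) missing from stack: {sorted(missing_layers)}")

    pts = points.reset_index(drop=True)
    lon_idx = xr.DataArray(pts["lon"].to_numpy(float), dims="points")
    lat_idx = xr.DataArray(pts["lat"].to_numpy(float), dims="points")
    sel = {"lon": lon_idx, "lat": lat_idx}
    if stack.has_time:
        days = pd.to_datetime(pts["timestamp"]).dt.floor("D")
        tmin = pd.Timestamp(stack.ds["time"].min().item())
        tmax = pd.Timestamp(stack.ds["time"].max().item())
        bad = sorted({str(d.date()) for d in days[(days < tmin) | (days > tmax)]})
        if bad:
            raise ValueError(f"point dates outside stack time range: {bad}")
        sel["time"] = xr.DataArray(days.to_numpy(), dims="points")

    sub = stack.ds[list(covariates)].sel(**sel, method="nearest")
    cov = pd.DataFrame({name: sub[name].to_numpy() for name in covariates})

    out = pd.concat([pts, cov], axis=1)
    isna = cov.isna()
    keep = ~isna.any(axis=1)
    report = {
        "n_points": int(len(pts)),
        "n_kept": int(keep.sum()),
        "n_dropped": int((~keep).sum()),
        "dropped_per_covariate": {c: int(isna[c].sum()) for c in covariates},
    }
    return out.loc[keep].reset_index(drop=True), report


def bathymetry_gradient(bathy: xr.DataArray) -> xr.DataArray:
    """Seafloor slope in degrees: arctan of the magnitude of the horizontal
    depth gradient.

    Central differences (one-sided at edges); the zonal spacing is scaled
    by cos(latitude) to convert degrees of longitude to metres.  Invariant
    to adding a constant to the depth field.
    """
    lats = bathy["lat"].to_numpy().astype(float)
    lons = bathy["lon"].to_numpy().astype(float)
    z = bathy.to_numpy().astype(float)
    dy = np.gradient(z, lats, axis=-2) / METERS_PER_DEGREE
    coslat = np.cos(np.radians(lats))[..., :, None]
    dx = np.gradient(z, lons, axis=-1) / (METERS_PER_DEGREE * coslat)
    slope = np.degrees(np.arctan(np.hypot(dx, dy)))
    return xr.DataArray(slope, coords=bathy.coords, dims=bathy.dims,
                        name="bathymetry_gradient")


def build_climatology(stack: EnvStack, months: tuple[int, ...] = (4, 5, 6, 7, 8, 9),
                      years: tuple[int, ...] | None = None) -> EnvStack:
    """Per-cell arithmetic mean over daily slices in the requested months
    (default April-September) and years.

    Missing values are excluded from the mean; cells missing on every
    qualifying date stay missing.  Raises if no date qualifies.
    """
    if not stack.has_time:
        raise ValueError("stack has no time axis; already a climatology?")
    t = stack.ds["time"]
    sel = t.dt.month.isin(list(months))
    if years is not None:
        sel = sel & t.dt.year.isin(list(years))
    if int(sel.sum()) == 0:
        raise ValueError("no dates match the requested months/years")
    clim = stack.ds.sel(time=sel).mean("time", skipna=True)
    return EnvStack(clim)
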