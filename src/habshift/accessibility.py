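"""Colony accessibility: a monotone decreasing function of distance.

Central-place foragers must return to the colony, so the probability
that a cell can be visited declines with its distance from the colony.
We convert observed + null fixes into a per-cell binary visited/not
response, bin it by great-circle distance to the colony, fit a
decreasing isotonic regression to the bin rates (weighted by bin
occupancy) and smooth the result with a shape-preserving monotone
(PCHIP) spline.  The curve multiplies the habitat-preference surface so
preferred-but-unreachable cells are down-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

from .sphere import great_circle_distance

__all__ = ["AccessibilityCurve", "build_access_response",
           "fit_accessibility", "combine_preference_accessibility",
           "distance_grid_to_colony"]


@dataclass
class AccessibilityCurve:
    """Fitted P(visited | distance) for one colony; non-increasing,
    clipped to [0, 1]; evaluation beyond the fitted range holds the last
    value."""

    colony_id: str
    distance_km: np.ndarray
    probability: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.probability, float)
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError("accessibility probabilities must lie in [0, 1]")
        if np.any(np.diff(p) > 1e-9):
            raise ValueError("accessibility curve must be non-increasing")

    def __call__(self, distance_km) -> np.ndarray:
        return np.interp(np.asarray(distance_km, float),
                         self.distance_km, self.probability)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_km": self.distance_km,
                             "probability": self.probability})


def distance_grid_to_colony(lons: np.ndarray, lats: np.ndarray,
                            colony_lon: float, colony_lat: float) -> xr.DataArray:
    """Great-circle distance (km) from every cell centre to the colony."""
    lon2, lat2 = np.meshgrid(lons, lats)
    d = great_circle_distance(lon2, lat2, colony_lon, colony_lat)
    return xr.DataArray(d, coords={"lat": lats, "lon": lons},
                        dims=("lat", "lon"))


def build_access_response(fixes: pd.DataFrame, lons: np.ndarray,
                          lats: np.ndarray, colony_lon: float,
                          colony_lat: float,
                          sea_mask: xr.DataArray | None = None,
                          ) -> pd.DataFrame:
    """Per-cell binary response: 1 if any observed or simulated fix falls
    in the cell, else 0, paired with the cell-to-colony distance.

    ``fixes`` needs ``lon``/``lat`` columns (observed and null pooled).
    ``sea_mask`` (True = sea) restricts the response to sea cells.
    """
    lon_edges = np.concatenate([lons - 0.5, [lons[-1] + 0.5]])
    lat_edges = np.concatenate([lats - 0.5, [lats[-1] + 0.5]])
    counts, _, _ = np.histogram2d(fixes["lat"].to_numpy(float),
                                  fixes["lon"].to_numpy(float),
                                  bins=[lat_edges, lon_edges])
    visited = counts > 0
    dist = distance_grid_to_colony(lons, lats, colony_lon, colony_lat)
    lat2, lon2 = np.meshgrid(lats, lons, indexing="ij")
    df = pd.DataFrame({
        "lon": lon2.ravel(), "lat": lat2.ravel(),
        "visited": visited.ravel().astype(int),
        "distance_km": dist.to_numpy().ravel(),
    })
    if sea_mask is not None:
        df = df[sea_mask.to_numpy().ravel()].reset_index(drop=True)
    return df


def fit_accessibility(response: np.ndarray, distances: np.ndarray,
                      colony_id: str = "", bin_km: float = 50.0,
                      distance_grid: np.ndarray | None = None,
                      ) -> AccessibilityCurve:
    """Monotone decreasing fit of P(visited | distance).

    Distances are binned (default 50 km), per-bin visit rates are fit by
    decreasing isotonic regression weighted by bin counts, and the step
    output is smoothed through the bin centres with a monotone PCHIP
    spline, then clipped to [0, 1].  A degenerate single-class response
    yields a flat curve at the class value, flagged in ``meta``.
    """
    response = np.asarray(response, float)
    distances = np.asarray(distances, float)
    if distance_grid is None:
        distance_grid = np.arange(0.0, distances.max() + bin_km, bin_km / 2.0)
    distance_grid = np.asarray(distance_grid, float)

    classes = np.unique(response)
    if len(classes) < 2:
        flat = float(classes[0])
        return AccessibilityCurve(colony_id, distance_grid,
                                  np.full_like(distance_grid, flat),
                                  meta={"degenerate": True, "bin_km": bin_km})

    edges = np.arange(0.0, distances.max() + bin_km, bin_km)
    idx = np.clip(np.digitize(distances, edges) - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=response, minlength=n_bins)
    occupied = counts > 0
    centers = (edges[:-1] + edges[1:]) / 2.0
    rate = sums[occupied] / counts[occupied]

    iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
    fitted = iso.fit_transform(centers[occupied], rate,
                               sample_weight=counts[occupied])

    x = np.concatenate([[0.0], centers[occupied]])
    yv = np.concatenate([[fitted[0]], fitted])
    x, keep = np.unique(x, return_index=True)
    yv = yv[keep]
    if len(x) >= 2:
        spline = PchipInterpolator(x, yv, extrapolate=False)
        prob = spline(np.clip(distance_grid, x[0], x[-1]))
    else:
        prob = np.full_like(distance_grid, yv[0])
    prob = np.clip(prob, 0.0, 1.0)
    prob = np.minimum.accumulate(prob)  # guard against numerical wiggles
    return AccessibilityCurve(colony_id, distance_grid, prob,
                              meta={"degenerate": False, "bin_km": bin_km,
                                    "n_bins": int(occupied.sum())})


def combine_preference_accessibility(pref: xr.DataArray,
                                     curves: dict[str, AccessibilityCurve],
                                     colonies,
                                     weights: dict[str, float] | None = None,
                                     ) -> xr.DataArray:
    """Combine a preference surface with per-colony accessibility.

    Per colony, combined = preference * accessibility(distance-to-colony).
    Unweighted mode (default) takes the cell-wise maximum over colonies —
    a cell counts as usable if birds from *any* colony can reach it — and
    stays in [0, 1], never exceeding the preference.  Weighted mode takes
    the colony-size-weighted mean instead, giving a relative density
    index.  Raises if a colony lacks a curve.
    """
    lats = pref["lat"].to_numpy().astype(float)
    lons = pref["lon"].to_numpy().astype(float)
    per_colony = []
    wts = []
    for col in colonies:
        if col.colony_id not in curves:
            raise KeyError(f"no accessibility curve for colony {col.colony_id!r}")
        dist = distance_grid_to_colony(lons, lats, col.lon, col.lat)
        access = curves[col.colony_id](dist.to_numpy())
        per_colony.append(pref.to_numpy() * access)
        if weights is not None:
            wts.append(float(weights[col.colony_id]))
    stack = np.stack(per_colony)
    if weights is None:
        # plain max so NaN (masked) cells stay NaN
        combined = np.max(stack, axis=0)
    else:
        w = np.asarray(wts, float)
        combined = np.tensordot(w, stack, axes=1) / w.sum()
    return xr.DataArray(combined, coords=pref.coords, dims=pref.dims)
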