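"""Ocean-wide prediction and percentile importance scores.

Raw preference predictions are relative, not absolute, so they are not
comparable across taxa.  Transforming each map by percentile yields a
habitat importance score from 0 (not important) to 100 (extremely
important) whose distribution is uniform by construction, making maps
directly comparable.  The "preferred habitat" used for projection is the
top decile of that score by default.
"""

from __future__ import annotations

import numpy as np
import xarray as xr
from scipy.stats import rankdata

from .env_match import EnvStack
from .habitat_pref import HabitatModelFit

__all__ = ["predict_surface", "percentile_transform", "top_percentile_mask"]


def predict_surface(fit: HabitatModelFit, clim: EnvStack,
                    access: xr.DataArray | None = None) -> xr.DataArray:
    """Predict relative preference on every non-missing climatology cell.

    ``access`` (optional) is a combined accessibility surface on the same
    grid; predictions are multiplied by it cell-wise.  Cells with any
    missing covariate (land/ice-masked) stay missing.  Raises ``KeyError``
    naming any model covariate absent from the climatology.
    """
    missing = [f for f in fit.features if f not in clim.layers]
    if missing:
        raise KeyError(f"climatology lacks model covariate(s): {missing}")
    shape = clim.ds[fit.features[0]].shape
    cols = [clim.ds[f].to_numpy().ravel() for f in fit.features]
    X = np.column_stack(cols)
    ok = np.isfinite(X).all(axis=1)
    out = np.full(X.shape[0], np.nan)
    if ok.any():
        out[ok] = fit.model.predict_proba(X[ok])[:, 1]
    surf = xr.DataArray(out.reshape(shape),
                        coords=clim.ds[fit.features[0]].coords,
                        dims=clim.ds[fit.features[0]].dims)
    if access is not None:
        surf = surf * access
    return surf


def percentile_transform(surface: xr.DataArray) -> xr.DataArray:
    """Percentile importance score 0-100: 100 * mean-rank / n over
    non-missing cells.  Order-preserving; ties share their mean rank; a
    strictly monotone rescaling of the input leaves the scores unchanged."""
    vals = surface.to_numpy().astype(float)
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError("surface has no non-missing cells")
    scores = np.full(vals.shape, np.nan)
    r = rankdata(vals[ok], method="average")
    scores[ok] = 100.0 * r / ok.sum()
    return xr.DataArray(scores, coords=surface.coords, dims=surface.dims)


def top_percentile_mask(importance: xr.DataArray, q: float = 90.0) -> xr.DataArray:
    """Binary preferred-habitat mask: cells whose importance score exceeds
    ``q`` (default the top decile).  Missing cells map to False."""
    if not (0 <= q < 100):
        raise ValueError("q must lie in [0, 100)")
    vals = importance.to_numpy()
    mask = np.isfinite(vals) & (vals > q)
    return xr.DataArray(mask, coords=importance.coords, dims=importance.dims)
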