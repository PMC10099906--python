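"""Climate-analogue projection of preferred habitat.

Rather than refitting the preference model on (biased) climate-model
hindcasts, future habitat is projected by analogy: each future-climate
cell is classified by the preferred/not-preferred status of its k most
environmentally similar current-climate cells.  Similarity is Euclidean
distance in a reduced space built per climate representation:

1. each available variable is scaled to 0-1 with min/max pooled over the
   current and future periods (so both periods share one scale);
2. PCA is fitted on current-period cells and the smallest number of
   components explaining >= 95% of variance is retained; future cells
   are projected with the same loadings;
3. accessibility (already 0-1) is appended as one extra feature axis;
4. each future cell takes the majority label of its k = 5 nearest
   current cells (odd k: no label ties; distance ties broken by lowest
   cell index).

Per-representation projections are combined per scenario by simple
majority, and each cell is categorised as retained / gained / lost /
never relative to the current preferred mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from sklearn.decomposition import PCA

from .env_match import EnvStack

__all__ = ["ClimateRepresentation", "AnalogueProjection",
           "normalize_variables", "reduce_dimensions",
           "knn_analog_classify", "ensemble_combine",
           "CATEGORY_CODES"]

#: integer codes of the combined-change categories
CATEGORY_CODES = {"never": 0, "lost": 1, "gained": 2, "retained": 3}


@dataclass
class ClimateRepresentation:
    """One climate model's current and future climatologies.

    ``variables`` is the subset (at most 8) of the covariate vocabulary
    this representation provides; current and future stacks must share
    grid and variables.
    """

    name: str
    scenario: str
    variables: tuple[str, ...]
    current: EnvStack
    future: EnvStack

    def __post_init__(self) -> None:
        for v in self.variables:
            if v not in self.current.layers or v not in self.future.layers:
                raise ValueError(f"variable {v!r} missing from a period stack")
        if (not np.array_equal(self.current.lats, self.future.lats)
                or not np.array_equal(self.current.lons, self.future.lons)):
            raise ValueError("current and future stacks must share the grid")


@dataclass
class AnalogueProjection:
    name: str
    scenario: str
    layer: xr.DataArray          # boolean preferred-habitat-like
    k: int
    n_components: int
    variance_explained: float


def normalize_variables(current: EnvStack, future: EnvStack,
                        variables: tuple[str, ...],
                        ) -> tuple[xr.Dataset, xr.Dataset, dict, list]:
    """Scale each variable to 0-1 with min/max pooled over both periods.

    Returns (current', future', scaling record {var: (min, max)},
    dropped variables).  Constant variables cannot be scaled and are
    dropped with a record; normalising already-normalised data is a
    no-op (idempotent).
    """
    cur, fut = {}, {}
    scaling: dict[str, tuple[float, float]] = {}
    dropped: list[str] = []
    for v in variables:
        a = current.ds[v].to_numpy().astype(float)
        b = future.ds[v].to_numpy().astype(float)
        lo = np.nanmin([np.nanmin(a), np.nanmin(b)])
        hi = np.nanmax([np.nanmax(a), np.nanmax(b)])
        if not np.isfinite(lo) or not np.isfinite(hi) or hi <= lo:
            dropped.append(v)
            continue
        scaling[v] = (float(lo), float(hi))
        cur[v] = (current.ds[v].dims, (a - lo) / (hi - lo))
        fut[v] = (future.ds[v].dims, (b - lo) / (hi - lo))
    if not cur:
        raise ValueError("no scalable variables remain")
    return (xr.Dataset(cur, coords=current.ds.coords),
            xr.Dataset(fut, coords=future.ds.coords), scaling, dropped)


def reduce_dimensions(cur_norm: xr.Dataset, fut_norm: xr.Dataset,
                      threshold: float = 0.95,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, float]:
    """PCA on current-period cells; keep the fewest components explaining
    >= ``threshold`` of variance; project future cells with the same
    loadings.

    Returns (current scores, future scores, joint sea-cell flags, number
    of components, variance explained).  Rows are grid cells in raveled
    (lat, lon) order; cells missing in either period are excluded.
    """
    variables = list(cur_norm.data_vars)
    Xc = np.column_stack([cur_norm[v].to_numpy().ravel() for v in variables])
    Xf = np.column_stack([fut_norm[v].to_numpy().ravel() for v in variables])
    ok = np.isfinite(Xc).all(axis=1) & np.isfinite(Xf).all(axis=1)
    if ok.sum() < len(variables):
        raise ValueError("fewer valid cells than variables")
    pca = PCA(n_components=len(variables), svd_solver="full")
    scores_c = pca.fit_transform(Xc[ok])
    cum = np.cumsum(pca.explained_variance_ratio_)
    # guard: zero-variance inputs give a denormalised ratio sum
    n_comp = int(np.searchsorted(np.minimum(cum, 1.0), threshold) + 1)
    n_comp = min(n_comp, len(variables))
    scores_f = pca.transform(Xf[ok])
    return (scores_c[:, :n_comp], scores_f[:, :n_comp], ok, n_comp,
            float(cum[n_comp - 1]))


def _majority_knn(cur_feat: np.ndarray, labels: np.ndarray,
                  fut_feat: np.ndarray, k: int) -> np.ndarray:
    """Brute-force k-NN majority vote with deterministic tie handling:
    equidistant neighbours are taken in ascending cell-index order."""
    if k > len(cur_feat):
        raise ValueError(f"k={k} exceeds the {len(cur_feat)} current cells")
    out = np.empty(len(fut_feat), dtype=bool)
    # chunked distance matrix keeps memory bounded on large grids
    chunk = max(1, int(2e7 // max(len(cur_feat), 1)))
    for s in range(0, len(fut_feat), chunk):
        d = np.sqrt(((fut_feat[s:s + chunk, None, :]
                      - cur_feat[None, :, :]) ** 2).sum(axis=2))
        order = np.argsort(d, axis=1, kind="stable")[:, :k]
        votes = labels[order].sum(axis=1)
        out[s:s + chunk] = votes * 2 > k
    return out


def knn_analog_classify(rep: ClimateRepresentation,
                        preferred_mask: xr.DataArray,
                        accessibility: xr.DataArray | None = None,
                        k: int = 5, pca_threshold: float = 0.95,
                        ) -> AnalogueProjection:
    """Classify each future cell as preferred-habitat-like or not by the
    majority label of its ``k`` nearest current-climate cells.

    ``preferred_mask`` is the current binary preferred-habitat layer
    (from the top-percentile transform); ``accessibility`` (0-1 surface)
    joins the PC scores as one extra feature dimension for both periods.
    Deterministic: odd ``k`` precludes vote ties and distance ties are
    broken by lowest cell index.
    """
    cur_n, fut_n, scaling, dropped = normalize_variables(
        rep.current, rep.future, rep.variables)
    sc, sf, ok, n_comp, var = reduce_dimensions(cur_n, fut_n, pca_threshold)

    if accessibility is not None:
        acc = accessibility.to_numpy().ravel()[ok][:, None]
        sc = np.hstack([sc, acc])
        sf = np.hstack([sf, acc])

    labels = preferred_mask.to_numpy().ravel()[ok].astype(bool)
    like = _majority_knn(sc, labels, sf, k)

    full = np.zeros(preferred_mask.size, dtype=bool)
    full[np.flatnonzero(ok)] = like
    layer = xr.DataArray(full.reshape(preferred_mask.shape),
                         coords=preferred_mask.coords,
                         dims=preferred_mask.dims)
    return AnalogueProjection(name=rep.name, scenario=rep.scenario,
                              layer=layer, k=k, n_components=n_comp,
                              variance_explained=var)


def ensemble_combine(projections: list[AnalogueProjection],
                     current_mask: xr.DataArray) -> dict:
    """Combine per-representation projections into one generalized
    projection per scenario.

    A cell is future-preferred when more than half of the representations
    classify it preferred-habitat-like.  Returns a dict with the
    ``agreement`` count layer, the majority ``future_preferred`` layer,
    and an integer ``category`` layer coded by :data:`CATEGORY_CODES`
    (0 never, 1 lost, 2 gained, 3 retained).  Raises on mixed scenarios.
    """
    if not projections:
        raise ValueError("no projections to combine")
    scenarios = {p.scenario for p in projections}
    if len(scenarios) > 1:
        raise ValueError(f"mixed scenarios in ensemble: {sorted(scenarios)}")
    stack = np.stack([p.layer.to_numpy() for p in projections])
    agreement = stack.sum(axis=0)
    n = len(projections)
    future = agreement * 2 > n
    cur = current_mask.to_numpy().astype(bool)
    category = np.select(
        [cur & future, cur & ~future, ~cur & future],
        [CATEGORY_CODES["retained"], CATEGORY_CODES["lost"],
         CATEGORY_CODES["gained"]],
        default=CATEGORY_CODES["never"])
    coords, dims = current_mask.coords, current_mask.dims
    return {
        "scenario": projections[0].scenario,
        "n_representations": n,
        "agreement": xr.DataArray(agreement, coords=coords, dims=dims),
        "future_preferred": xr.DataArray(future, coords=coords, dims=dims),
        "category": xr.DataArray(category.astype(np.int8), coords=coords,
                                 dims=dims),
    }
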