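# Methods

This note documents the models behind `habshift`, the choices that were
genuinely open, and what the synthetic-world tests do and do not
establish.

## The analysis chain

### Case–control (presence–background) habitat preference

Habitat preference is inferred by contrasting the environment at
observed track fixes (cases, label 1) with the environment at simulated
"availability" fixes (controls, label 0). Because the case:control
ratio is fixed by design (one observed track against *n* null tracks,
default 50), fitted probabilities are a **relative** preference index,
not an absolute occurrence probability; all downstream use is
rank-based (percentile importance scores), which is invariant to that
scaling.

### Track regularisation

Raw tracks are resampled to an exact 12-h lattice anchored at the first
fix, with positions obtained by spherical linear interpolation between
the bracketing raw fixes on a sphere of radius 6371 km. This is a
deliberate substitution for a state-space movement model: an SSM earns
its keep by handling the large observation error of light-level
geolocation, which pre-filtered or synthetic tracks do not carry, and
the downstream contract only needs regular fixes plus empirical
movement parameters. Fixes interpolated across a raw gap longer than 7
days are flagged (`gap_flag`), never silently fabricated. Turning
angles are signed changes in initial great-circle bearing (positive =
clockwise); the antimeridian is handled implicitly by doing all
geometry on the unit sphere.

### Null tracks

Each null track starts at the observed start point, reuses the observed
timestamps element-wise, draws one uniform random initial bearing, and
builds subsequent steps by **jointly** resampling (speed, turning-angle)
pairs from the observed track — joint rather than independent so the
within-track autocorrelation of step lengths survives into the
availability sample. Constraints: sea cells only, equatorward of the
>80% ice-concentration edge, poleward of 30°S, and displacement from
the start capped at the observed maximum +5%. A violating step is
redrawn (up to 100 times; cap breaches reflect the heading inward,
toward the start); an exhausted step backtracks one step. Null tracks
are **not** forced to end at the colony: the central-place constraint
is carried by the accessibility model, not the availability sample.

### Boosted regression trees

`sklearn.ensemble.GradientBoostingClassifier` with Bernoulli (log-loss)
deviance stands behind the fit: learning rate 0.01, bag fraction
(subsample) 0.5, tree complexity (max depth) 5. The tree count is
selected from the grid `tree_step, 2·tree_step, …, max_trees` by
k-fold cross-validation **blocked by individual** (no animal on both
sides of a fold), minimising mean held-out deviance; the final model is
refit on all rows at the selected count. Per-fold AUC at the selected
count gives the CV AUC mean ± sd. Reported metrics follow the standard
format: tree count, percent deviance explained
(100·(1 − residual/null Bernoulli deviance)), R² operationalised as the
squared Pearson correlation between label and fitted preference (the
source description is only verbal), and CV AUC. Colony-level blocking
validation refits with one colony held out and reports 2×2 confusion
matrices at a 0.5 threshold — the threshold is reported alongside
because prevalence is fixed by the 1:n design. Partial dependence is
computed by clamp-and-average on the logit scale and centred to mean
zero. Defaults `max_trees=2000, tree_step=100, n_folds=10`; the desk-
scale configurations used in tests and the acceptance script pass
smaller grids (200–400 trees, 3–4 folds) explicitly to bound runtime —
on the synthetic world held-out deviance always bottoms out well below
these ceilings.

### Accessibility

Observed + null fixes are rasterised to a per-cell binary
visited/not-visited response paired with great-circle distance from the
colony (straight-line; no least-cost paths around land). Distances are
binned (50 km), bin rates are fit by **decreasing isotonic regression**
weighted by bin occupancy, and the step output is smoothed through the
bin centres by a monotone (PCHIP) spline, clipped to [0, 1]. Curves are
fit per colony. Combination with preference is multiplicative —
`combined = preference × access(distance)` — the minimal operator that
up-weights preferred-and-reachable cells and down-weights
preferred-but-unreachable ones. Multi-colony aggregation: cell-wise
maximum over colonies (default, unweighted — a cell is usable if birds
from any colony can reach it, output stays within [0, 1] and never
exceeds the preference), or a population-weighted mean giving a
relative density index.

### Importance scores and preferred habitat

Ocean-wide predictions on the winter (April–September) climatology are
transformed by percentile: `score = 100 · mean-rank / n` over
non-missing sea cells. Ties share their mean rank, which preserves the
uniformity of the score distribution; any strictly monotone rescaling
of the raw predictions leaves the scores unchanged, which is exactly
why two taxa's maps become comparable. "Preferred habitat" is the top
decile (score > 90), configurable. Percentiles are computed over all
non-missing cells of the analysis extent.

### Climate-analogue projection

Per climate representation (each providing ≤8 of the covariate
vocabulary): variables are scaled to 0–1 with min/max **pooled over the
current and future periods** so both periods share one scale (constant
variables are dropped with a warning); PCA is fitted on current-period
cells only — projecting future cells with the same loadings avoids
leaking the future shift into the embedding — keeping the fewest
components explaining ≥95% of variance; accessibility (already 0–1)
joins as one extra feature axis. Each future cell then takes the
majority preferred/not-preferred label of its k = 5 nearest
current-climate cells under Euclidean distance. Odd k precludes vote
ties; distance ties are broken deterministically by lowest cell index.
The matching direction — classify future cells against labelled current
cells — is one of two readings of the source description; the
alternative (tracking where current preferred cells "move to") is noted
but not implemented. Ensemble combination is a simple majority over
representations (agreement counts are emitted so users can
re-threshold), and each cell is categorised retained (1→1), gained
(0→1), lost (1→0) or never (0→0) relative to the current mask, coded
0/1/2/3 = never/lost/gained/retained.

### Regional change

Five meridional sectors approximate the MEASO assessment areas
(boundaries 70°W, 30°E, 80°E, 150°E, 130°W; the West Pacific sector
spans the antimeridian); authoritative polygons can be supplied as
GeoJSON instead. Cells are assigned by their centre point — at 1°
resolution fractional overlap would change little and centre assignment
preserves the partition invariant. Areas are geodesic:
`R²·Δλ·(sin(φ+Δφ/2) − sin(φ−Δφ/2))` per cell (a cell-count mode exists
for sensitivity). Percent change is `100·(future − current)/current`,
undefined (flagged) where a region holds no current habitat. Ensemble
summaries report median, 25th/75th percentiles (linear, "type 7"
interpolation), min and max.

## The synthetic world

The generator's defaults state a world at the scale of the real system:

| parameter | default | rationale |
|---|---|---|
| grid | 0–90°E × 35–68°S, 1° cells | Southern-Ocean-like window poleward of 30°S |
| season | Apr 1 – Sep 30, daily | the post-moult winter window |
| SST | 20 °C at 30°S, −0.5 °C per ° latitude | zonal banding; declines poleward |
| SSH | 0.7 m at 30°S, −0.02 m per ° latitude | co-varying frontal-height proxy |
| spatial / daily noise | 0.3 / 0.2 °C (SST) | mesoscale + day-to-day variability |
| niche | Gaussian, μ_T = 8 °C, σ_T = 1 °C; μ_H = 0.22 m, σ_H = 0.3 m | reported prevalence bands for these birds are a few °C wide (e.g. peak 3–4.5 °C over a 2–6 °C range), i.e. σ ≈ 1 °C; SSH tolerance broad so SST dominates |
| land | 5% of cells (smoothed-relief peaks); 3×3 sea ring kept around colonies | islands/shelf; colonies need sea access |
| ice | 0% at 58°S rising 20%/° poleward; >80% blocks | winter ice edge as a track constraint |
| trips | 120 d × 12-h steps, mean speed 5 km/h (gamma, shape 4) | 4–6-month, ~10,000-km round trips, desk-scaled toward the lower end |
| movement | candidate-heading fan von Mises κ = 1 around the previous heading; softmax habitat bias 15 on destination true preference; final 20% of steps re-aimed at the colony | a correlated walk whose contrast with the availability sample is wide (availability spans many °C of SST, occupancy ~1σ of the niche), as in the real system |
| future | SST + 1 °C; 4 pseudo-representations differing by 0.1 °C noise fields | end-of-century-style uniform warming; noise mimics inter-model spread |

The true preference is the product of the two Gaussians, evaluated on
the climatological fields; the ground-truth "preferred" mask is its top
decile, and the warmed-field mask gives the analytic answer the
analogue projection must recover (with a linear zonal gradient the band
shifts poleward by ΔT/gradient degrees).

Early prototypes used 20-day, 3-km/h trips and σ_T = 1.5 °C; that world
gave the null tracks almost no room to differ environmentally from the
observed ones, so no method could have recovered the niche. The
defaults above were fixed before the acceptance tests were written and
not revisited afterwards.

What the synthetic world does **not** emulate: geolocation error (so
the regulariser's SSM substitution is untested against noise),
multi-year climatological structure, behavioural states (transit vs
foraging), current advection, and prey fields. A green test therefore
establishes that the pipeline's statistics recover a known
environmental niche from a biased-walk sample under the stated
constraints — not that the movement model is behaviourally realistic.

## Numerical choices

- Sphere radius 6371 km everywhere; haversine distances; positions and
  interpolation on unit-sphere vectors (antimeridian-safe).
- Nearest-cell covariate lookup (no interpolation): at 1° resolution
  cells dwarf 12-h step lengths. Rows with any missing covariate are
  dropped listwise and counted in the extraction report.
- Bathymetry slope: central differences, one-sided at edges, zonal
  spacing scaled by cos(latitude); arctan to degrees.
- Isotonic accessibility is clipped to [0, 1] and post-processed with a
  running minimum to absorb spline wiggles at the 1e-12 level.
- Determinism: every stochastic stage takes a seed derived from the one
  pipeline seed; `run_all` twice with the same configuration produces
  bit-identical CSV/NetCDF artifacts (verified by hash in the tests).
- Degenerate inputs: single-class accessibility responses yield a flat
  flagged curve; colonies holding a single label are flagged in
  blocking validation; constant variables are dropped before PCA;
  fewer individuals than folds reduces the fold count with a warning.

## Known limitations

- Accessibility distance ignores land barriers (no least-cost paths).
- The preference model is one learner (boosted trees); no GAM/MaxEnt
  alternatives, and no spatially-aware CV beyond individual/colony
  blocking.
- The analogue projection inherits the ambiguity of multivariate
  matching: when the future changes only a subset of the variables the
  niche depends on, the analogue answer legitimately differs from a
  refit — this is a property of the method, not of the implementation.
- NetCDF output uses the NetCDF3 (scipy) backend; no GeoTIFF writer.
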