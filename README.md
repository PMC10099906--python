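# habshift

Habitat-preference and climate-redistribution modelling for
central-place marine predators (built around the post-moult migrations
of *Eudyptes* — crested — penguins in the Southern Ocean).

Migratory penguins spend their 4–6-month post-moult winter at sea and
must return to the colony to breed. Where they go is shaped by ocean
properties — sea surface temperature and height above all — and those
properties are moving poleward under climate change. `habshift`
implements the full analysis chain from animal tracks and gridded
environmental covariates to:

1. **habitat preference** — a presence–background (case–control) design:
   covariates at observed track fixes (label 1) are contrasted against
   constrained **null tracks** (label 0) that keep each track's dates,
   duration, speeds, turning angles and maximum colony displacement but
   take random headings, restricted to sea cells between 30°S and the
   >80% sea-ice edge. Preference is fit with **boosted regression
   trees** (Bernoulli loss, learning rate 0.01, bag fraction 0.5, tree
   complexity 5) with the tree count chosen by k-fold cross-validation
   blocked by individual, plus colony-level blocking validation;
2. **accessibility** — the probability a cell is reachable on a round
   trip, modelled as a monotone decreasing function of great-circle
   distance to the colony (isotonic fit + monotone spline) and
   multiplied into the preference surface;
3. **importance maps** — ocean-wide predictions transformed by
   percentile to a 0–100 habitat importance score (uniform by
   construction, hence comparable across taxa); "preferred habitat" is
   the top decile;
4. **climate-analogue projection** — instead of refitting on climate
   model hindcasts, each future-climate cell is classified by the
   majority preferred/not-preferred label of its k = 5 nearest
   current-climate cells (variables normalised 0–1 with pooled bounds,
   PCA to ≥95% variance, accessibility as an extra feature axis,
   Euclidean distance), repeated per climate representation and
   combined by majority into retained / gained / lost habitat;
5. **regional change** — percent change in preferred-habitat area per
   MEASO-style sector (Atlantic, Central Indian, East Indian, West
   Pacific, East Pacific) using latitude-dependent geodesic cell areas,
   with quartile summaries across the representation ensemble.

Because real tracking data and climate-model fields are large external
downloads, the package ships a first-class **synthetic world**
(`habshift.synthetic_world`): zonally banded SST/SSH fields with noise,
land and ice masks, colonies, habitat-biased correlated-random-walk
tracks, and warmed future climates — all derived from a closed-form
"true" preference function so every stage can be tested against a known
answer. See `docs/methods.md` for the model details and defaults.

## Worked example

```python
from habshift import BRTConfig, PipelineConfig, WorldConfig, run_all

cfg = PipelineConfig(
    world=WorldConfig(n_individuals=16, trip_days=20.0),
    n_nulls=20,
    brt=BRTConfig(max_trees=400, tree_step=50, n_folds=4),
).reseed(1)
res = run_all(cfg, "out/")

print(res["metrics"])
print(res["fit"].importance.sort_values(ascending=False).head(3))
print(res["summary"])
```

prints (about 40 s on one CPU):

```
{'n_trees': 250, 'pct_deviance_explained': 27.35, 'r2': 0.215,
 'cv_auc_mean': 0.774, 'cv_auc_sd': 0.070}
sst                    31.5
eddy_kinetic_energy    15.1
sea_surface_height     11.8
             taxon         region  scenario  n  median    q25    q75    min    max
synthetic_eudyptes       Atlantic synthetic  4  -15.54 -15.94 -15.14 -15.94 -15.14
synthetic_eudyptes Central Indian synthetic  4  -10.52 -10.53 -10.34 -10.53  -9.82
```

Reading this: the boosted-tree model selected 250 trees and separates
observed from null fixes with a blocked cross-validated AUC of 0.77;
SST is correctly recovered as the dominant covariate (the generator's
true niche is a Gaussian in SST and SSH). Under the configured +1 °C
warming, the preferred band moves poleward and the two sectors holding
preferred habitat lose about 16% and 11% of its area, with the spread
over the four pseudo-representations shown by the quartiles. `out/`
additionally holds the tracks, case-control table, accessibility
curves, importance/projection NetCDF layers and tidy CSV change
records.

A command-line wrapper exposes the same workflow:

```sh
habshift -v run-all --config config.yaml --seed 1 --out out/
habshift report --out out/
```

## Acceptance script

`scripts/acceptance.py` re-runs the complete pipeline from scratch on
the synthetic world (world → tracks → nulls → extraction → preference
model → accessibility → maps → analogue projection → regional change),
deriving all randomness from `--seed`, and writes the results manifest
to `--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
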