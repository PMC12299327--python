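# ferncast

Ensemble species-distribution modelling and cultivation zoning for a wild
edible fern, built as a tested, reusable pipeline that runs end-to-end on
synthetic landscapes with known ground truth.

## The problem

Montane wild vegetables such as bracken fern (*Pteridium aquilinum* var.
*latiusculum*) are harvested across alpine gorge regions where climate change
is shifting the habitats they depend on. Managing such a resource requires
answering a chain of quantitative questions: where is habitat suitable today,
how do suitable areas grow or shrink under emission scenarios, how far and in
which direction does the habitat centroid migrate, how much does the realized
climatic niche drift, and — since the plant is harvested for food — where do
habitat suitability and nutritional quality jointly support cultivation?

`ferncast` implements that full chain for researchers in ecological niche
modelling and resource management:

1. **Variable screening** — prune collinear environmental variables
   (pairwise Spearman |ρ| < 0.7, VIF < 5, explicit ecological-relevance
   priorities break ties).
2. **Ensemble SDM** — thin occurrences to one per 1-km cell, draw 1200
   pseudo-absences, fit five base learners (regularized logistic regression,
   random forest, gradient boosting, a Maxent-style L1 exponential model, a
   rectilinear envelope) over ten stratified 75/25 splits, score with
   ROC AUC / TSS / Cohen's κ, keep fits with TSS ≥ 0.7 and average their
   predictions with TSS-proportional weights
   (w_m = TSS_m / Σ_k TSS_k,  S(x) = Σ_m w_m S_m(x)).
3. **Tiering and change accounting** — binarize at the TSS-maximizing cutoff,
   split the suprathreshold range into equal-width low/moderate/high tiers,
   and account areas (spherical-Earth cell areas, 10⁴ km² units) and
   loss/stable/gain overlays between periods.
4. **Centroid migration** — area-weighted habitat centroids and haversine
   migration distances/bearings per scenario.
5. **Niche overlap** — occupancy densities over a PC1×PC2 environmental
   space (Gaussian KDE, availability-corrected) compared with Schoener's
   D = 1 − ½ Σ |z₁ − z₂|.
6. **Cultivation zoning** — an entropy-weighted nutrition index
   N = Σᵢ wᵢ·Xᵢⁿᵒʳᵐ combined with suitability into site productivity
   P = (S + N)/2, a seven-candidate trendline regression of P on S selected
   by AIC (ΔAIC < 2 parsimony rule), and core/general/marginal zones at the
   P > 0.58 / 0.37–0.58 / < 0.37 thresholds.

The fit/transform-shaped stages are scikit-learn estimators
(`CollinearityScreener`, `EnsembleSDM`, `ProductivityRegressor`) that compose
with sklearn pipelines and model selection; everything else is plain
functions over small numpy-backed containers.

## Worked example

```python
import numpy as np
import ferncast as fc

lc = fc.LandscapeConfig(grid_rows=60, grid_cols=60, n_vars=8,
                        scenario_deltas={"SSP585-2090": np.r_[2.0, 2.0, np.zeros(6)]},
                        seed=7)
stack = fc.generate_env_stack(lc)
truth = fc.default_truth(8)
presences = fc.thin_occurrences(fc.generate_occurrences(stack, truth, 256, seed=7))
absences = fc.sample_pseudo_absences(stack, presences, 600, seed=7)
points = fc.OccurrenceSet.concat(presences, absences)
X = stack.values_at(points.lon, points.lat).to_numpy()
y = points.is_presence.astype(int)

model = fc.EnsembleSDM(repeats=3, tss_gate=0.7, random_state=7).fit(X, y)
print(f"gated members: {len(model.members_)}/{len(model.all_scores_)}")
print(f"held-out ensemble AUC: {model.pooled_auc_:.3f}, cutoff: {model.cutoff_:.3f}")

current = model.predict_map(stack)
future = model.predict_map(fc.generate_env_stack(lc, "SSP585-2090"))
areas = fc.cell_areas(stack.geometry)
summary = fc.area_summary(current, areas)
print(f"current suitable area: {summary.total:.2f}e4 km2 "
      f"(high share {summary.share('high'):.2f}%)")
change, _ = fc.overlay_change(current, future, areas)
print(f"loss {change.loss:.2f}, stable {change.stable:.2f}, gain {change.gain:.2f} (e4 km2)")
seg = fc.build_trajectory([fc.habitat_centroid(current, areas),
                           fc.habitat_centroid(future, areas)])[0]
print(f"centroid shift: {seg.distance_km:.2f} km {seg.compass}")
```

prints

```
gated members: 15/15
held-out ensemble AUC: 0.984, cutoff: 0.494
current suitable area: 1.55e4 km2 (high share 49.86%)
loss 0.56, stable 0.99, gain 0.05 (e4 km2)
centroid shift: 8.67 km NE
```

Every base-learner fit cleared the TSS ≥ 0.7 gate, the pooled held-out AUC
shows the ensemble separates presences from background almost perfectly on
this synthetic landscape, and the strong warming scenario (+2 SD on the two
leading climate variables) destroys about a third of suitable habitat while
pushing its centroid ~9 km northeast.

The same chain runs from the command line on one YAML config:

```bash
ferncast all --config run.yml --seed 7 --out-dir out/
```

producing suitable-area, change and cultivation-zone tables (CSV), centroid
trajectories (CSV + GeoJSON), niche-overlap summaries (JSON), raster outputs
(multi-band TIFF + JSON georeferencing sidecar) and a checksummed manifest.

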