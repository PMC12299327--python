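# Methods

## Synthetic landscapes and ground truth

Environmental layers are Gaussian random fields: white noise smoothed with a
Gaussian kernel (`spatial_corr_length`, default 8 cells) and standardized to
zero mean, unit variance. Future scenarios add a per-variable mean shift to
the current layers, so scenario contrasts are exactly the configured deltas;
the default scenario set applies shifts that grow with emission intensity
(SSP1-2.6 < SSP2-4.5 < SSP5-8.5) and horizon (2090 = 2× 2050) to the leading
six variables, emulating warming-driven climatic drift without modelling
GCM physics.

The ground-truth response is logistic,
S = σ(β₀ + Σ βᵢ zᵢ). The default truth puts weights (8, −6, 4, 3) on the
first four variables with intercept −16, i.e. a *sharply delimited,
low-prevalence* niche occupying roughly 8% of the landscape. That regime was
chosen because it is the one in which near-perfect discrimination between
presences and background is attainable — the fragmented, climatically
confined habitat typical of a montane species. A diffuse niche (coefficients
of order 1) caps the achievable AUC near 0.85 regardless of the learner, so
it cannot represent a species whose distribution models score TSS ≳ 0.9.

Occurrences are drawn with probability proportional to S, with uniform
within-cell jitter so 1-km thinning has duplicates to remove. Nutrition
indicators are affine in site suitability (loading proportional to the
configured true weight) plus Gaussian noise, with heterogeneous scales and
offsets mimicking different assay units.

**What the synthetic data do not emulate:** sampling bias (roads, survey
effort), spatially structured observation error, covariate interactions or
threshold responses in the truth, non-climatic land-use dynamics, and
variance changes under future climates (scenarios shift means only, though
variance scaling can be added through the deltas). Passing the recovery
tests therefore demonstrates that the pipeline's machinery is correct and
well-calibrated under its own assumptions — not that any given field system
satisfies them.

## Variable screening

Two greedy passes: (1) while any pair of surviving variables has
|Spearman ρ| ≥ 0.7, drop the lower-priority member of the worst pair;
(2) while any survivor has VIF ≥ 5, drop the worst (ties broken by
priority). Correlation pruning runs first because rank correlations are
defined pairwise and cheap, and the VIF pass then operates on an already
thinned set; the procedure is idempotent and column-order independent given
a total priority order. "Ecological relevance" is an explicit user-supplied
ranking — the package does not infer it. PCA of the screened background
sample is exposed as a diagnostic (loadings, variance shares), not as a
selection criterion.

## Ensemble SDM

Presences are thinned to one per 1-km grid cell (grid anchored at the
south-west corner of the point cloud; first point in input order wins).
Pseudo-absences (default 1200) are drawn uniformly without replacement from
valid cells containing no presence, once per run (a per-repeat redraw is a
config flag). Splits are stratified 75/25, repeated 10 times; with five
algorithms this yields 50 member fits.

Every member is scored on its held-out fold: ROC AUC by rank statistic, and
TSS/κ at the threshold maximizing TSS over the observed-score grid (the
standard convention when no external threshold exists). Members with
TSS ≥ 0.7 enter the ensemble with weights proportional to their TSS. The
binarization cutoff is the TSS-maximizing threshold on the pooled held-out
ensemble scores; the suprathreshold interval [cutoff, 1] is split into three
equal-width tiers, lower bound inclusive in the low tier and each band
upper-closed.

The Maxent-style member is an L1-regularized logistic model over linear,
quadratic and pairwise-product feature transforms — an exponential-family
approximation of Maxent's feature machinery, not a port of the reference
implementation. The rectilinear envelope (SRE) member scores 1 inside the
per-dimension presence range (quantile trimming available, default off) and
0 outside; it is deliberately crude and routinely fails the TSS gate, which
is the gate working as intended.

## Habitat dynamics, centroids

Cell areas use the spherical-Earth band formula
A = R²·Δλ·(sin φ_top − sin φ_bot) with R = 6371.0088 km; at basin scale the
sphere-vs-ellipsoid error is far below the 0.01 precision of reported area
tables. "Suitable" for overlays means any tier at or above low (S ≥ cutoff).
Loss/stable/gain conservation identities (loss + stable = current total,
stable + gain = future total) hold exactly by construction. Percent changes
are signed, 100·(comparison − reference)/reference, reported to two
decimals; published change tables carry rounding of their own, so
comparisons against them use 0.01–0.02 absolute tolerances on areas computed
from unrounded values.

Centroids are area-weighted means of suitable-cell centers (binary mode,
the default, matching the habitat-centroid convention of SDM toolkits); a
suitability-weighted mode is available since the literature convention is
ambiguous. Longitude is averaged arithmetically, valid for domains spanning
a few degrees. Distances are haversine on the same sphere; bearings are
initial great-circle bearings with quadrant compass labels (NW/NE/SW/SE,
cardinal at exact multiples of 90°).

## Niche overlap

Background environments come from square (Chebyshev) 1° buffers around
occurrence points under current climate, or from ensemble-suitable habitat
under future climates; a circular buffer would change little at this buffer
size and the square form maps directly onto the grid. The background sample
is projected by centered-and-scaled PCA; occurrence and background densities
are Gaussian KDEs (Silverman bandwidth) on a 100×100 lattice over the joint
PC1×PC2 bounding box. Occupancy is the occurrence density divided by
background availability where availability exceeds 10⁻¹², zero elsewhere,
normalized to sum to one. Schoener's D = 1 − ½ Σ |z₁ − z₂| is snapped to
exactly 0/1 within 10⁻¹² to absorb summation round-off. Published D values
from field data are treated as a qualitative ordering (stronger forcing →
smaller overlap), which the synthetic shift experiment reproduces; they are
not numeric targets because they depend on undeposited occurrence data.

## Cultivation model

Indicators are min-max standardized per column (constant columns become
zeros with a warning and receive entropy weight 0). Entropy weights use
p_ij = x_ij/Σ_i x_ij with a 10⁻¹² shift on zeros, e_j = −(1/ln n) Σ p ln p,
w_j ∝ 1 − e_j; diversification below 10⁻¹⁰ is snapped to zero so constant
indicators get exactly zero weight.

Site productivity is P = S + N. As printed, a P = S + N identity combined
with a P~S regression is circular; the implemented reading is: P is
*computed* at the sampled sites (where both S and N exist), the P~S relation
is *fitted* there, and the fitted relation *projects* P from S alone across
the raster — the only reading that lets zones be mapped where no nutrition
data exist. By default P is rescaled to (S + N)/2 so it stays in [0, 1] and
the fixed zone thresholds (core > 0.58, general 0.37–0.58 inclusive at both
ends, marginal < 0.37, within suitable habitat only) remain meaningful; the
raw sum is available via `rescale=False`.

The seven candidate forms follow the canonical trendline-fitting set:
y = ax+b, y = ax²+bx+c, y = a·ln x + b, y = a·e^{bx}, y = a·e^{bx}+c,
y = a·x^b, y = a·x^b+c. Each is least-squares fitted (`scipy.optimize.
curve_fit`); log/power forms are skipped with a record when any S ≤ 0.
Selection uses AIC = n·ln(RSS/n) + 2k; candidates within ΔAIC < 2 of the
minimum are equivalent and the fewest-parameter one wins, remaining ties
broken by registry order. This parsimony rule is what prevents the quadratic
(which nests the line) from winning on noise.

## Pipeline and reproducibility

One global seed fans out per stage as
`SeedSequence([seed, stage_index]).generate_state(1)[0] mod 2³¹`, so stages
re-run standalone reproduce their in-pipeline behaviour. All stochastic
components (field generation, occurrence sampling, pseudo-absences, splits,
tree learners, background sampling, nutrition noise) are seeded; two runs of
the same config produce byte-identical outputs, verified via SHA-256
checksums in the run manifest.

Raster I/O writes multi-band TIFF with a JSON sidecar carrying cell-center
coordinates and band names; containers are plain lon/lat grids (row 0 at the
southern edge in memory, flipped to the raster convention on disk). No CRS
machinery is included — the pipeline operates on geographic grids only.

## Problem sizes

The test suite exercises the ensemble on 60×60 landscapes with 8 variables
and 3 repeats; the parameter-recovery check and the acceptance script use
the full study configuration (120×120 cells, 16 variables, 176 presences,
1200 pseudo-absences, 10 repeats × 5 algorithms = 50 fits, ~1 minute on one
CPU). Niche-shift experiments use a 60-lattice with 1500 background and 200
occurrence points per seed, which is where the D-vs-shift curve stabilizes.

## Known limitations

- The envelope and Maxent-style members are simplified stand-ins for their
  reference implementations; their role is breadth of model class, and the
  TSS gate decides whether they contribute.
- Equal-width suitability tiers are sensitive to the cutoff; equal-area
  tiers would change tier-level area tables.
- The availability correction in niche space divides two KDEs; where
  background density is thin the ratio is noisy even after clipping.
- Rank agreement between ensemble output and truth degrades in the deeply
  unsuitable tail (tree ensembles are flat there), so cell-wise rank
  correlations depend on landscape prevalence.
- Entropy weights measure dispersion, not relevance: an indicator can earn a
  large weight while being ecologically meaningless.
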