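# Methods

This note documents the models, conventions, parameter defaults and known
limitations of `flywaysdm`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external runs.

## Spatial conventions

One planar CRS throughout; no reprojection. Grids are north-up and
row-major: cell (0, 0) is the northwest cell, cell extents are half-open
`[x, x + cellsize)`, and coordinates snap to cells by flooring against the
lower-left origin. ESRI ASCII grids are written with the canonical header
order (`ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value`);
GeoTIFFs carry ModelPixelScale/ModelTiepoint/GDAL_NODATA tags. Nodata is
NaN in memory. GeoJSON polygons rasterize by **cell-center containment**.

Occurrence de-duplication retains one record per species per
`dedup_cellsize` cell (default 1000 m — coarser than the 300 m analysis
grid, applied before snapping), keeping the first record in input order so
the operation is deterministic and multiplicity-invariant.

## MaxEnt

The model is the background-normalized Gibbs density
`q(x) = exp(lambda.f(x)) / Z` with features min-max scaled to [0, 1] on the
background sample; classes are linear, quadratic, and forward hinge (10
knots per variable at background quantiles; reverse hinges are not
implemented). The objective is the L1-penalized negative mean presence
log-likelihood. Assumptions inherited from the formulation: presences are
an unbiased sample of the species' environmental distribution, and the
background sample represents available environment (sampled uniformly from
valid cells, presence cells not excluded, resampled fresh per replicate).

**Optimizer.** Cyclic coordinate descent. Each coordinate solves its exact
1-D convex problem by safeguarded Newton with the L1 subgradient cases
(soft-threshold logic; per-update step capped at |delta| <= 30 on a [0,1]
feature). Convergence when a full cycle improves the objective by less than
`tol` (1e-6); `max_iter` 500 cycles; the objective is recomputed from
scratch each cycle to prevent drift. The fitted background distribution
satisfies sum(q) = 1 to 1e-9 (tested).

**Regularization.** `beta_j = beta_multiplier * base(m) * sd_j / sqrt(m)`,
where `base(m)` interpolates 1.0 -> 0.05 over presence counts 10 -> 100 for
linear/quadratic features and is 0.5 for hinges, and `sd_j` is the feature's
presence-sample standard deviation (floored at 1e-3). This follows the
published default schedule in shape; `beta_multiplier` rescales it.

**Outputs.** Logistic suitability `P = q e^H / (1 + q e^H)` (entropy `H` of
the background distribution), so the uniform model scores 0.5 everywhere.
Training gain is `(1/m) sum ln q + ln N_background` (0 for the uniform
model). Percent contribution credits each coordinate update's positive
objective improvement to the feature's source variable and normalizes to
100 — like all gain-attribution measures it is unreliable under strong
multicollinearity, which is why screening precedes final fits. Jackknife
gains refit with only/without each variable. AUC is the rank statistic with
0.5 tie credit.

**Evaluation protocol.** Per species: 10 replicates of a random 75/25
presence-cell split with a fresh 10,000-point background sample, AUC of
test presences vs. background, reported as mean, SD and CV = SD/mean; the
final map is the mean of replicate logistic maps. Species with
AUC mean <= 0.90 or CV >= 0.15 are flagged excluded. At least 8 presence
cells are required so the test split is nonempty.

## Variable screening

Step 1 removes zero-contribution variables (contributions from a
preliminary all-variable fit at default regularization). Step 2 computes
Pearson correlations over layer values at the occupied cells and
iteratively finds the currently largest |r| >= 0.8 pair, dropping its
lower-contribution member (tie: the later in input order) until no pair
remains at the threshold. The iterative greedy form and the tie rule are
this package's choices (the alternative simultaneous form is
order-ambiguous); the result is deterministic and permutation-invariant
away from ties, and the kept set provably has max |r| below the threshold.
Zero-variance layers at the points get undefined r, treated as |r| = 0 with
a warning.

## Stacking and hotspots

Per-species logistic maps are binarized by the top class of a 3-class
Fisher–Jenks partition (or a supplied fixed threshold, `value >= t`);
binarize-then-stack order is used, richness is the cellwise sum, and the
richness surface is reclassified by 3-class natural breaks into
non-suitable / low / high (codes 0/1/2); high-suitability cells are the
group's "suitable habitat". Values equal to a break join the lower class.
The Jenks solver is an exact weighted dynamic program over distinct values;
maps with more than ~100,000 finite cells are sampled (seeded) and
continuous values binned to 1024 quantile levels before the DP — at that
resolution the breaks are stable to far below the class widths that matter
here. Degenerate richness surfaces (fewer than 3 distinct values) code to
0/2 or all-0 with a warning. Density surfaces are square moving-window
means (1 km default) with edge windows shrinking to in-bounds cells; unique
suitable habitat labels cells suitable for exactly one group.

## Group-level climate importance

Response: the group's suitable/unsuitable mask; predictors: the climate
variables exceeding the 10% contribution threshold in the group's species
models (fallback: the two highest-contribution climate variables, so the
stage is always defined). Rows are all finite cells up to `sample_cap`
(default 100,000; class-proportion-preserving seeded sample above that)
with inverse-class-frequency weights. Trainer: xgboost with binary logistic
loss, shallow trees (depth 2–4), learning rates {0.05, 0.1}, subsample 0.8,
up to 500 trees with early-stopping patience 20. Hyperparameters are chosen
by fivefold stratified CV inside a 70% training partition (maximize mean
fold accuracy, then minimize its SD, ties to shallower/fewer trees);
overall accuracy is measured on the untouched 30% (the final model's early
stopping uses a validation split carved from the training partition, never
the test set). Importance is total Gain per variable, normalized to sum 1
within each fold, reported as fold mean ± SD.

Known Gain-metric property: exactly collinear predictors are credited
winner-take-all (the library tie-breaks deterministically), not 50/50. The
pair's combined gain is conserved; screening upstream is what keeps this
from affecting interpretation.

## Preference and terrain profiles

RF(i, l) = (U / S) × 10⁴ with U the area of **distinct** suitable cells of
class *l* occupied by at least one of the group's records (so duplicated
records cannot inflate it) and S the suitable area in the class. RF is
missing (never 0) where S = 0; a flag allows counting occupied cells
outside suitable habitat for sensitivity analysis. Slope/aspect use Horn's
3×3 method; aspect is reported as the compass bearing of the **upslope**
gradient (0° = north, clockwise), undefined on flat cells. Terrain/NDVI
profiles are median, type-7 quartiles and 1.5×IQR whiskers capped at the
data range, over each group's suitable cells.

## Landscape metrics and gaps

SHDI = −Σ p ln p over class shares in a square moving window (900 m
default; the window edge is converted to the nearest odd cell count), SHEI
= SHDI / ln m with m the classes **present in the window** by default (the
map-wide FRAGSTATS basis is available by flag and recorded in output
metadata); single-class windows score 0 on both; natural logarithms
throughout; edge windows shrink. Gap analysis tallies per-region suitable,
reserve and overlap areas (cell counts × cell area, reported in 10⁴ km²)
and two ratios: overlap/reserve (the convention matching published regional
coverage tables) and overlap/suitable (the share of habitat protected);
zero denominators give missing ratios.

## Synthetic landscapes: what they emulate, and what they do not

Climate-style fields are white noise smoothed by a separable Gaussian
kernel (scale 4 cells default), standardized, and mixed through the
Cholesky factor of a requested correlation matrix; empirical pairwise
correlations land within ±0.1 of the target at 128×128 (tested). The DEM is
a lower-frequency field (3× the smoothing scale) mapped to 500 ± 300 m;
slope/aspect derive from it by the same Horn convention used in analysis.
Land cover is a 6-class quantile mosaic of two latent fields; population
and nighttime lights are Gaussian kernels around random city seeds.

Group truth is `logistic(intercept + sum coef_k * z_k)` on standardized
drivers. Defaults: dominant coefficient 2.0, a secondary driver at 0.5, and
intercept −3.0, putting suitable-habitat prevalence near 13% — a rare,
specialist-type habitat that keeps every downstream stage (stacking, class
weighting, gap overlays) well conditioned. Presences are multinomial draws
with cell probability proportional to suitability × effort (effort uniform
by default; a city-kernel effort layer is available for sampling-bias
robustness checks), jittered uniformly within the cell.

**Separability ceiling.** Because presences are sampled *proportionally* to
a logistic truth, the presence and background score distributions overlap
by construction: for w = logistic(a + 2z), z ~ N(0,1), the best achievable
presence-vs-background AUC is ≈ 0.74 at a = −1, ≈ 0.83 at a = −3, and only
approaches 0.90 as prevalence collapses below 2% — independent of the
fitted model. Measured replicate AUC on the default truth is ≈ 0.82 with
CV ≈ 2%, i.e. at the ceiling. Consequently the 0.90 reliability gate, which
real specialist species pass easily, is *not* passable by these synthetic
species; pipeline tests of the synthetic study therefore set `auc_min = 0`
to exercise all stages, and the gate itself is tested separately (it must
flag both null and ceiling-limited species as excluded). Passing tests on
synthetic data demonstrate driver recovery, calibration and plumbing — not
the absolute AUC levels attainable with strongly clustered real
occurrences.

What the generator does **not** emulate: real geography or hydrological
networks, anisotropic or long-range spatial structure, temporal dynamics,
detection error conditional on presence, taxonomic noise, or the empirical
bias structure of citizen-science archives (the city-kernel effort field is
a stand-in, not a claim about that structure).

## Determinism

One root seed derives per-stage, per-species seeds as
`crc32(seed:stage:name)` (kept below 2³¹), so adding a species never
perturbs another's results. Background sampling, splits, boosting
subsampling and synthetic generation all flow from these seeds; two runs of
the pipeline with the same seed produce byte-identical CSV ledgers
(tested). Pipeline tests and the acceptance script run scaled-down problem
sizes (48–96 cell grids, 3–10 replicates, linear+quadratic features) chosen
so the full validation battery completes in a few minutes while leaving
every statistical conclusion unchanged at larger sizes.

## Known limitations

- No product/threshold/categorical MaxEnt features, no reverse hinges, no
  clamping or extrapolation (MESS) diagnostics.
- Percent contribution and Gain importance are attribution heuristics;
  both are unstable under multicollinearity (hence the screening step).
- The ASC/GeoTIFF readers handle single-band, square-pixel, single-CRS
  rasters only; no mosaicking, reprojection, or cloud-optimized access.
- Jenks breaks on very large continuous rasters are computed on a seeded
  sample with 1024-level binning — exact on integer richness surfaces,
  approximate (to well below class width) on continuous maps.
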