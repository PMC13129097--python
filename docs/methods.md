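# Methods

This note documents the models, conventions and defaults implemented in
`floradrift`, the choices made where several reasonable options existed, and
what the synthetic generator does and does not emulate.

## Inputs and scales

All analyses operate on a complete rectangular lattice of grid cells
(default 10 km resolution) carrying static geography (planar x/y in km,
affine longitude/latitude proxies, elevation, distance to coast, land mask),
per-scenario × per-period climate fields (mean annual temperature MAT in °C,
annual precipitation MAP in mm, isothermality, precipitation of the driest
month), and a binary species × cell × scenario × period occupancy cube.
Distances are always computed in planar km; longitude/latitude are affine
descriptors only.  Period labels default to `Current, 1140, 4170, 7100` and
scenarios to the SSP shorthand `126, 370, 585`; arbitrary labels are
accepted.

## Synthetic data generator

The generator emulates the *output* shape of a thresholded ensemble SDM, not
the SDM itself (no pseudo-absences, cross-validation or skill weighting).

* **Landscape** — an elliptical landmass with a seeded wavy coastline on the
  lattice; elevation is a smooth ridge field rising toward the north-east
  (peak ≈ 1,500 m) over a gentle south→north slope, plus seeded Gaussian
  relief noise (sd 30 m), clipped at 0.  Coast distance is the exact minimum
  center-to-center distance to a sea cell; 5% of near-coast cells have it
  masked to exercise imputation, mimicking land–sea resampling gaps.
* **Climate** — MAT = 15 °C − 1.0·(lat − lat₀) − 6.0·(elevation/1000) +
  t·δ_scenario + ε(cell); MAP has a coastal-wet and orographic structure
  with a mild wet-get-wetter trend; isothermality is a bounded smooth field.
  Default per-period warming increments are δ = 0.3/0.6/0.9 °C for scenarios
  126/370/585 (end-century anomalies of 0.9/1.8/2.7 °C).  The noise ε is a
  *static spatial field* drawn once per cell and shared across scenarios and
  periods, so within-scenario warming is exactly monotone by construction;
  setting its sd to 0 yields fully deterministic fields.
* **Species pool** — species *s* is present where
  exp(−(MAT − opt_s)²/(2σ_s²)) · logistic((MAP − req_s)/150 mm) ≥ τ_s on
  land.  Optima are warm-skewed (q95 of current MAT minus an Exponential(2 °C)
  offset), breadths uniform on 1.5–3.5 °C, moisture requirements uniform on
  800–1300 mm, thresholds uniform on 0.30–0.50.  This concentrates baseline
  richness in warm coastal lowlands and, under warming, moves every species'
  suitable band poleward and upslope while the warmest-edge cells lose
  species (range retraction).  All parameters are serialized (`ShiftTruth`)
  for recovery checks; identical seeds reproduce cubes bit-for-bit.

What the generator does **not** emulate: dispersal limitation, biotic
interactions, landscape fragmentation by land use, observation error in
occurrences, or prediction gaps (cubes are complete).  Tests passing on this
generator therefore demonstrate correctness of the analysis machinery and
recoverability of a clean constructed signal, not performance on noisy real
SDM stacks.

## Environmental zoning

The four static variables are z-transformed with the *population* standard
deviation (the z-scores are descriptive; the convention simply has to be
fixed) and clustered by Lloyd k-means with k-means++ starts, best of 10
restarts by inertia.  Candidate k is constrained to k ≥ 6 — fewer zones are
too coarse to resolve the elevational and coastal gradients the zoning is
meant to capture — and k\* is the smallest candidate whose mean silhouette is
within 1% of the best ("plateau" rule); the default without selection is
k = 9.  Cluster labels are arbitrary in k-means, so clusters are relabelled
1..k by descending size (ties break on centroid lexicographic order), making
labels reproducible and row-order invariant.  Spatial autocorrelation is
deliberately ignored: the goal is interpretable scenario-invariant zones,
not spatially contiguous ones.

Missing coast distances are filled by inverse-distance-weighted (power 2)
interpolation over the 8 nearest observed land cells, before
standardization.  This is a boundary correction only; a smoother-based
interpolation would serve equally and the choice is immaterial downstream.

## Core response zones

Richness-weighted KDE uses the bivariate Gaussian kernel with a full 2×2
bandwidth matrix.  The default selector is the weighted normal-scale rule
H = n_eff^(−1/3) Σ̂_w with the Kish effective sample size
n_eff = (Σw)²/Σw² and the weighted covariance Σ̂_w (at d = 2 the usual
(4/(d+2))^(2/(d+4)) prefactor equals 1).  Note that n_eff is a property of
the weight vector: replicating every point with half weight doubles n_eff
and shrinks H by 2^(−1/3), while rescaling all weights leaves H unchanged.
A coordinate-wise two-stage direct plug-in selector (Gaussian reference at
stage zero) is available behind the same interface for data where the
normal-scale rule oversmooths.

The evaluation lattice is the analysis grid itself; density × cell area
approximates mass, and no kernel edge correction is applied — the post-hoc
clip to land leaves a known mild density deficit near coasts.  The
KDE50 region is the discrete highest-density set: cells sorted by density,
accumulated to 50% of mass, with all cells tied at the threshold density
included (deterministic and order-independent; the discrete set can overshoot
50% by at most one cell's mass).  Regions are raster cell sets, not vector
polygons; at a single fixed resolution this matches polygon dissolution up to
half-cell discretization.  Per cluster the KDE50 ∩ land ∩ cluster-footprint
set is summarized by its centroid (mean of member cell centers), area,
4-connected component count, and mean/median/IQR of elevation and coast
distance (quantiles use linear interpolation throughout the package).
Displacement records difference centroids and attribute means between
periods; clusters empty in either period are reported absent, not zero.
Scenario agreement counts, per land cell, the scenarios whose KDE50 set for
the cell's own cluster contains it.

The default estimates one pooled KDE per scenario × period and intersects
with clusters; a per-cluster KDE mode exists because the cluster-level
reading of the isopleths is equally defensible.

## Compositional trajectories

Eligibility requires a cell to have complete predictions *and* at least one
species present in every period — Bray–Curtis is undefined on empty
communities, so "complete predictions" is read as no-missing plus non-empty.
Per cluster, 20 cells are drawn without replacement, 30 times (defaults);
each (cluster, replicate) uses an independently split child seed so any
subset reruns identically.

One **reference ordination** is fitted per scenario on the union of all
sampled cells × the four periods: binary Bray–Curtis distances, Gower double
centering of −d²/2, eigendecomposition, and — if the smallest eigenvalue is
negative — the Lingoes correction d′² = d² + 2c with c = −λ_min, which makes
the configuration exactly Euclidean (round-trip distance reconstruction is
tested to 1e-8).  Axis signs are fixed by making each axis's
largest-magnitude score positive.  A dense solver is used up to 1,200
entities and a Lanczos (ARPACK) solver above, computing the two retained
axes plus the extreme eigenvalue needed for the correction.  Fitting one
shared plane avoids per-replicate axis indeterminacy; Procrustes alignment
of per-replicate ordinations was considered and rejected as strictly more
machinery for the same comparisons.

Replicate trajectories are the per-period means of the replicate cells'
scores (cluster-centroid paths).  Metrics: length L (cumulative Euclidean
distance), directionality D = net displacement / L (NaN when L = 0), and
internal variation V = sample (n−1) standard deviation of unsigned turning
angles in [0°, 180°], skipping zero-length segments (NaN with fewer than two
angles).  The trajectory vector for alignment is the net displacement
p_T − p₁; cos Δθ is its cosine against each fitted environmental direction
and the scaled alignment is A = L·cos Δθ, so |A| ≤ L always.  The dominant
driver is argmax |A| with ties broken by the configured variable order.

**Environmental vectors** are least-squares regressions of each standardized
variable on the two plotted axes; the direction is the normalized
coefficient vector, r² the coefficient of determination, and p a permutation
tail probability (add-one convention) from shuffling the variable.  The
default variable set is latitude, longitude, isothermality and
precipitation of the driest month — the gradients such ordinations typically
resolve — with any landscape or climate variable (elevation, coast distance,
MAT, MAP) accepted; time-varying variables take their period-specific
values.  Fitting uses the two plotted axes only, matching how the vectors
are displayed and interpreted.

A note on signs: the fitted latitude vector points toward high-latitude
(cool, species-poor) community types.  Under warming, a *fixed* cell's
composition slides toward warm community types, so retracting (richness-
losing) clusters align *negatively* with the latitude vector and positively
with the MAT vector.  The recovery checks encode exactly these constructed
signs via `expected_alignment_signs` (a cluster counts as retracting when
its mean richness falls ≥ 20% between first and last period).  Geographic
poleward displacement is a separate, positive-signed quantity measured by
the KDE50 centroid shift.

**Interval turnover** reports per-cell Bray–Curtis between consecutive
periods within each replicate, summarized as median and IQR per interval.

**PERMANOVA** uses the McArdle–Anderson trace partition on the Gower-centered
matrix with sequential (Type-I) sums of squares, cluster entered before
period (an interaction term is available); pseudo-F per term against the
residual mean square; p by free permutation of entities with the add-one
convention; 9,999 permutations by default.  **PERMDISP** embeds entities by
PCoA keeping real and imaginary parts (z² = d²_real − d²_imag, floored at
0), computes distances to group *centroids*, and permutes group labels of a
one-way ANOVA F on those distances.  Fully degenerate configurations (all
z = 0) are reported as NaN rather than a spurious F.  Type-I error of
PERMANOVA under the null and uniformity of envfit permutation p-values are
verified by simulation in the acceptance suite (500 and 200 Monte-Carlo
runs).

## Climate space

MAP is converted to centimetres so ellipse areas are in °C·cm.  Confidence
ellipses use the multivariate-normal approximation: center = sample mean,
shape = sample covariance (ddof 1), boundary at the chi-square(2df) quantile
q (1.3863 at 50%, 5.9915 at 95%), area = π·q·√detΣ.  ΔArea and percent
change compare same-level ellipses.  Overlaps (Jaccard = |∩|/|∪|;
minimum-based = |∩|/min area) are computed on a shared 500×500 raster over
the joint bounding box, with O(1/raster_n) discretization error —
convergence to the closed-form area within 1% is asserted in tests.  Both
pooled and per-cluster ellipses are produced.

The k × k transition matrix P(F|C) counts cluster reassignment of cells in
standardized MAT–MAP space.  How "future labels" arise is genuinely
ambiguous, so three sources are provided: assign each cell's *current*
climate to nearest *future-period* cluster centroids (default — the entry
then reads "cluster C's present climate matches the future climate of
cluster F", so warming sends warm rows toward cooler columns); assign each
cell's *future* climate to *current* centroids (the reverse orientation);
or keep static labels (identity, a null reference).  Rows of empty clusters
are NaN; occupied rows sum to 1.

Biome fractions rasterize an ellipse against user-supplied labelled polygons
in MAT–MAP coordinates (first polygon wins on overlap, with a warning); no
digitized biome reference is bundled — it is an optional user input.

## Pipeline, seeds, determinism

`run_pipeline` executes simulate → zone → corezones → trajectories →
climatespace → summary, writing plain CSVs plus a JSON manifest with the
config hash, per-stage wall-clock and SHA-256 checksums of every output.
A single root seed is split deterministically per (stage, cluster,
replicate) through `numpy.random.SeedSequence`; identical config + seed
reproduces byte-identical CSVs (asserted in the suite).  Replicate-level
metrics are aggregated as medians and IQRs (linear-interpolation quantiles).
Defaults mirror the reference settings: 10 km cells, k = 9, 50% isopleth,
20 cells × 30 replicates, 9,999 permutations, 50%/95% ellipses.

## Verification problem sizes

The acceptance suite runs, per design, at reduced scale: oracle checks on
n ≤ 100 instances; permutation calibration at 40 entities × 500 runs × 199
permutations (envfit: 200 runs × 999 permutations); end-to-end recovery on a
40 × 40 grid with 30 species, k = 9, zero climate noise, 10 replicates per
cluster, across 20 seeds; determinism on a 16 × 16 grid.  These sizes were
chosen as the smallest at which the checked signals are unambiguous.

## Known limitations

* No kernel edge correction: KDE50 areas are biased slightly inland on
  concave coastlines.
* The cosine alignment assumes an approximately linear compositional
  response along each gradient; strongly horseshoe-shaped ordinations can
  make single-axis-pair alignments hard to interpret.
* Raster (cell-set) isopleths quantize areas to whole cells; at coarse
  resolutions vector contouring would differ near boundaries.
* The transition matrix depends on the chosen label source (documented
  above); report which orientation you used.
* PERMANOVA permutes entities freely; with strong spatial autocorrelation
  within clusters its p-values are anti-conservative, as in any
  non-restricted permutation design.
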