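# Methods

## Marked point patterns and Ripley's L

A tissue section is reduced to points (x, y) in µm inside an axis-aligned
rectangular observation window, each marked `portal` or `central`.  All
spatial statistics consume this `MarkedPointPattern`.

**Intensity** is count/area (per µm²; `portal_density` converts to mm⁻²).

**Ripley's K/L.**  For the selected points (pooled marks by default, since
the vascular-dispersion question concerns all large vessels together),

    K̂(r) = |W| / (n(n−1)) · Σ_{i≠j} w_ij · 1[d_ij ≤ r],      L̂ = √(K̂/π).

The intensity denominator is fixed to (n−1)/|W| (the convention that makes
K̂ unbiased for a Poisson process).  Edge corrections:

* `isotropic` (default): w_ij is the reciprocal of the fraction of the
  circle centred at point i with radius d_ij lying inside the window,
  computed with the exterior-arc formula (per-edge arcs
  2·arccos(d_edge/r), minus pairwise corner overlaps
  max(0, θ_e + θ_f − π/2)).  Standard and nearly unbiased for patterns of
  this size on rectangles.
* `translation`: w_ij = |W| / ((W−|Δx|)(H−|Δy|)).
* `border`: minus-sampling on source points.

Grids default to 512 points on [0, min(window side)/4]; requests beyond
min(side)/2 are truncated with a warning because the corrections degrade
there.  At r where no pairs exist, K̂ = 0 and L̂ = 0; the variance-
stabilised L̂ has a small negative bias at very small r (Jensen, √ of a
noisy non-negative count), which is why calibration checks start the grid
above zero.

**Grouped studentized permutation test.**  Given m_i L-functions per group
on a shared grid, the statistic sums over unordered group pairs the
integrated studentized discrepancy

    T = Σ_{i<j} ∫ ( L̄_i(r) − L̄_j(r) )² / ( s_i²(r)/m_i + s_j²(r)/m_j ) dr

(trapezoid rule).  Grid cells whose pooled variance term vanishes are
dropped from the integrand (they carry no information and would divide by
zero).  The null distribution permutes the pattern-to-group assignment;
p = (1 + #{T* ≥ T}) / (B + 1), ties counted as exceedances (conservative).
Groups of size 1 are rejected — within-group variance is undefined.
Empirically the test holds its nominal size: with 3 CSR groups × 4
sections and 199 permutations, 200 null replicates give a rejection rate
statistically indistinguishable from 0.05 (the acceptance script
recomputes this).  Note the permutation distribution is discrete: with
m + m sections split evenly, only C(2m, m)/2 distinct assignments exist,
bounding the attainable p from below — power assertions use ≥ 6 sections
per group.

## Lobule geometry

For every central vein the sorted distances to its k_max (default 6)
nearest portal tracts are computed (exact kd-tree queries; brute-force
O(n²) oracle equivalence is tested).  The per-k mean over central veins is
the step profile; the boundary k\* maximises mean_{k+1} − mean_k, ties
broken toward the smallest k (the conservative lobule definition) with a
relative tolerance of 1e−9 so that rescaling coordinates cannot flip a
tie.  A constant profile returns k\* = 1 flagged `is_flat`.

The lobule-as-hexagon estimator takes r_i = mean distance from central
vein i to its three nearest portal tracts and A_i = (3√3/2)·r_i².  Near
the window boundary the true nearest portals may lie outside the window,
biasing r upward; `exclude_boundary=True` drops central veins closer than
the section-mean r to the edge.  The default keeps every vein (whole-
section analysis); accuracy-of-recovery checks use the exclusion, under
which the estimate is exact on a noise-free lattice and within ~1% at
jitter_sd = 0.05·r0.

Aggregation runs per section first (profile, mean area, density), then
across sections per group; the per-central-vein table is retained so
either pooling convention can be reproduced.

## Synthetic vascular lattice

Central veins sit at the centres of a regular honeycomb (hexagon
circumradius r0, default 100 µm — lobule diameters of a few hundred µm);
portal tracts at occupied vertices.  A uniform random phase shifts the
lattice relative to the window (sections cut the tissue at arbitrary
positions — this also makes per-section counts genuinely variable), and
isotropic Gaussian jitter of sd `jitter_sd` perturbs every point.  Jitter
has no empirically known value and is treated as a sweep parameter
(defaults around 0.05–0.15·r0 in examples); points jittered outside the
window are clamped to it.

Occupancy modes: `three_alternate` takes the three alternating apices of
every hexagon — one bipartite vertex sublattice of the honeycomb.  After
deduplicating shared vertices this sublattice is itself triangular with
exactly one vertex per hexagon: portal and central intensities are
asymptotically equal, and each interior central vein has 3 portals at r0,
3 more at 2·r0, then 6 at √7·r0 — which is what makes the detected 3:4
step exact.  `all_vertices` occupies all six apices; `random_fraction`
keeps each vertex with probability p.  Hexagons whose six vertices all lie
inside the window flag their central vein `interior`; edge-sensitive
assertions further restrict to veins ≥ 2.2·r0 from the boundary so the
whole 2·r0 shell is observed.

CSR null patterns are homogeneous Poisson (count ~ Poisson(λ|W|), uniform
positions); Thomas-like clustered alternatives (Poisson parents, Gaussian
offspring) provide the power case.

## Synthetic nuclear population

The generator emulates the statistical structure the classifier faces,
not images: each nucleus carries area (µm²), perimeter (back-solved from
circularity 4πA/P²), circularity, elongation (major/minor ≥ 1), intensity
mean/sd, nearest-neighbour distance and touching-neighbour count, the last
two computed from the realised geometry.

Class-conditional feature distributions are truncated normals (truncation
at 0 forbids impossible negative areas; circularity clipped to (0, 1],
elongation to ≥ 1):

| feature        | hepatocyte-like | non-hepatocyte |
|----------------|-----------------|----------------|
| area µm²       | 70 ± 15         | 45 ± 16        |
| circularity    | 0.85 ± 0.07     | 0.76 ± 0.11    |
| elongation     | 1.15 ± 0.12     | 1.35 ± 0.28    |
| intensity mean | 120 ± 18        | 135 ± 25       |
| intensity sd   | 15 ± 5          | 21 ± 8         |

The hepatocyte centre is anchored at the typical 70 µm² hepatocyte
nucleus; the overlaps were chosen once so that no single feature separates
the classes and a depth-7 tree reaches realistic (≈ 0.91–0.95, not 1.0)
held-out accuracy, and then frozen.

Geometry: singleton hepatocytes are placed by sequential inhibition at
1.5× the touching distance (plate spacing — hepatocyte nuclei do not
touch); binucleated cells are pairs of hepatocyte-like nuclei with
centroid separation 0.5–0.95× the touching distance (default 12 µm,
slightly above one nuclear diameter), their centroids kept ≥ 1.6× touching
distance from hepatocytes and ≥ 3× from other pairs so each pair touches
only itself — the defining context of a binucleated hepatocyte inside a
plate; non-hepatocyte nuclei fall in tight Gaussian clusters (mean size
4, sd 0.45× touching distance) mimicking inflammatory foci and small
granulomas, kept 2.5× touching distance away from planted pairs.  What
this deliberately does **not** emulate: scattered single sinusoidal
endothelial cells threaded between plates, intensity textures, nuclear
shape irregularity, or segmentation artefacts — so passing tests show the
pipeline's statistical machinery is correct on its stated model, not that
the defaults transfer to any particular scanner or stain.

## Classification and binuclear cascade

The tree is binary (hepatocyte-like vs non-hepatocyte; binuclear ground
truth collapses to hepatocyte for this stage, because per-nucleus features
cannot distinguish a binuclear member from a touching non-hepatocyte —
that is precisely why the cascade exists).  Defaults follow the training
recipe: stratified 70/30 split (per-class round(0.7·n) to train), CART
with max depth 7 and ≥ 1 sample per leaf, 5-fold stratified CV accuracy
recorded for tuning, final fit on the whole training set, deterministic
per seed.  `iterative_tune` formalises "train and test statistics as
comparable as possible" as: choose the grid config minimising the maximum
absolute train−test gap across the nine error-matrix statistics, ties to
the smaller depth.

The cascade then runs three ordered rules over nuclei with predicted
classes: R1 candidate pairs are touching hepatocyte-predicted nuclei
(centroid separation ≤ 12 µm); R2 keeps pairs with combined area in
[1.4, 2.6] × 70 µm² (≈ 1.5–2.5 typical nuclei — one-and-a-half excludes
a nucleus plus a fragment, two-and-a-half excludes merged clusters); R3
refuses any nucleus participating in a clique of ≥ 3 mutually touching
nuclei (dense non-hepatocyte context).  Survivors are relabelled
Binuclear, each rule logged with its pair count.  The cascade is
idempotent: promoted nuclei are no longer hepatocyte-predicted, so a
second pass changes nothing.  All thresholds are configurable
(`BinuclearRules`).

The error matrix computes its nine statistics in exact rational arithmetic
(floats only at the boundary), flags zero-denominator ratios as NaN, and
rounds to 4 decimals for display.  `reconstruct_confusion` rebuilds
integer confusion counts from population sizes and printed
sensitivity/specificity by nearest-integer rounding, which lets a
published error-matrix row be reproduced and cross-checked exactly.

## Group statistics

One-way ANOVA is the classical SS decomposition (F with df (k−1, N−k);
zero within-group variance flagged rather than silently propagated);
Tukey HSD uses the studentized range with the Tukey–Kramer denominator for
unbalanced groups; Kruskal–Wallis applies the tie correction with χ²
p-values on k−1 df; Spearman is the Pearson correlation of mid-ranks with
a t-approximation on n−2 df (an exact permutation option enumerates all
rank permutations for n ≤ 10 — the two can disagree in the third decimal
at small n, which is why both are exposed); the two-sample t-test defaults
to Welch (robust to unequal variances; pooled available by flag).  Type-I
calibration of ANOVA and the t-test is asserted against the binomial 95%
interval over 500 simulated nulls.

## Problem sizes and determinism

Every generator and test accepts an explicit integer seed and is
reproducible bit-for-bit given it; the pipeline stamps outputs with the
seed and a config hash.  The validation suite uses 2 mm² synthetic
sections (~150 lobules), CSR calibrations of 50 patterns at n ≈ 500,
200 null replicates × 199 permutations for the grouped test's size, and
20 seed-replicates of the ~1 900-nucleus classification population —
sizes at which every Monte-Carlo band asserted is comfortably resolved on
a single CPU in a few minutes.

## Known limitations

* Windows are rectangles; polygonal sections and inhomogeneous-intensity
  K variants are out of scope.
* The honeycomb generator is an idealisation: real lobules are irregular
  polygons with 3–7 faces and variable portal occupancy; only the jitter
  and occupancy parameters probe that variability.
* The nuclear feature set is a declared contract, not a reconstruction of
  any particular segmentation platform's feature list; thresholds of the
  binuclear cascade are anchored to the 70 µm² typical nucleus, not fitted
  to data.
* Group-level reproduction of any specific study's animal cohorts requires
  their per-animal annotations, which are external deposits; the suite
  validates the machinery by parameter recovery and calibration instead.
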