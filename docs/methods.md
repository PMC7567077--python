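# Methods

`nicheshift` quantifies climatic niche shifts between the native and
non-native realized niches of introduced species, and relates shift
magnitude to geographic dispersion and native niche size. This note
records the models, the defaults and the design choices made where the
underlying methodology leaves the implementer freedom.

## Niche space

For each species the bioclimatic values at all cleaned occurrences (native
and non-native pooled) are z-scored and reduced by PCA. A between-class
analysis on the first 10 axes, with range status as the a-priori class,
yields the single direction separating the two ranges the most; for two
classes this is exactly the unit vector along the difference of the class
centroids in score space, sign-fixed so the native centroid projects at or
below the non-native one. When the centroids coincide the axis falls back
to PC1 with a warning. All three niche-shift metrics are computed along
this axis.

Occurrence scores are binned into **100 bins** spanning the pooled
background of both ranges (so native and non-native densities share one
grid) and smoothed with a Gaussian kernel (Silverman's rule,
`1.06 · SD · n^(-1/5)`, truncated at the grid bounds by renormalisation).
The description this implements speaks of a "100 × 100" grid, but a single
ordination axis is one-dimensional; we therefore use a 1-D grid of 100
bins along the axis — the resolution is preserved, the dimensionality
follows from the axis definition.

Availability (`e`) is the kernel density of the background climate scores,
**masked to the observed background score range** before renormalising.
The mask matters: a Gaussian tail stays above any fixed threshold for many
bandwidths past the last real climate cell, and without the mask the
corrected occupancy `z ∝ o/e` would be positive over essentially the whole
axis, making "climates absent from the native niche" — and hence the
expansion metric — undetectable. With the mask, the support of `z` is
exactly the climates the range's background actually contains.

The background of a range defaults to all valid raster cells inside the
convex hull of its occurrences buffered by one grid cell (`mode="hull"`),
with a whole-raster option.

## Niche-shift metrics

* **Schoener's D** `= 1 − ½ Σ|z₁ − z₂|` on the common grid; 0 = no
  overlap, 1 = identical niches.
* **Expansion** `= 100 × Σ z_nonnative` over bins where `z_native = 0`.
  Species are classed low (< 10%) or high (≥ 10%); exactly 10% counts as
  high (the conventional "<10% / >10%" phrasing leaves the boundary
  undefined, so we document this tie rule). An optional
  `presence_quantile` discards the lowest-density native bins holding a
  fraction q of native mass before defining presence; the default is the
  plain `z > 0` rule.
* **Equivalency test**: all occurrences are pooled and randomly re-split
  1000 times at the observed native:non-native ratio; each split is scored
  with the same procedure as the observed labelling and
  `p = (1 + #{D_sim ≤ D_obs}) / (1 + n_reps)` (ties favour the null; p is
  never 0). p-values are Benjamini–Hochberg adjusted across species.

Two equivalency design points deserve emphasis:

1. **The between-class axis is re-derived for every permutation**
  (default). The axis is supervised by the labels, so holding the observed
  axis fixed would hand the observed split an advantage no permuted split
  can attain — the observed centroid difference is maximal along its own
  direction — biasing D_obs low and inflating the type-I error. Refitting
  per split restores exchangeability; the pooled standardisation and PCA
  are label-free and computed once, so the cost is minor. A fixed-axis
  mode remains available (`refit_axis=False`).
2. **Both pseudo-ranges share one pooled availability background.** If
  each pseudo-range kept its own geographic background under permutation,
  the availability mask would delete exactly the foreign-climate mass the
  permutation moved in, so the simulated D would track the observed D and
  the test would lose essentially all power.

## Preprocessing

Cleaning follows standard occurrence-data practice, per species × status
group: (i) greedy nearest-neighbour thinning in input order — a record is
kept iff it lies strictly more than 0.02° (≈ 2 km) from every previously
kept record; keep-first makes the pass deterministic and idempotent;
(ii) at most one record per climate grid cell (first wins); (iii) species
with fewer than 10 native or fewer than 10 non-native records are dropped.
Raster cells are half-open, `[x, x+Δ) × (y−Δ, y]`, north-up, so edge
points are assigned reproducibly. Distances are planar degrees, matching
the thinning rule's units. Manual exclusion of dubious records is
supported via an exclusion table.

## Dispersion metrics

Richness is the number of map polygons containing at least one occurrence
(boundaries inclusive). Rao's quadratic entropy
`Q = Σᵢⱼ pᵢ pⱼ dᵢⱼ` uses great-circle distances (haversine, R = 6371 km)
between occupied-polygon centroids and uniform weights (abundance weights
optional). Species are grouped by k-means (k = 3, 20 restarts, fixed seed)
on z-scored (richness, Q), clusters named regional < transcontinental <
global by ascending mean Q.

## Native niche hypervolume

A PCA is fit once on the standardised environment of **every valid raster
cell** (default 3 dimensions), so species' volumes are comparable. KDE in
10+ dimensions is uninformative at realistic sample sizes, hence the low
default; 2–5 are reasonable. Each species' native occurrences are
projected into this space and a Gaussian KDE (equal-weight isotropic
kernels) is fit with a **single bandwidth fixed across species**: the
maximum, over species and axes, of the per-axis rule-of-thumb bandwidths
`1.06 · SD · n^(-1/5)` from a preliminary pass. The niche volume is the
geometric volume of the region holding q = 0.95 of the KDE's mass,
estimated by importance sampling: draw `10 000 · d` points from the
mixture, set the threshold at the empirical (1−q) quantile of the sampled
densities, and average `1/f` over retained samples. Density evaluation is
batched (default 500 samples per chunk), which bounds memory without
affecting results. The estimator is deterministic given its seed and is
validated against the closed-form 0.95-mass ellipse of a bivariate
standard normal.

## Synthetic data

The virtual-species generator supplies every input the pipeline needs,
with known ground truth:

* **Climate layers** are sums of low-frequency plane waves plus a shared
  component and 5% white noise, z-scale-mixed so any pairwise correlation
  in [0, 1) can be requested. At correlation 0 the per-layer wave modes are
  drawn without replacement from an orthogonal pool, so layers are
  uncorrelated by construction rather than on average. The shared
  component contains a one-sided eastward ramp (zero over the western
  half, weight 4× the shared waves): the east of the domain then offers
  both climates that also occur in the west *and* genuinely novel ones,
  the way an invaded continent offers analog and non-analog climate. A
  coherent dominant gradient is also what makes novelty visible to a 1-D
  ordination axis at all; with purely incoherent fields, no single
  direction separates novel from analog climate.
* **Occurrences**: native points are drawn from cells of the native
  window with probability `exp(−½‖(x − c)/σ‖²)` of the cell's
  standardised climate x; non-native points come from the (disjoint)
  non-native window with the centre displaced by the true shift vector.
  A fraction `target_expansion` is forced, by rejection against the native
  window's per-layer min/max climate envelope, into novel climates — these
  draws are availability-weighted (uniform over novel cells), because a
  suitability surface anchored in the native niche carries no information
  about climates outside it. The remaining fraction is kept inside the
  envelope so the injected expansion is exactly the target. Points are
  jittered uniformly within their cell.
* **Polygons** are a regular rectangular tessellation with known
  centroids.

Default cohort conditions: 30 species cycling over shift magnitudes
{0, 1, 2, 3} (pooled-SD units, along the environmental direction
separating the windows) × target expansion {0, 0.25, 0.5, 1.0}; 200
native / 100 non-native points; 17 layers at pairwise correlation 0.6
(real bioclim variables are strongly correlated) on a 50 × 50 one-degree
grid; ≈ 17% of species labelled invasive (the label is an external input
in real analyses, so it is assigned at random here).

What the generator does *not* emulate: realistic continental outlines and
spatial sampling bias, temporal spread dynamics, species interactions,
label–trait dependence, and non-Gaussian suitability. Passing tests
therefore demonstrate the correctness and calibration of the machinery,
not ecological conclusions about any real assemblage.

## Numerical conventions

* Availability threshold: a bin counts as available when `e` exceeds
  1e-12 of total availability mass (within the masked support).
* Equivalency p uses add-one smoothing; ties count toward the null.
* k-means dispersion grouping warns and reduces k when fewer distinct
  (richness, Q) points than clusters exist.
* Every stochastic stage derives its seed from the master seed and a
  stage/species tag via SHA-256, so results are reproducible and adding a
  species never perturbs another's draws.
* Problem sizes in the validation suite (20 seeds per recovery point,
  200 trials × 199 permutations for calibration, 50 000 importance
  samples for the hypervolume benchmark) were chosen to keep Monte-Carlo
  error comfortably below the tolerances being checked.

## Known limitations

* The 1-D axis cannot register novelty orthogonal to the between-class
  direction; expansion is measured, as in the underlying framework, along
  the axis of maximal separation only.
* Greedy thinning depends on input order (documented, deterministic);
  sorted input gives fully reproducible output.
* The k-means dispersion grouping approximates the richness–diversity
  clustering of prior work without reproducing its exact algorithm.
* Hypervolumes depend on the shared bandwidth and mass quantile; only
  comparisons under identical settings are meaningful.
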