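# nicheshift

Climatic niche-shift analysis between the native and non-native ranges of
introduced species.

When a species establishes outside its native range, its realized climatic
niche — the set of climates it actually occupies — may or may not track the
native one. `nicheshift` quantifies that shift and relates it to the
species' geography, for invasion biologists and macroecologists working
with labelled occurrence data (species, native/non-native status,
coordinates) and a stack of bioclimatic raster layers:

* **Niche overlap (Schoener's D)** — occurrences of both ranges are
  standardised, reduced by PCA, and projected on the between-class axis
  separating native from non-native climates the most; occurrence and
  climate-availability densities are kernel-smoothed on a common 100-bin
  grid, giving corrected occupancies `z ∝ o/e`, and
  `D = 1 − ½ Σ|z_nat − z_non|` (0 = no overlap, 1 = identical).
* **Expansion** — the percentage of non-native occupancy on climates
  absent from the native niche (`z_nat = 0`), classed non-significant
  (< 10%) or significant (≥ 10%).
* **Niche equivalency test** — pooled occurrences are re-split 1000 times
  at the observed ratio; equivalency is rejected when the observed D falls
  below 95% of the simulated values (Benjamini–Hochberg adjusted across
  species).
* **Geographic dispersion** — polygon richness and Rao's quadratic entropy
  `Q = Σᵢⱼ pᵢ pⱼ dᵢⱼ` over occupied-polygon centroids, with k-means
  grouping into regional / transcontinental / global species.
* **Native niche volume** — the q = 0.95 mass volume of a Gaussian KDE of
  the native occurrences in a shared all-climates PCA space, with a single
  bandwidth fixed across species.

A seeded virtual-species generator (`nicheshift.synthetic`) produces
climate rasters, occurrences with known true niche shift and expansion,
and polygon maps, so the whole pipeline can be validated end-to-end
against ground truth. See `docs/methods.md` for the models, defaults and
design decisions.

## Worked example

Simulate a six-species cohort and run the full pipeline:

```python
from nicheshift.pipeline import CohortSpec, RunConfig, run_all, simulate_cohort

spec = CohortSpec(n_species=6, seed=0)
stack, occ, polys, truth = simulate_cohort(spec, out_dir="demo_fixture")
cfg = RunConfig(fixture_dir="demo_fixture", output_dir="demo_results",
                equivalency_reps=199, seed=0)
table = run_all(cfg)["species_table"]
```

which prints (merged with the generator's truth for context):

```text
species  shift_magnitude  target_expansion  n_native  n_nonnative     D  expansion_pct expansion_class  p_equiv_adj  richness  hypervolume            group
  sp001            0.000             0.000       165           68 0.656          1.315             low        0.005        66       24.984         regional
  sp002            0.000             0.250       165           75 0.613         35.402            high        0.005        79       25.261 transcontinental
  sp003            0.000             0.500       163           89 0.444         48.739            high        0.005        88       25.718           global
  sp004            0.000             1.000       172           91 0.047         93.813            high        0.005        78       25.451 transcontinental
  sp005            1.000             0.000       166           76 0.427         11.570            high        0.005        63       26.139         regional
  sp006            1.000             0.250       173           78 0.615         35.777            high        0.005        80       26.616 transcontinental
```

Reading the rows: the species simulated with no niche shift and no forced
expansion (sp001) keeps a high overlap (D = 0.66) and negligible expansion;
injected expansion fractions of 0.25/0.5/1.0 are recovered as ≈ 35/49/94%
of non-native occupancy in novel climates, and overlap collapses (D = 0.05)
when the whole non-native niche is novel. The equivalency test rejects
niche equivalency for every species (adjusted p = 0.005 at 199
permutations) — expected, since even an unshifted species occupies a
different available climate space in its new range. Richness, Rao entropy
and the fixed-bandwidth hypervolume feed the downstream group comparisons
(Kruskal–Wallis, chi-squared, Dunn, Kendall's tau) written to
`demo_results/reports.json`.

The same pipeline is scriptable from the shell:

```bash
nicheshift simulate demo_fixture --n-species 6 --seed 0
nicheshift run-all demo_fixture --out demo_results --seed 0 --reps 199
```

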