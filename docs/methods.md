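# Methods

This note documents the models behind `climprior`, the defaults and why
they are set where they are, what the synthetic generator does and does not
emulate, and the numerical choices that make runs reproducible.

## Grid and coordinate conventions

The study region is a regular latitude–longitude grid (default 40×40 cells
of 0.1°). Cells are indexed (row, col) from the lower-left, 0-based; in-mask
cells get contiguous ids 0..N−1 in row-major order, and all geometry uses
cell centers. Distances are computed in projected cell units with a single
isotropic factor of 111.32 km/degree and no latitude correction: the grid
is treated as effectively equal-area, which keeps dispersal kernels
radially symmetric and makes every distance testable in closed form. Any
cell the study mask marks is in the analysis; there is no partial-cell
handling.

Grid layers are exchanged as ESRI ASCII (.asc) with NODATA defining the
mask; matrices as (species_id, cell_id, value) CSV triplets. All CSV floats
are printed with 9 significant digits so identical runs are byte-identical.

## Synthetic study system

The generator stands in for rasterized range maps and downscaled climate
surfaces, with exact ground truth for recovery testing.

**Climate.** Four bioclimatic variables (annual mean temperature,
temperature seasonality, annual precipitation, precipitation seasonality)
are linear south–north / west–east gradients plus spatially autocorrelated
noise (moving-average-smoothed white noise, rescaled to unit variance, then
scaled per variable). The default temperature span across the grid is
16 °C: the desk-scale domain stands in for a whole biome's effective
climatic span (latitude plus elevation), and this span sets how severe a
3–4.4 °C warming is relative to the landscape. Future scenarios add a
uniform warming offset (defaults 3.1, 3.75, 4.4 °C — the span of
equilibrium climate sensitivities across circulation models), an optional
south–north tilt of that warming, and a precipitation multiplier (defaults
0.95, 0.92, 0.90).

**Species.** A species is a bioclimatic envelope: it occupies exactly the
cells whose axis-scaled (diagonal-Mahalanobis) climate distance to its
niche centre is ≤ 1.96, with the same rule re-evaluated under every future
climate. Niche centres are the standardized climate of randomly drawn
in-mask cells (so every species has a viable current range); per-variable
breadths are log-normal with log-mean log(0.55) and log-SD 0.35. These
breadths were chosen so the realized assemblage looks like a hotspot fauna
of mostly restricted-range species — median range fraction ≈ 0.2 of the
landscape — and so that, under the default warming, the assemblage shows
the qualitative regime the method is designed for: mean range contraction
of roughly half, a small fraction (~5–10%) of regional extinctions, and
measurable poleward centroid shifts. Species whose current range would hold
fewer than `min_range_cells` (default 5) cells are redrawn, keeping
calibration splits and pseudo-absence selection well-posed. IUCN categories
are drawn from a fixed mixture (50% LC, 10% NT, 15% VU, 5% DD, 12% EN,
8% CR); the mixture is a config default, not a claim about any real fauna.

**Landscape.** Protected cells number round-half-up(pa_fraction·N)
(default fraction 820/11461 ≈ 7.2%) and are spatially clumped by growing
patches from random seeds. Vegetation fraction is a logistic transform of
smoothed noise, in [0, 1], spatially independent of the species — a
deliberately conservative choice that makes the vegetation feature a pure
competitor for selection rather than a correlate of richness.

**What the generator does not emulate.** Real range-map geometry (ranges
here are climate isoclines, not expert polygons), dispersal-limited or
interaction-limited occupancy (truth ranges assume unlimited dispersal and
no biotic interactions), observation error in occurrences, coastline/biome
shape, and any correlation between vegetation, protection and biodiversity.
Passing recovery tests therefore show the pipeline recovers a known
climate-driven signal through its own machinery — not that it would be this
accurate on real data.

## Niche-modelling stage

Labelled data per species: all presence cells, plus an equal number of
pseudo-absences sampled (seeded) from the cells outside the species' 95%
per-variable percentile envelope; if that pool is too small the remainder
comes from unoccupied in-envelope cells. The 1:1 ratio is a fixed design
choice. Splits are 75/25 stratified by label, repeated 50 times.

The three reference suitability methods deliberately span the main
modelling paradigms behind one fit/predict contract:

* **envelope** (presence-only): per variable, twice the smaller tail
  percentile rank of the cell's value within the calibration presences;
  suitability is the minimum over variables.
* **logistic** (presence/absence): L2-regularized logistic regression on
  standardized climate plus squared terms.
* **distance** (presence-only): 1 − (scaled Euclidean distance to the
  presence climate centroid)/3, clipped to [0, 1].

The binarization threshold is chosen among observed suitability values to
maximize sensitivity + specificity on the validation cells (ties to the
lower threshold — more inclusive ranges), refit per repetition; the
threshold and model fitted on current climate are reused for every future
projection (the transferability assumption). Per (species, method,
scenario), the final binary map is the majority vote across the 50
repetitions; the method's skill weight is its mean validation TSS.

## Ensemble, turnover, uncertainty

Consensus: TSS-weighted frequency over methods (current) or over
method × scenario combinations (future), thresholded inclusively at 0.5.
Negative-TSS methods are clamped to weight zero rather than dropped, so a
worse-than-random model can never vote but the model count stays stable.

Turnover = (G + L)/(S + G); cells empty in both periods get 0.

The uncertainty map is a cellwise two-way ANOVA without replication on the
method × scenario table of **future** richness (current projections do not
vary by scenario, so the factorial table is only complete for the future;
the current-period cost reuses the same map). The residual sum of squares
is computed directly from the interaction deviations
(x − rowmean − colmean + grand)², not by subtraction, so tables with pure
main effects give an exactly zero residual and an uncertainty proportion of
exactly 1. The proportion's numerator is SS_method + SS_gcm by default
(`anova_numerator: main_plus_interaction` switches to the full numerator).
Cost c_i = 1 + proportion keeps costs ≥ 1, so marginal-loss division is
always defined and uncertainty at most doubles a cell's price.

## Dispersal stage

D_j is the Euclidean distance between the centroids (unweighted means of
occupied cell centers) of the species' current and future consensus maps.
The smoothing kernel is exp(−α_j d) with α_j = 2/D_j — the standard
conversion of a dispersal distance into a negative-exponential kernel
width, under which the weight at distance D_j is e⁻² of the center —
truncated at 3·D_j (residual mass ≈ 0.25%) and renormalized to sum 1.
D_j = 0 degenerates to the identity kernel. Smoothing conserves mass on the
mask exactly: each source cell's kernel is renormalized over its in-mask
targets (two convolutions), so the smoothed layer sums to the occupied-cell
count.

The combined feature is the cellwise geometric mean of the smoothed current
and future layers (alternatives `min` and `product` are selectable):
geometric mean zeroes exactly where either period is unsuitable while
keeping units comparable to occupancy. Species regionally extinct in the
future (or with disjoint smoothed supports) contribute their smoothed
current layer instead, flagged, so they still value present-day sites.
Centroids are computed on consensus maps, not per-model maps; per-model and
frequency-weighted variants were evaluated and gave no systematically
better shift recovery.

## Prioritization stage

Exact greedy reverse elimination with full marginal-loss recomputation each
step (no batched removal by default): N is desk-scale here, and exactness
is what enables brute-force oracle equivalence tests. Ties in δ break
toward the lower cell id, making ranks bit-reproducible. Locked cells are
never candidates; their feature content counts toward Q_j throughout, and
they occupy the top |locked| ranks, internally ordered by marginal loss at
termination. Feature layers are normalized to Σ_i q_ij = 1 at problem
build; z defaults to 0.25 (the conventional additive-benefit concavity —
strong enough to protect rare features, mild enough to reward richness);
the basic core-area rule (max over features) is also implemented, and the
additive benefit function is the default for headline runs.

The three published solution variants are three feature sets over the same
engine: current consensus, future consensus (species with no future range
are necessarily absent from this variant), and the combined smoothed
features. The vegetation layer enters each variant unsmoothed at weight 5;
the "full combination" map is the cellwise union of the three top-fraction
sets. Coverage reports use n_top = round-half-up(fraction·N) selected
cells; at the reference scale (N = 11,461, 820 locked, 17% target) this
yields 1948 cells and an additional-protection share of 9.8%.

## Reproducibility and problem sizes

One global seed expands into per-stage and per-species substreams by stable
SHA-256 hashing of string keys, so adding a species or reordering stages
does not perturb other draws. The default study conditions — 40×40 cells,
30 species, 3 scenarios, 50 repetitions — are the package's desk-scale
reference: the full pipeline runs in well under a minute on one CPU, and
every recovery statistic quoted in the README comes from exactly this
configuration. Tests use a 16×16/8-species/8-repetition configuration where
only plumbing (not statistical power) is under test.

## Known limitations

* Greedy ranking is a heuristic: it makes no optimality guarantee, and in
  particular it does not guarantee that every feature is retained at least
  proportionally in a top-fraction extract. Widespread low-weight species
  can fall below proportional representation when rare or heavily weighted
  features dominate the marginal-loss signal — the price of the
  complementarity curve shape, visible in the per-feature performance
  curves.
* Centroid-shift estimates inherit the disagreement between suitability
  methods; on small grids, rank agreement between estimated and true shifts
  is imperfect (ρ ≈ 0.7–0.9 across seeds at default conditions) even though
  the estimator is exactly consistent when the projections are exact.
* The ANOVA uncertainty layer treats methods and scenarios as fixed
  factors without replication; the interaction is not separable from
  noise.
* No boundary-length penalty, land cost, or condition/retention layers;
  connectivity enters only through distribution smoothing.
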