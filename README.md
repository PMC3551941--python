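# climprior

Dynamic spatial conservation prioritization under climate change, as a
tested, reusable pipeline: ensemble ecological niche modelling with
uncertainty quantification, climate-forced dispersal encoded as
distribution-centroid shifts, and greedy complementarity-based site ranking
with feature weights, costs and locked protected areas.

**Who it is for.** Conservation planners and macroecologists who want to
rank grid cells of a study region by conservation value when species
distributions are projected to move — and who need every stage (niche
models, consensus, variance partition, dispersal kernels, site ranking) to
be inspectable and testable. A synthetic-data module generates climate
layers, climatically-determined species ranges, protected areas and
vegetation with known ground truth, so the whole pipeline runs and is
validated without any external download; each stage equally accepts user
grids in ESRI ASCII / CSV form.

## The method

**Niche models.** Each species' presence/absence data (presences from its
range map; pseudo-absences sampled outside the 95% per-variable percentile
envelope of its presence climate) are split 75/25 into calibration and
validation, stratified by label, 50 times. Three reference suitability
methods (percentile bioclimatic envelope, regularized logistic regression
with squared climate terms, climate-centroid distance) are fitted per
split, thresholded at the suitability value maximizing sensitivity +
specificity, scored by the True Skill Statistic (TSS = sensitivity +
specificity − 1), and projected onto current and future climates with the
current-fitted model.

**Ensemble consensus.** Binary projections are combined into a per-cell
frequency weighted by each method's TSS (negative-TSS models get weight 0);
a cell is a consensus presence where the frequency is ≥ 0.5. Per-cell
species turnover between periods is (G + L)/(S + G), with S current
richness, G gains and L losses. A cellwise two-way ANOVA without
replication on the method × scenario future-richness table splits
projection variance into SS_method + SS_gcm + SS_residual; the proportion
of the two main effects in the total becomes the prioritization cost
c_i = 1 + proportion, so climatically uncertain cells are dearer.

**Climate-forced dispersal.** For each species, the Euclidean distance D_j
between the centroids of its current and future consensus distributions is
the displacement its suitable climate imposes. D_j parameterizes a
negative-exponential smoothing kernel with decay α_j = 2/D_j (truncated at
3·D_j, renormalized); convolving each period's occupancy with the kernel
and taking the cellwise geometric mean yields a feature layer that values
only sites useful in both periods, connected at the species' own scale.

**Prioritization.** A reverse greedy ranking repeatedly removes the
unlocked cell with the smallest marginal loss δ_i, under either the
core-area rule δ_i = max_j w_j q_ij / (c_i Q_j(S)) or the additive benefit
function δ_i = (1/c_i) Σ_j w_j [V(Q_j(S)) − V(Q_j(S) − q_ij)] with
V(Q) = Q^z (default z = 0.25). Here q_ij is feature j's normalized
representation in cell i and Q_j(S) its fraction remaining. Weights follow
IUCN categories (LC/NT 1, VU/DD 2, EN 3, CR 4); a natural-vegetation
feature carries weight 5; established protected areas are locked at the top
of the ranking. The top 17% of cells (the CBD terrestrial coverage target)
is extracted for three feature sets — current-only, future-only and
dispersal-aware — plus their union.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic conditions (40×40 grid of 0.1° cells, 30 species, 3 warming
scenarios of 3.1–4.4 °C, seed 1), writing everything under `results/run/`:

```bash
python analysis/01_simulate.py
python analysis/02_fit_niche_models.py
python analysis/03_ensemble_consensus.py
python analysis/04_dispersal_features.py
python analysis/05_prioritize.py
python analysis/06_report.py
```

which prints, among other things:

```
species: 30; median range fraction 0.21 (min 0.017, max 0.33)
protected cells: 114 (7.1%)
...
overall mean TSS 0.942 over 4500 evaluations
...
  mean contraction 46.4% (SD 34.0, max 100.0)
  regionally extinct: 6.7% of 30 species
turnover range: 0.00 - 1.00
variance partition: methods 41.1%, scenarios 46.1%, interaction 12.8%
...
centroid shifts (km): median 67.2, range 9.3 - 226.4 (28 species; ...)
...
dispersal : top 272 cells (17%), locked 114, additional 9.9% of the landscape
...
current   : mean feature retention at top 17% = 0.26
future    : mean feature retention at top 17% = 0.46
dispersal : mean feature retention at top 17% = 0.29
```

Reading the numbers: the niche models fit the envelope-truth species well
(mean validation TSS 0.94); warming contracts consensus ranges by 46% on
average and leaves 6.7% of species with no future range in the region;
reaching the 17% coverage target requires protecting an additional 9.9% of
the landscape beyond the existing network; and the dispersal-aware plan's
retention sits between the current-only and future-only plans — it trades
some present-day representation for sites that stay valuable as ranges
move.

The same pipeline is available as a CLI
(`climprior {simulate,enm,ensemble,dispersal,prioritize,report,run}`) with
a YAML configuration; `climprior run --seed 1 --outdir run/` executes
everything and writes a manifest with config, versions and output
checksums. Identical config + seed gives byte-identical CSV outputs.

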