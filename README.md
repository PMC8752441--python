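# traitenv

Analysis pipeline for global trait–environment structure at ecoregion
scale. Starting from individual trait observations with taxonomy and
coordinates, the package:

1. **gap-fills** missing trait values with a Gibbs-sampled hierarchical
   probabilistic matrix factorization that shrinks row latent vectors
   through the taxonomy (species → genus → family), with per-value
   uncertainty (`traitenv.qc_gapfill`);
2. applies **zlog standardization and a z-score quality filter**
   (|z| > 4 removed, |z| > 3 flagged);
3. **aggregates** observations to species medians per ecoregion (A1) and
   ecoregion medians of species medians (A2), keeping ecoregions with
   >20 species covering >1% of estimated richness, and averages
   environmental variables over observation locations so sampling
   density weights the mean (`traitenv.aggregate`);
4. analyses **trait structure**: absolute Pearson correlations,
   complete-linkage clustering at the 1 − |r| distance (cut at 1.0),
   correlation-matrix PCA, a permutation test for the number of
   significant axes, and regressions of component scores on absolute
   latitude, raw and in 1° bins (`traitenv.trait_structure`);
5. **partitions explained variance** per trait between climate and soil:
   each predictor block is PCA-reduced to 20 components, ridge
   regressions (nested 10×10-fold CV over a λ grid, 50 repetitions) are
   fitted on climate-only / soil-only / combined predictors with shared
   fold layouts, and holdout r² (squared Pearson correlation of
   concatenated out-of-fold predictions) is decomposed by
   inclusion–exclusion into joint and independent effects
   (`traitenv.partition`);
6. runs a **redundancy analysis** of the ecoregion trait matrix on
   scaled climate + topsoil predictors after iterative VIF pruning
   (`traitenv.rda`).

A synthetic world generator (`traitenv.synthdata`) produces observation,
environment and ecoregion tables from a known latent structure — a
latitude-linked factor driving climate and plant size, and a fertility
factor driving soil and leaf economics, with a configurable shared
weight between the two — so every stage has a ground-truth recovery
test.

## CLI

```sh
# end-to-end run on a synthetic world
traitenv run --config config.yaml --seed 1 --outdir out/

# individual stages
traitenv simulate --outdir world/
traitenv aggregate --config config.yaml --outdir out/
traitenv axes --config config.yaml --outdir out/
traitenv partition --config config.yaml --outdir out/
traitenv rda --config config.yaml
traitenv report --rundir out/        # plots from a completed run
```

A minimal YAML config (all keys optional; unknown keys are rejected):

```yaml
mode: synthetic          # or "files" with paths under files:
seed: 1
world:
  n_species: 500
  n_ecoregions: 120
aggregate:
  min_species: 20        # strict >
  min_fraction: 0.01     # strict >, fraction of richness estimate
partition:
  repetitions: 50
  n_components: 20
rda:
  vif_exclude_above: 20
  topsoil_only: true
```

In `files` mode the three tab-delimited inputs follow the schema written
by `traitenv simulate` (`schema.json`): an observation table (taxonomy,
ecoregion, location, one column per trait, empty field = missing), an
environment table keyed by location id, and ecoregion metadata with
richness estimates.

## Layout

```
src/traitenv/
  synthdata.py        synthetic world generator + missingness injection
  qc_gapfill.py       zlog, z-filter, hierarchical gap filling
  aggregate.py        A1/A2 aggregation, environment averaging
  trait_structure.py  correlations, clustering, PCA, latitude fits
  partition.py        ridge CV + joint/independent variance partition
  rda.py              VIF pruning + redundancy analysis
  pipeline.py         config validation and orchestration
  cli.py              click-based CLI
tests/                unit, property and acceptance suites
scripts/acceptance.py acceptance report generator
```
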