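# granulefit

Analysis toolkit for binned starch-granule size distributions from
volumetric particle counters (Multisizer-class instruments): even-bin
density transformation, bimodal log-normal deconvolution into A-type and
B-type granule components, extraction of granule phenotypes, developmental
bimodality detection, and genotype comparison statistics. A built-in
simulator generates complete mock experiments (granule populations,
instrument measurement emulation, genotype panels and developmental time
courses) so every pipeline stage is testable without instrument data.

## What it computes

From one volume-percent trace per grain:

- **even-bin transform** — log-binned volume percentages are divided by bin
  width to give a volume-percentage *density*, comparable across unequal
  bins (`to_density`);
- **mixture deconvolution** — a two-component Gaussian mixture on the
  ln(diameter) axis (equivalently, two log-normals in diameter) is fitted to
  the density by bounded least squares (`fit_bimodal`). The B component's
  mixing weight is its share of total volume;
- **phenotypes** — B-type volume percentage (`100·f_B`), mean A-/B-type
  diameters (`exp(mu + sigma²/2)`; medians `exp(mu)` reported alongside),
  granules per mg of grain back-calculated through the dilution scheme, and
  the percentage of granules below 10 µm by number (`pct_small`, computed
  from the same volumetric trace via `convert_weighting`);
- **modality** — unimodal vs bimodal call per trace from a ΔAIC comparison
  of 1- and 2-component fits (`classify_modality`);
- **group statistics** — per-phenotype one-way ANOVA with Tukey-adjusted
  pairwise differences of means and 95% confidence intervals
  (`anova_oneway`, `tukey_pairwise`, `run_comparisons`).

Note on conventions: a volumetric trace is the *volume-weighted* diameter
distribution, so the fitted component parameters describe volume-weighted
log-normals. d³-weighting a log-normal (mu, sigma) gives a log-normal at
(mu + 3·sigma², sigma); the simulator's truth tables record both the
number-scale generating medians and the volume-scale medians a fit can
recover.

## Command line

```sh
# synthetic two-genotype panel: 54 traces + sample sheet + truth table
granulefit simulate --out data/panel --seed 1

# developmental time course (8/14/20/30 dpa)
granulefit simulate --timecourse --out data/tc --seed 1

# fit every trace, derive per-sample and per-plant phenotypes
granulefit fit --sample-sheet data/panel/sample_sheet.csv --out runs/panel

# genotype comparisons (ANOVA + Tukey), optional forest plot
granulefit compare --phenotypes runs/panel/phenotypes.csv \
    --out runs/panel_cmp --plots

# or everything in one go
granulefit report --sample-sheet data/panel/sample_sheet.csv --out runs/all
```

Custom simulation designs are YAML (`granulefit simulate --design d.yaml`):

```yaml
genotypes: [WT, mutant]
n_plants: 9
n_grains: 3
n_granules: 100000
cell_params:
  WT:     {f_b_volume: 0.20, median_diam_a_um: 22.0}
  mutant: {f_b_volume: 0.35, median_diam_a_um: 19.5}
# time courses key cells as "genotype@dpa":
#   WT@14: {f_b_volume: 0.0, median_diam_a_um: 17.0}
```

## File formats

A trace is delimited text (`,` for `.csv`, tab for `.tsv`) with columns
`bin_low_um, bin_high_um, value` plus constant metadata columns
(`sample_id, genotype, plant, dpa, weighting, value_kind`). This CSV is the
bridge from instrument exports: the study's raw traces are not public, so
export the instrument's binned table to this layout. Bins must be
contiguous and strictly increasing; decimal commas are rejected unless
`decimal=","` is passed. Sample sheets list one row per trace
(`sample_id, genotype, plant, dpa, grain_mass_mg, aliquot_volume_mL,
total_volume_mL, counted_granules, trace_path`).

Every `fit`/`compare` run writes its resolved configuration (JSON) and a
timestamped run log next to the output tables; unreadable traces are
recorded and skipped, with a nonzero "partial" exit status.

## Package layout

| module | contents |
| --- | --- |
| `granulefit.distributions` | `BinnedDistribution` and binning/weighting transforms |
| `granulefit.io` | trace / sample-sheet / table readers and writers |
| `granulefit.mixture` | log-normal mixture model, fitting, modality calls |
| `granulefit.phenotypes` | granules/mg, % small granules, per-plant summaries |
| `granulefit.stats` | one-way ANOVA, Tukey pairwise contrasts |
| `granulefit.simulate` | population/measurement/experiment simulator |
| `granulefit.pipeline` | run orchestration used by the CLI |
| `granulefit.cli` | `granulefit simulate / fit / compare / report` |
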