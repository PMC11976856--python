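# nanopotency

A tested pipeline for ranking nanoform cytotoxic potency from in vitro
dose-response data and relating those potencies to particle properties and
perturbed pathways:

1. **synthetic** — seeded generators for plate-level cytotoxicity readings,
   physicochemical descriptor tables (with a planted correlated
   determinant), mechanistic marker panels, and protein quantification
   matrices (with planted perturbed gene sets). Every downstream stage is
   testable offline with these.
2. **potency** — raw signals are normalized to the mean dose-0 control
   within each particle × cell line × assay × experiment group (fold effect,
   FE), the power law `FE = (dose + 1) ** beta` is fitted through the origin
   on the log-log scale, the three endpoint magnitudes (LDH, ATP, CTB) are
   averaged into a consensus `beta_avg`, and particles are dense-ranked on
   the 3-decimal-rounded consensus (ties share a rank).
3. **association** — rank-transform factorial ANOVA (Type II sums of
   squares, all two-way interactions), Holm–Sidak step-down adjustment, and
   Pearson/Spearman correlation screens of `beta_avg` against
   physicochemical descriptors (with explicit subset masks and pairwise
   missing-value deletion) or mechanistic markers (GSH/GSSG ratio,
   cytokines).
4. **enrichment** — from-scratch preranked GSEA on protein fold changes
   (weighted running-sum ES, gene-label permutation null, sign-stratified
   NES/p/FDR), deterministic hierarchical clustering of NES matrices
   (pairwise-complete correlation or Euclidean distance, average/complete
   linkage), and hypergeometric over-representation of thresholded proteins
   (fold change ≥ 1.5 or ≤ 1/1.5, p < 0.05, |z| ≥ 2).
5. **cli** — `simulate`, `potency`, `associate`, `enrich`, and `report`
   subcommands binding the stages, with YAML configuration, flag overrides,
   and reconciled per-stage run reports.

## CLI quick start

```sh
# generate all synthetic inputs into ./sim
nanopotency simulate --seed 11 --out-dir sim

# fold effects -> potency fits -> consensus -> ranks
nanopotency potency --plate sim/plate.csv --out-dir pot

# factorial ANOVA + correlation screens
nanopotency associate \
    --fold-effects pot/fold_effects.tsv \
    --consensus pot/consensus.tsv \
    --physchem sim/physchem.csv --markers sim/markers.csv \
    --cell-line A549 --out-dir assoc

# protein fold changes -> preranked GSEA -> over-representation
nanopotency enrich --treated sim/proteins_treated.csv \
    --control sim/proteins_control.csv --gmt sim/sets.gmt \
    --seed 3 --out-dir enr

# per-stage record accounting of any run
nanopotency report pot
```

All subcommands accept `--config config.yaml` (keys mirror
`nanopotency.config.PipelineConfig`); command-line flags override config
values. Stochastic stages refuse to run without a seed, and identical
config + seed reproduces byte-identical tabular outputs.

## Notes on the potency fit

- `beta` is reported as a magnitude (`|slope|`); endpoints that decline
  with dose (ATP, CTB) fit a negative slope, preserved in
  `signed_slope`.
- The standard error of `beta` propagates both the per-well log-FE noise
  and the variance of the shared dose-0 control mean each experiment
  divides by; with the naive residual-only SE, the interval
  `beta ± 2·SE` covers the truth far less often than nominal because all
  fold effects within an experiment share one noisy denominator.
- The `(dose + 1)` offset makes the model unit-dependent: doses are in
  μg/cm².
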