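# snpower

Simulation-based power and sample-size calculation for a single bi-allelic
candidate SNP, plus a study of what it costs to analyze a truly dominant
variant under the (incorrect) additive genotype coding.

## What it does

* **Synthetic cohorts** (`snpower.simcohort`): two independent
  Bernoulli(MAF) allele vectors per individual (Hardy-Weinberg), genotype
  coded as a carrier indicator (dominant/"binary" model) or allele count
  (additive model). Binary outcomes come from a logistic linear predictor
  with a zero-mean normal subject effect whose SD is derived from a
  "baseline odds ratio" (the 95th-vs-5th population risk percentile
  contrast); continuous outcomes are Gaussian around the linear predictor.
* **Inference** (`snpower.inference`): intercept+slope GLM fit (logistic
  via exact Newton iterations on per-genotype-class sufficient statistics;
  Gaussian via OLS) and a two-sided large-sample Wald z test.
* **Power engine** (`snpower.power_engine`): empirical power at fixed n
  over Monte-Carlo replicates, and sample-size search (geometric
  bracketing then bisection on n) to a target power.
* **Misspecification study** (`snpower.misspec_study`): paired
  comparisons — each simulated cohort is generated under the dominant
  truth and fitted under *both* codings — yielding power loss,
  sample-size inflation and effect-size shrinkage across MAF and
  effect-size grids.

Every replicate draws its RNG substream from the scenario seed by
counter-based splitting, so all results are bitwise reproducible.

## CLI

Subcommands: `power`, `samplesize`, `maf-sweep`, `effect-sweep`. Scenario
parameters come from a YAML/JSON config (see `examples/binary_design.yaml`);
`--seed/--reps/--alpha` override it, `--out` writes a tidy CSV plus a run
manifest, `--dry-run` prints the expanded scenario grid, and `--plots`
(sweeps) writes PNG line plots.

```sh
snpower power      --config examples/binary_design.yaml --out results/power.csv
snpower samplesize --config examples/binary_design.yaml --out results/n.csv
snpower maf-sweep  --config examples/binary_design.yaml \
    --maf-grid 0.008,0.025,0.1 --out results/maf_sweep.csv --plots results/plots
snpower effect-sweep --config examples/binary_design.yaml --out results/effects.csv
```

A config with `maf_grid` / `effect_grid` keys expands to the cartesian
product of scenarios, each with a deterministic child seed.

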