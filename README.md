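# stresscomp

Reproducible analysis pipeline relating children's salivary biomarker
trajectories (cortisol and cell-free DNA) to the closed three-part
composition of their in-school activity time (sedentary behavior / light /
moderate-to-vigorous physical activity), via four Bayesian hierarchical
linear models with group-specific compositional ridge slopes — plus a
synthetic-cohort generator so every stage runs and is testable without any
external dataset.

## Pipeline stages

| stage | module | what it does |
|---|---|---|
| simulate | `stresscomp.synthetic` | seeded cohorts: diurnal log-scale trajectories, 3-state epoch counts, missingness |
| compose | `stresscomp.accelerometry` | cut-point classification of epoch counts, closure to an SB/LPA/MVPA composition, compositional (geometric) means |
| indices | `stresscomp.indices` | natural-log transform, then peak reactivity (PR, change from baseline per timepoint) and AUC-with-respect-to-increase (AUCi) |
| fit | `stresscomp.bhlm` | four hierarchical models (cortisol/cfDNA × PR/AUCi) with a self-contained Gibbs-within-slice MCMC sampler |
| diagnose | `stresscomp.diagnostics` | split-chain Rhat, Geyer ESS, DIC (pD variant), posterior predictive checks, credible-interval classification and coefficient plots |

Model structure: `y = alpha[id] + beta_cmp(group) · (SB, LPA, MVPA) +
season + gender (+ timepoint) + noise`, where the six group-specific
composition slopes share a Normal ridge prior centered on a scalar
hyperparameter (`mu_alpha`). Because each composition row sums to one,
that shared center plays the role of the grand intercept ("alternative
hierarchical centering"), and the ridge controls the collinearity of raw
compositional covariates without log-ratio transforms.

## CLI

```bash
stresscomp run-all  --seed 1 --out-dir results/      # everything, defaults
stresscomp simulate --config config.yaml             # just the tables
stresscomp fit --config config.yaml --model BHLM1 --model BHLM4
```

A YAML config mirrors `stresscomp.pipeline.PipelineConfig`:

```yaml
seed: 1
out_dir: results
models: [BHLM1, BHLM2, BHLM3, BHLM4]
cohort: {n_ig: 37, n_cg: 11}
mcmc: {chains: 3, iterations: 50000, burn_in: 25000, thinning: 10}
cutpoint_preset: romanzini_vm
epoch_length_s: 15
```

Every CSV/JSON artifact is stamped with a config hash and the seed;
reruns under the same config are byte-identical, and artifacts from
different configs refuse to be joined. Exit codes: 0 ok, 1 validation
failure, 2 runtime failure.

Real data can be supplied instead of the generator
(`synthetic: false` plus `students_csv` / `saliva_csv` / `counts_csv`):
`students.csv` (id, group ∈ {CG, IG}, gender), `saliva.csv`
(id, season, time_h, cortisol, cfdna), `counts.csv`
(id, season, epoch_start_s, vm_counts).

## Conventions and switches

- The second argument of every Normal prior is read as a **precision**
  (the JAGS convention); `PriorSet(normal_arg="variance")` flips this.
- Half-Cauchy scale priors sit on the **standard deviations**;
  `half_cauchy_on="variance"` flips this.
- The `romanzini_vm` cut-point preset (SB ≤ 180, MVPA ≥ 757 vector-
  magnitude counts per 15 s epoch) is configuration, not a constant —
  confirm the numbers against the original calibration study before
  substantive use.
- PR defaults to change-from-baseline per post-baseline timepoint
  (`pr_definition: per_timepoint`); a max-minus-baseline variant is
  available (`max`).

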