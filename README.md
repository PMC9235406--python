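# artbayes

Hierarchical Bayesian analysis of a sequential risk-taking ("angling")
task: casts earn points, a per-cast loss probability ends the trial and
forfeits them, and each cast/collect decision is a Bernoulli draw from a
2-parameter cognitive model — risk propensity `gamma_plus` (which sets the
internal cast target `omega = -gamma_plus / log(1 - p)`) and behavioural
consistency `beta` (the steepness of the logistic cast probability
`1 / (1 + exp(beta * (l - omega)))`).

The package covers the full pipeline:

- **`artbayes.task`** — probability schedules (0.05 rising to 0.30 in the
  canonical 30-trial design), geometric pre-generated max-cast sequences,
  and within-block reordered task versions (A/B/C).
- **`artbayes.model`** — the cognitive model and the censored Bernoulli
  likelihood of observed play (forced-fail trials censor the collect
  decision).
- **`artbayes.simulate`** — synthetic agents, lognormal-hierarchy cohorts,
  and covariates with exact target correlations to the generating
  parameters.
- **`artbayes.inference`** — hierarchical Bayesian fits (per-group
  lognormal hierarchies, weakly-informative priors) via an adaptive
  Metropolis-within-Gibbs sampler with non-centred interweaved hyper
  updates; split R-hat / ESS diagnostics in **`artbayes.diagnostics`**.
- **`artbayes.stats`** — adjusted scores, default-prior (JZS) Bayes factors
  for two-sample and one-way designs, permutation tests, Pearson
  associations with optional log transform, and TIV volume normalisation.
- **`artbayes.io`** / **`artbayes.cli`** — tidy CSV formats, YAML/JSON
  configuration, manifests, and the end-to-end CLI.

## CLI

All subcommands read a YAML/JSON config (see `tests/test_io_cli.py` for a
worked example) and accept `--seed`, `--out`, `--log-level`, `--json-logs`:

```sh
artbayes run --config config.yaml --out results/      # full pipeline
artbayes simulate --config config.yaml                # designs + cohort + covariates
artbayes fit --config config.yaml                     # hierarchical fit of a gameplay CSV
artbayes score --config config.yaml                   # + adjusted scores, point estimates
artbayes associate --config config.yaml               # + Pearson associations
artbayes report --config config.yaml                  # + Markdown summary report
```

A run writes `design.csv`, `gameplay.csv`, `truth.csv`, `covariates.csv`,
`posterior_summary.csv`, `draws.csv`, `diagnostics.csv`,
`point_estimates.csv`, `scores.csv`, `associations.csv`, `report.md`, the
resolved config, and a `manifest.json` (config hash + seed). Re-running
with the same config and seed reproduces the simulation outputs byte for
byte.

## File formats

Gameplay CSV (one row per trial, 1-based trial indices):

```
subject_id,group,version,trial,p_yellow,max_casts,n_casts,outcome,points_banked
```

with `outcome` in `{collected, forced_fail}`. Design CSV:
`version,trial,p_yellow,max_casts`. Posterior draws:
`group,parameter,chain,draw,value`.
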