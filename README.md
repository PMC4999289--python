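# nmareg

Bayesian network meta-analysis and meta-regression for arm-level binary
outcomes, built around a 15-comparator stroke-prevention evidence network:

- **Unadjusted NMA** — binomial likelihood, logit link, fixed or random
  effects with the standard multi-arm correlation-½ construction, vague
  priors (Normal(0, 100²) effects, Uniform(0, 2) between-study SD).
- **Meta-regression** — a single study-level covariate with one common
  interaction coefficient versus the reference treatment, so contrasts
  between non-reference treatments are covariate-free by construction.
- **Baseline-risk adjustment** — the covariate is the *latent* trial
  baseline log-odds (exchangeable across trials), propagating its
  estimation uncertainty into the coefficient and avoiding the
  regression-dilution bias of plugging in observed baseline rates.
- **Model criticism** — per-point residual deviance, pD, DIC, leverage
  coordinates with the c = x² + y threshold family (flagging at c = 3),
  split-chain Brooks-Gelman-Rubin diagnostics and autocorrelations.
- **Synthetic networks** — a seeded generator of star-like connected
  networks with known truth (trial baselines, effects, heterogeneity,
  interactions, naturally arising zero-event arms) powering all
  parameter-recovery and dilution tests.

Sampling is a self-contained adaptive Metropolis-within-Gibbs engine
(vectorized study-level block updates plus funnel-crossing joint rescale
and translation moves); no external probabilistic-programming framework is
required.

## Command line

```sh
nmareg simulate --seed 1 --out simdata            # synthetic 19-study network
nmareg describe --arms simdata/arms.csv --covariates simdata/covariates.csv \
    --coding simdata/coding.txt --anchor adjusted_dose_VKA
nmareg fit --config run.yaml --seed 1 --out results
nmareg compare-covariates --config run.yaml --out results
```

A run config looks like:

```yaml
arms: simdata/arms.csv
covariates: simdata/covariates.csv
coding: simdata/coding.txt
model: {effect: RE}
covariate: {name: follow_up}        # omit for unadjusted; or "baseline_risk"
mcmc: {chains: 3, burn_in: 50000, samples: 50000, seed: 1}
decision_set: [adjusted_dose_VKA, apixaban, rivaroxaban, dabigatran_150, edoxaban_60]
forest_reference: adjusted_dose_VKA
out: results
```

`fit` writes the posterior summary, a league table of all K(K−1)/2 pairwise
odds ratios, a forest table versus the chosen reference, per-point
diagnostics/leverage coordinates, a convergence report and a reproducible
run manifest (seed, config hash, versions). `compare-covariates` fits the
four covariate models plus the baseline-risk model, each paired with a
matched unadjusted fit on the same reduced data, and writes a comparison
grid (interaction coefficient, DIC difference, residual deviance,
between-study SD).

## Covariate units

Percent covariates (previous stroke/TIA, proportion male) are regressed
per percentage point, age per year, follow-up per year (stored as months,
scaled by 1/12 at attachment); covariates are centered at the mean of the
retained studies. Override via `attach_covariate(..., scale=...)`.
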