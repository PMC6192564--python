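# ppickd

Cohort analysis of proton-pump-inhibitor (PPI) exposure and incident
chronic kidney disease (CKD), built as a tested, reproducible pipeline for
pharmacoepidemiologists working with EHR-style longitudinal data:
participant registries, dated prescriptions, laboratory panels and
diagnosis flags.

The pipeline covers:

* **Renal phenotyping** — eGFR from serum creatinine (CKD-EPI 2009),
  incident CKD defined as eGFR < 60 mL/min/1.73 m² and/or UACR ≥ 30 mg/g
  in two or more determinations spanning at least 3 months, and exclusion
  of prevalent cases detected during a first screening year.
* **Exposure construction** — prescriptions merged into exposure episodes
  (consecutive prescriptions chain; a configurable grace period), per-drug
  standard/high dose classification, cumulative-duration categories, and
  never / baseline / follow-up user strata.
* **Andersen–Gill restructuring** — each participant's follow-up is split
  into start–stop risk intervals at every covariate change point, with
  delayed entry (left truncation) preserved.
* **Hazard modelling** — a Bayesian piecewise-exponential proportional
  hazards model

  &nbsp;&nbsp;&nbsp;&nbsp;*h<sub>i</sub>(t) = exp( λ<sub>b(t)</sub> +
  x<sub>i</sub>(t)ʹβ + u<sub>i</sub> + s<sub>g(i)</sub> )*

  with a random-walk-smoothed piecewise-constant log baseline hazard λ,
  fixed effects β, iid Gaussian frailty *u* and a Matérn-covariance spatial
  effect *s*, fitted by an empirical-Bayes Laplace approximation under
  penalised-complexity (PC) priors. The piecewise-exponential likelihood is
  handled through its exact Poisson equivalence (interval pieces with
  log-exposure offsets).
* **Reporting** — Kalbfleisch–Prentice survival curves (≡ Kaplan–Meier at
  unit weights) honouring delayed entry, log-rank tests, and stratified
  descriptive tables with chi-squared comparisons.
* **Synthetic cohorts** — a generator that draws event times exactly from
  the model above, realises exposure as dated prescriptions and lab visits
  whose values cross the diagnostic thresholds at the latent event time,
  and keeps the ground truth for parameter-recovery testing.

## Worked example

```bash
ppickd all --seed 1 --outdir run
```

simulates a 2 000-participant cohort under the default conditions (8-year
window, staggered entry, ~25 % baseline PPI users, true PPI hazard ratio
1.30, frailty SD 0.3) and runs every stage. `run/coefficients.tsv` then
holds the adjusted fixed effects, e.g.:

```
name          mode     sd      hr     hr_low  hr_high
ppi           0.2215   0.0871  1.2480 1.0521  1.4804
age70         0.7915   0.1008  2.2068 1.8112  2.6887
female        -0.0237  0.0801  0.9765 0.8346  1.1426
hypertension  0.0407   0.1091  1.0416 0.8411  1.2898
diabetes      0.4292   0.1068  1.5361 1.2459  1.8938
```

`hr` is the posterior-mode hazard ratio for incident CKD with its 95 %
credible interval: here ever-use of a PPI multiplies the CKD hazard by
1.25 (CrI 1.05–1.48), covering the generator's true value 1.30, with the
remaining rows consistent with their true effects (2.39, 1.04, 1.17, 1.43)
within posterior uncertainty. `run/fit.json` records the optimised
hyperparameters (frailty SD, random-walk smoothness), `run/survival_curves.tsv`
the CKD-free curves per PPI stratum, and `run/log_rank.json` their
comparison.

Each stage is also exposed as a subcommand (`simulate`, `phenotype`,
`exposure`, `split`, `fit`, `report`) and as plain library functions
(`ppickd.analyze` runs the chain on in-memory tables).

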