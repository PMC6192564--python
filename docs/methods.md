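# Methods

## Outcome definition and phenotyping

Incident CKD is a binary, once-only outcome defined on laboratory
determinations: a determination *qualifies* when eGFR < 60 mL/min/1.73 m²
or UACR ≥ 30 mg/g (either analyte; a date with both counts once), and a
participant becomes incident when some qualifying determination lies at
least 90 days after the earliest qualifying one, both inside the
participant's follow-up window. eGFR comes from the CKD-EPI 2009
creatinine equation; the race factor defaults to non-black (the target
setting is Spanish primary care) but is a parameter.

Conventions chosen where the clinical rule leaves room:

* **Months are 30 days**; "3 months" is exactly 90 days. Calendar-month
  arithmetic was rejected for determinism.
* **Qualifying determinations need not be consecutive** — intervening
  normal values do not reset the confirmation clock. This is the most
  inclusive reading and the one the order-invariance property requires.
* **Event date = the confirming (second qualifying) determination**,
  because chronicity is only established then. Dating the event at the
  first qualifying determination is a configuration switch
  (`event_rule="first"`).
* **Prevalent-CKD exclusion** applies the same two-determination rule to
  determinations inside the first study year `[0, 365)`; survivors'
  at-risk time starts at `max(entry, 365)` — the first year is a screening
  window, not follow-up. Whether a single abnormal first-year value should
  exclude is genuinely open; the symmetric (two-determination) choice
  keeps the exclusion and incidence definitions identical.

Derived clinical covariates (hypertension, high-normal BP, type-2
diabetes, impaired fasting glucose, obesity, low HDL,
hypertriglyceridemia, metabolic syndrome = ≥ 3 of the 5 components) follow
the usual primary-care operational rules, with three-valued logic: a flag
whose inputs are missing is `None` (unknown), never silently false.

## Exposure construction

Exposure to a PPI runs from the prescription date for its calculated
duration — the recorded treatment days when present, otherwise
⌈quantity / daily dose⌉. Prescriptions whose gap to the running episode is
at most the grace period merge into one episode; the default grace is
0 days (the strict reading of "consecutive"), configurable to 30, because
the clinical definition of "consecutive prescriptions" is not sharp. A
merged episode is high-dose if any constituent is. Standard/high dose
thresholds per drug: 20 mg for omeprazole, esomeprazole and pantoprazole,
15 mg for lansoprazole, 10 mg for rabeprazole; anything above the printed
high range (e.g. omeprazole 80 mg) is still "high" (open upper bound,
logged). Cumulative exposure is the running sum of episode lengths
(piecewise linear in time, slope 0 or 1); duration categories are the six
regulatory bins {<1, 1–3, 3–6, 6–12, 12–24, >24 months} with half-open
boundaries at {30, 90, 180, 360, 720} days, plus the collapsed
{<1, 1–3, 3–6, >6} scheme. User strata: *baseline* if any episode
intersects the first study year (the default reading of "user at the basal
visit"; active-on-entry is the alternative), *follow-up* if exposure
starts later, *never* otherwise.

## Counting-process restructuring

The analysis time scale is days since study start with left truncation at
the individual entry day; age enters as the time-varying ≥ 70 indicator,
not as the time scale. Each participant's follow-up is split at every
covariate change point: exposure start/end, ever-use onset, cumulative-
duration bin crossings, dose-category changes, the 70th birthday, and
recorded comorbidity onsets. Ties between an event and a change are
resolved by attributing the event to the covariate state in force just
before the change (changes apply left-closed). Splitting conserves at-risk
time and event counts by construction, and `validate_table` checks the
invariants (contiguity, single terminal event, positive interval lengths)
on every pipeline run.

## Hazard model

The hazard for participant *i* at time *t* is

    h_i(t) = exp( lambda_b(t) + x_i(t)' beta + u_i + s_g(i) )

* `lambda` — log baseline hazard, piecewise constant on time bins
  (default: 24 equal-width bins over the observed range; "small intervals"
  is otherwise a free choice). A first-order random-walk (RW1) prior
  penalises deviations from a constant baseline; its standard deviation is
  a hyperparameter. The RW1 is improper in the level, which is anchored by
  a fixed, numerically negligible ridge (1e-8) rather than an explicit
  sum-to-zero constraint — algebraically simpler, identical fits.
* `beta` — fixed effects with a vague Gaussian prior (precision 1e-6), so
  that no-random-effect fits agree with an unpenalised Poisson GLM to
  well below 1e-6.
* `u` — iid Gaussian frailty per participant, SD `sigma_u`.
* `s` — Gaussian field over distinct practice/residence locations with
  Matérn covariance (default smoothness ν = 1; ν = ½ is the exponential
  covariance). The field is represented directly as a dense Gaussian
  process over the deduplicated location set rather than through an SPDE
  mesh: at the location counts this package targets (tens to a few hundred
  sites) the dense solve is exact, simpler and fast, and coincident
  locations share one effect.

The piecewise-exponential likelihood is handled through the standard
Poisson equivalence: every start–stop row is split at bin boundaries into
pieces with exposure time `E` and event indicator `d`, giving the
log likelihood Σ (d·η − E·e^η).

### Inference

Empirical-Bayes Laplace, in two nested loops:

* **Inner:** Newton–Raphson on the latent field (λ, β, s, u) at fixed
  hyperparameters, to gradient max-norm < 1e-6. The negative Hessian is
  A'WA + Q with diagonal frailty block, so each step is solved through the
  Schur complement of the small dense block (bins + covariates + sites) —
  cohorts of several thousand participants take milliseconds per
  iteration. Step halving guards the ascent.
* **Outer:** Nelder–Mead on the log hyperparameters (frailty SD, RW1 SD,
  spatial SD and range — at most four), maximising the Laplace
  approximation of the log marginal posterior
  `f(x̂) + dim/2·log 2π − ½·log|H| + log prior(θ)`, warm-starting each
  inner solve at the previous mode. Full posterior integration over
  hyperparameters (the full INLA scheme) is deliberately out of scope: the
  posterior modes coincide and the empirical-Bayes fit runs at desk scale.

PC priors are implemented as exponential priors on each standard
deviation with rate −ln(α)/σ₀, i.e. P(σ > σ₀) = α, default σ₀ = 1,
α = 0.01; the spatial range carries the analogous prior on 1/range
(shrinking toward a flat field). SDs are optimised on a log scale bounded
below at e⁻⁶; a hyperparameter that collapses to the bound is reported as
degenerate in the `FitResult` rather than raising.

Credible intervals are Gaussian (Laplace) intervals,
`exp(mode ± 1.96·SD)`, with the SD taken from the inverse Schur complement
(the dense-block posterior covariance).

Known behaviour: with a single (often censored) event per subject, the
empirical-Bayes frailty SD is attenuated relative to the truth (≈ 0.15
estimated when simulating 0.3 at n ≈ 3000); this is the familiar
difficulty of separating individual heterogeneity from Poisson noise in
survival data with non-repeatable events, and it leaves the fixed-effect
recovery (bias, interval coverage) intact, which the acceptance tests
check directly.

## Reporting

Survival curves use the Kalbfleisch–Prentice weighted product-limit
estimator; with unit weights (the default) it is exactly Kaplan–Meier with
delayed entry — a subject joins the risk set at its entry time (risk set at
an event time t: entry < t ≤ exit). The log-rank test uses the same risk
sets; the multi-group statistic inverts the hypergeometric covariance of
the first K−1 strata. Exported curves state their time origin (days since
study start) explicitly, since "months after exposure" curves depend on an
origin convention. Chi-squared tests in descriptive tables are Pearson
without continuity correction (a toggle exists), flagged at the
Bonferroni-corrected threshold p < 0.01.

## Synthetic cohorts

The generator draws what the analysis assumes, plus the ground truth:

* staggered entry: 60 % of participants present at study start, the rest
  uniform over the first six years; administrative censoring at eight
  years plus random loss (2 %/year);
* demographics near the target population (age ~ N(45, 20²) truncated to
  [15, 100], half women) and age-dependent comorbidity prevalences;
* PPI initiation with covariate-dependent logits calibrated so that
  ≈ 25 % of participants are baseline users and ≈ 7 % initiate during
  follow-up, matching the user-strata proportions of the motivating
  setting; log-normal episode lengths (median 120 days) and gaps,
  realised as dated 28-day prescriptions, 30 % of which carry
  quantity/daily-dose instead of recorded treatment days;
* event times sampled **exactly** by inversion of the piecewise cumulative
  hazard (no time discretisation) from
  exp(λ_bin + x(t)'β + u + s), where the PPI covariate is the ever-use
  indicator; default true effects: PPI HR 1.30, age ≥ 70 HR 2.39, female
  1.04, hypertension 1.17, diabetes 1.43; frailty SD 0.3; the spatial
  field defaults off and, when on, also loads on the initiation logit so
  that it is a genuine unobserved confounder;
* lab panels at scheduled visits — regular spacing (default 6/year) with
  a random phase — so the first determination after a latent event is at
  most one visit interval late; pre-event eGFR fluctuates around
  90 mL/min/1.73 m² (SD 4), post-event values sit below the 60 threshold
  (mean 52, SD 3, slow decline), and for a configurable 20 % of
  participants the event manifests through UACR instead (exercising the
  "and/or" rule). Healthy UACR is truncated just below 30 mg/g so noise
  never produces a false qualifying determination — a deliberate
  idealisation that gives the generator its "never detected early"
  guarantee;
* 3 % of participants are prevalent cases (low eGFR from entry) to
  exercise the first-year exclusion.

Creatinine values are obtained by inverting the CKD-EPI equation at the
participant's age and sex, so the phenotype stage recomputes the intended
eGFR exactly.

What the generator does **not** emulate: pharmacokinetics and adherence,
calendar/seasonal effects, ICD-coded diagnoses, analyte-specific assay
drift, missing-at-random lab panels (88 % of a real registry may lack
renal panels entirely), or informative visit schedules. Passing recovery
tests therefore demonstrates correctness of the estimation machinery under
the stated model, not robustness to the full messiness of registry data.

## Problem sizes in the test suite

Parameter-recovery checks run 20 replicates at n = 3000 (credible-interval
coverage) and 20 at n = 5000 (bias of the PPI log hazard ratio), and the
spatial-deconfounding comparison runs 20 paired fits at n = 1000 with 64
sites — sizes at which Monte-Carlo error on the checked summaries is well
below the acceptance margins while the full suite completes in minutes.
The acceptance script analyses one 2 500-participant cohort end to end.
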