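# Methods

This note documents the statistical procedures implemented in `screenfuse`,
the design of the synthetic-cohort generator, and the numerical and design
choices made where more than one defensible option existed.

## Outcome ascertainment

Outcomes (suicide attempt, SA; suicidal ideation, SI) are defined purely by
membership of an event's diagnostic code in configurable per-outcome code
lists; an event may count toward both outcomes, and events matching no list
are dropped. The package ships a small synthetic code alphabet as the
default configuration — real code lists are user-supplied configuration,
not computation.

A visit is a case at horizon *h* iff the patient has a qualifying event with
`discharge_date < event_date ≤ discharge_date + h`. The window is half-open
on the left by design: a code dated on the discharge day plausibly documents
the index presentation itself, and counting it would let the screen
"predict" the event that prompted it. This convention is a package decision;
an analysis wishing to include same-day events can shift event dates.
Labels attach per *encounter*: patients with several visits contribute
several rows, and one event can label every covering visit. Case sets
therefore nest across horizons by construction.

## Triage tiers and feature encoding

Tier assignment takes the **maximum severity** over all satisfied criteria
(red: intent without or with plan, or behavior within 3 months; orange:
method without plan, or behavior 3–12 months ago; yellow: wish to be dead,
ideation without method or plan, or behavior more than a year ago; green
otherwise). Maximum-severity precedence is forced by the tiers' role as an
ordered escalation ladder — any other precedence could let a red criterion
be masked by a lower one. "Ideation without method or plan" is read
literally as Q2 = yes with Q3–Q5 not yes.

For the regression, each component is flattened to one binary indicator
(yes → 1, no and not-asked → 0). Behavior (Q6) flattens to *any lifetime
behavior*; recency information survives only in the tier rules. The
unasked state for Q3–Q5 is stored as an explicit sentinel in files and
collapsed to 0 only at encoding time, so the cascade remains recoverable.

## Screening regression

Per outcome and horizon, a maximum-likelihood logistic regression on the
seven binary features, with Wald 95% CIs exponentiated to the odds-ratio
scale (standard for reported OR tables; profile-likelihood CIs are
available via `ci_method="profile"`, computed by bisection on the profile
deviance). Constant features are flagged `constant` and skipped rather than
crashing the fit. Quasi-separation — detected as non-convergence or any
|log-odds| > 15 — triggers a weak ridge refit (L2 penalty 1/n) with every
row flagged `regularized`; those odds ratios are no longer ML estimates and
carry no CIs. Separation is a real hazard here: outcomes are rare and some
question patterns are nearly deterministic at small n.

Out-of-fold prediction uses stratified k-fold assignment (k = 5 by
default), deterministic given a seed; each visit is scored by the model
fitted with its fold held out. Stratification and seeding are package
decisions — with 0.1%-prevalence outcomes, unstratified folds can lose all
cases from a training split. Because the features are 7 binaries, OOF
scores take at most 2⁷ distinct values per fold; all downstream percentile
logic is written for heavily tied scores (see below).

## Late fusion

Four combiners of the OOF screening score *s* and the EHR score *v*:

* mean (s+v)/2 and elementwise maximum;
* tier-conditional weighted average: weight 1 on *s* for yellow/orange/red,
  0 for green. The quoted clinical definition assigns full weight to one
  input per tier, so the default is a hard selector; continuous per-tier
  weights are exposed as an option.
* lasso stacker: L1-penalized **logistic** regression on (s, v). A linear
  lasso on 0/1 labels would emit out-of-range scores, while the stacker's
  output must be a risk probability to be thresholded; hence the logistic
  reading. The inverse penalty C is selected per outer fold by 3-fold
  cross-validated log-loss within the training folds only, over a fixed
  5-point grid 10⁻²…10² (a coarser grid than a full path; with two features
  the selected model is insensitive to grid density, and the grid keeps the
  full 10-block pipeline run inside a few minutes). The stacker reuses the
  screening regression's fold plan — a documented simplification: nested CV
  would be cleaner, but a single shared partition avoids silent leakage
  differences between stages, and the held-out rows never inform penalty
  choice or coefficients.

## Discrimination metrics

AUROC is the rank/concordance probability with ties counted ½; AUPR is
average precision (step interpolation; trapezoidal PR interpolation is
known to be optimistic and is not used). Both are validated in the test
suite against brute-force oracles (pairwise enumeration; explicit threshold
walk) to 10⁻¹².

Percentile threshold tables set the cutoff at the empirical p-quantile of
the model's **own** score distribution for that outcome and horizon, and
flag scores **strictly greater** than the cutoff. With coarse score
distributions the realized flagged fraction can fall short of (100−p)%;
it is reported in its own column rather than forced. A fully degenerate
score vector yields rows flagging nothing, with a warning. Tier tables use
cumulative at-or-above positivity (≥ yellow, ≥ orange, ≥ red).

IDI is the discrimination-slope difference. Analytic inference is the
standard two-sample z on per-subject score differences with independent
case/noncase variances. Because repeat visits violate independence, a
seeded bootstrap (encounter-level by default, patient-cluster optional,
1000 draws) is provided as the alternative; the acceptance suite checks
that the two procedures agree in their rejection decision in ≥ 90% of null
and strong-effect simulations.

The reclassification report partitions cases by membership in each model's
top risk decile (> 90th percentile of its own scores) and summarizes
configured covariates per group (binary: count and percent; numeric:
median and IQR). In the pipeline the covariates are a prior-coded-event
flag, sex, within-cohort visit count and within-cohort record span.

## The synthetic-cohort generator

The generator is the package's substitute for an undistributable clinical
cohort. Its defaults *are* the study conditions of the shipped analyses;
they were chosen once, against published cohort descriptions, and are not
tuned per run.

**Structure.** Each patient draws a stable risk trait `stable ~ N(0, 1)`;
each visit draws an acute state correlated ρ = 0.15 with it. Extra visits
are Poisson with mean 0.45 (≈ 1.45 visits/patient) and a log-rate loading
of 0.7 on the stable trait — sicker patients visit more, as utilization
features in real EHR risk models attest. The daily event hazard is

    λ(t) = base · exp(0.9·stable + 2.0·acute·2^(−t/20)) ,

so the acute component decays with a 20-day half-life while the stable
component is time-constant: screening-derived scores discriminate best at
short horizons and the EHR score holds steady — the complementary-time-
scales pattern the fusion analysis exists to detect. Baselines (SA
8·10⁻⁶/day, SI 5.6·10⁻⁵/day) put 30-day prevalences near 0.2% (SA) and
1.3% (SI) on ~120k encounters, matching the order reported for large
screened hospital cohorts. Event counts are Poisson with the integrated
intensity; event days are placed proportionally to the daily hazard, and
events attach to the patient. A small rate of off-list codes exercises the
classification filter.

**Screening responses.** Questions observe the acute state through a
nondisclosure/measurement channel: `seen = acute + 0.4·stable + N(0, 0.6)`.
The stable term reflects that chronic risk partly shows in answers; the
noise term models patients who deny ideation while at elevated risk — both
channels are needed for the EHR score to add value *within* the green
tier, which is where tier-conditional fusion earns its gain. Q1–Q5 are
Bernoulli with per-question intercepts and loadings on `seen`; Q3–Q5 are
generated only when Q2 = yes. Q6 recency comes from a cumulative-logit
model on `seen` plus an extra stable loading of 0.8 (behavior history is
largely a trait). Care settings shift the acute state additively
(psychiatric ED +1.6, ambulatory surgery −0.5, …), giving realistic
setting gradients in prevalence and screening positivity.

**EHR score.** `sigmoid(−6.0 + 0.7·stable + N(0, 0.65))` — a noisy
monotone transform of the stable trait whose distribution sits *below* the
screening regression's off-green scores. That location matters only to the
scale-sensitive fusions (mean and tier selection); AUROC-type metrics are
invariant to it. It emulates an externally trained model's output; the
training of such a model is out of scope and the score enters the pipeline
as given data.

**Direct-feature mode.** For parameter-recovery studies the hazard can
instead depend log-linearly on the binary question features with known
coefficients (`recovery_params()`: Q1 1.6, Q2 0.7, Q6 0.6 on 30-day SI, one
visit per patient, ≈1.2% prevalence). At rare-outcome prevalence the
per-window probability is then log-linear in the features up to O(p), so
the screening regression is essentially correctly specified and its CI
coverage of the generating coefficients can be measured; the acceptance
suite requires 93–97% pooled coverage over 200 replicates.

**What the generator does not emulate.** Screening non-administration (real
cohorts condition on the screen having happened); calendar seasonality;
realistic diagnostic-code strings; informative missingness (refused or
partial screens are forbidden by the data model); suicide death as an
outcome. The red tier is over-represented relative to real triage mixes
(≈10% of visits versus a few percent) because the generator's conditional
yes-rates for the intent questions are high among disclosing patients;
tier-mix shape was left as-is since no shipped analysis depends on it.
Passing tests therefore demonstrate that the *pipeline* is correct and that
the fusion conclusions hold under the generator's assumptions — not that
any particular clinical cohort will show the same effect sizes.

## Determinism and numerics

Every source of randomness descends from one seed through a fixed SHA-256
derivation (`derive_seed(seed, stage_label)`), so stages can be re-run in
isolation and a full `run-all` is a pure function of (config, simulation
parameters). Report files use fixed float formatting and carry no
timestamps; `manifest.json` records SHA-256 digests of every artifact, and
two identical runs produce byte-identical bundles (asserted at ~120k
encounters in the acceptance suite). Logs — which do carry timestamps — go
to stderr as JSON lines, never into the bundle. Liblinear and LBFGS fits
are seeded or deterministic; the unpenalized OOF fits use `C = inf` rather
than a nominal large penalty.

Degenerate inputs are handled explicitly rather than by exception where a
defined answer exists: caseless subgroup strata are skipped and listed;
metrics undefined for one-class inputs raise a dedicated error; IDI with
fewer than two cases or noncases returns a point estimate flagged
`point_only`.

## Problem sizes used by the shipped analyses

The acceptance suite runs the recovery study at 20k encounters × 200
replicates, the time-scale/fusion study at ~50k encounters × 25 seeds, and
the determinism check at ~120k encounters — sizes at which the measured
quantities' seed-to-seed variation is small relative to the margins being
asserted, while a full suite run stays in the minutes range on one CPU.
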