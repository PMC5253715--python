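# Methods

This note documents the models, estimation choices, numerical conventions,
and known limitations of the package. It is written for a reader who wants
to know exactly what each number means and which design decisions were
genuinely open.

## 1. Trial data model

One record per participant: arm (`lens_extraction` / `standard_care`),
baseline covariates (age, sex, Chinese ethnicity, PAC vs PACG diagnosis,
one vs both eyes eligible, recruiting centre), EQ-5D utility index at
0/6/12/24/36 months, Glaucoma Utility Index at the same visits, GSS2
severity stage at baseline and 36 months, dated procedure events, per-period
primary-care contact counts, medication episodes, participant-borne cost
inputs, and death time. Times are **months from randomisation** throughout
the trial data model; the Markov module converts to years.

Missingness is explicit: a missing questionnaire cell is `None`/an empty
CSV cell, never zero. Zero is always a real observed value. This matters
because roughly a third of participants have at least one missing cost or
utility element, and the complete-case/multiple-imputation contrast is an
analysis output.

Unit costs are GBP at 2012–13 prices (HRG-style reference tariffs for
procedures, per-visit primary-care costs, monthly medication class costs,
hourly wage rates for time valuation), carried as a table keyed by the
closed procedure/contact kind set with the currency year as metadata. No
inflation adjustment is applied. The "other glaucoma procedure" kind has a
single configurable tariff (default £500) since no per-kind breakdown is
available.

## 2. Costing and QALYs

`compute_costs` classifies each event into the reporting categories
(initial intervention; each subsequent procedure kind split by
eligible/non-eligible eye; medications by eye class; GP/nurse/optician;
ophthalmology outpatient). An eligible-eye lens extraction in the lens arm
is the initial intervention; an eligible-eye iridotomy in the standard-care
arm within 2 months of randomisation (the 60-day protocol window) is the
initial intervention, later ones are subsequent procedures. Category sums
are exact and additive: splitting a record's events across two records and
adding the breakdowns reproduces the original.

Participant costs = self-purchased items + travel cost per visit × visits.
Indirect costs = lost paid hours × wage rate + lost unpaid
(housework/leisure) hours × an inferred hourly value. Defaults £13.08 and
£7.00/hour; both configurable. Pharmacist time is not costed. These enter
the analysis only under the societal-perspective scenario.

`compute_qalys` integrates the utility trajectory by the trapezoid rule
(linear change between visits), divided by 12 to give years. Death
handling: utility declines **linearly from the last pre-death observation
to zero at the death time** and is zero thereafter. A step to zero at the
last visit would have been the alternative; the linear decline is
consistent with the interpolation assumption used everywhere else. A
missing pre-death utility raises an incompleteness signal and the patient
drops out of the complete-case set. Within-trial costs and QALYs are
undiscounted (a config flag exists but defaults off); discounting applies
only in the extrapolation model.

## 3. Within-trial estimation

* **Adjusted means**: OLS of cost (and, separately, QALYs) on the arm
  indicator, minimisation factors (sex, ethnicity, diagnosis, eyes
  eligible; centre optional and off by default), baseline cost, and
  baseline utility, followed by recycled predictions (predict everyone
  under each arm; average). Because both equations share regressors,
  equation-by-equation least squares equals the SUR point estimates; the
  cross-equation error correlation is preserved by bootstrapping patients
  jointly. A log-link Gamma GLM for costs is available behind the scenario
  flag. Covariate columns constant in the estimation sample are dropped
  (they carry no information and would otherwise make subgroup and
  bootstrap designs singular); genuinely collinear columns raise an error
  naming them.
* **Bootstrap**: patient-level resampling with replacement, stratified by
  arm (the design fixes arm sizes; the source publication does not state
  stratification — this is our choice), `B`=1000 by default,
  seed-reproducible. CEAC(Rc) = share of replicates with ΔE·Rc − ΔC > 0;
  NMB intervals are percentile (bias correction not used).
* **Confidence ellipses**: bivariate-normal ellipses from the replicate
  mean and covariance at the χ²(2) quantile (50/75/95 % by default);
  degenerate covariances are flagged.
* **Multiple imputation**: chained equations (statsmodels MICE, predictive
  mean matching) over the four follow-up utilities and the
  questionnaire-derived cost categories, conditional on arm, minimisation
  factors, baseline cost/utility, and the fully observed event-based cost.
  Cells structurally absent through death are not imputed. m=20 by
  default. Point estimates pool the within-imputation recycled-prediction
  estimates; uncertainty, when requested, uses **bootstrap-then-impute**
  (resample patients, impute within each replicate at reduced m) rather
  than Rubin's rules, because the estimand is a functional of the fitted
  predictions rather than a single coefficient. This is slower but matches
  the resampling logic of the complete-case analysis.
* **Subgroups**: the full pipeline within each level of diagnosis
  (PAC/PACG) or eyes-eligible (one/both), with the split variable removed
  from the adjustment set.
* **ICER conventions**: ΔC/ΔE only when ΔE ≠ 0; cheaper-and-better prints
  a dominance ("cost saving") label; costlier-and-worse prints "dominated";
  ΔE = 0 prints "undefined". Note that a ratio of *rounded* increments
  (e.g. 981/0.069 = 14 217) differs from the ratio of unrounded means; all
  report tables compute increments before display rounding.

## 4. Markov model

Structure: {PAC/normal, mild, moderate, severe} × {pre-surgery,
post-surgery} plus absorbing death — nine states, 6-month cycles. Within a
cycle the order is **mortality → surgery → progression**, applied as
conditional probabilities so each row sums to one (the ordering is our
choice; the textual model description does not fix it). Progression moves
at most one stage per cycle; the severe stage cannot progress further;
surgery happens at most once per patient. Rewards accrue at cycle start on
start-of-cycle occupancy and are discounted by (1+r)^(−t) at the cycle
start time; there is **no half-cycle correction** by default (a documented
limitation, matching common practice in cohort models built in decision
tree software).

Inputs, all fitted from a trial data set:

* entry stage distribution, mean entry age, and sex mix from baseline;
* per-arm per-stage 36-month progression probabilities from a saturated
  logistic fit (cell probabilities = empirical proportions;
  continuity-corrected under separation; empty cells fall back to the
  arm's pooled rate with a flag), converted by p6 = 1 − (1 − p36)^(1/6);
* per-arm Weibull time to first eligible-eye glaucoma/cataract surgery
  (lifelines accelerated-failure-time fit, arm on scale, common shape)
  giving time-dependent cycle probabilities 1 − S(t+u)/S(t); a nested
  exponential fit (per-arm constant hazard, closed-form MLE) with BIC for
  both, the exponential being scenario 7;
* a one-off **entry cost** per arm (mean initial-intervention cost) and a
  one-off **surgery transition cost** (default an equal
  trabeculectomy/day-case cataract tariff mix, £1003; weights
  configurable);
* per-arm per-6-month-window state costs: dated monitoring attendances and
  smaller procedures + primary-care costs apportioned from questionnaire
  periods + medication-month overlap. Windows beyond 36 months reuse the
  30–36-month values;
* per-arm per-window state utilities: patient-level linear interpolation of
  the EQ-5D trajectory at window midpoints, averaged. Stage-resolved
  utilities are supported by the engine but the estimator returns
  stage-constant values (the trial is too small to resolve stage × arm ×
  window cells);
* a standard-care cohort member who transits to surgery takes the
  **lens-extraction arm's** stage utilities from that point on;
* mortality from an age/sex life table, independent of severity and
  treatment; cohort age advances deterministically and the two sexes'
  annual probabilities are mixed by the cohort's female share before the
  per-cycle conversion 1 − (1 − q)^u. Ages beyond the table clamp to the
  oldest row. The packaged life table is **synthetic** — a Gompertz hazard
  (rate doubling every 8 years) calibrated to UK-like all-cause mortality
  at the cohort's ages (q ≈ 0.015 for men, 0.009 for women at 67) — since
  the national tables are not redistributable here; any table can be
  supplied as CSV.

`run_microsim` simulates individual walkers through the identical process
(same mixed mortality, same reward timing) and serves as an independent
oracle: the cohort trace must agree within Monte Carlo error. This guards
the transition algebra, not the parameter estimates.

## 5. Probabilistic and deterministic sensitivity analysis

PSA draws, per iteration: gamma(mean, SE) for every cost cell (method of
moments), beta(mean, SE) for every utility cell, multinormal (Cholesky) for
the progression cell logits and the Weibull AFT coefficients, and gamma for
the entry/surgery costs. Draws are common to both strategies within an
iteration. CEAC(Rc) is the share of iterations where a strategy has the
greatest NMB, ties broken toward standard care (probability-zero under
continuous draws). Iterations producing out-of-range probabilities are
redrawn and counted; more than 1 % rejections aborts the run. An all-fixed
(zero-SE) configuration reproduces the deterministic model exactly, which
is tested.

Deterministic scenarios mirror the configured flags: (1) exclude
non-eligible-eye procedure and medication costs, (2) parameterise the model
from the multiple-imputation data (record cells completed by
across-imputation means before refitting), (3) include participant and
indirect costs (spread evenly across windows), (4) GLM-estimated
within-trial means, (5) cohort entry age 50, (6) alternative horizons,
(7) exponential time to surgery.

## 6. Synthetic-data generator

The generator is the package's test bed and defines its study conditions:

* n=285, minimisation allocation over sex, ethnicity, centre (22 levels),
  diagnosis, and eyes-eligible with a 0.8 biased coin toward the
  imbalance-minimising arm;
* baseline: age ~ Normal(67.5, 8.42) truncated at 50; 57.5 % female;
  44.6 % both eyes eligible; 35.4 % PAC; 1.4 % Chinese; PACG baseline
  stages mild/moderate/severe = 0.60/0.37/0.03 (PAC participants are stage
  PAC/normal by definition; the severe share is small because advanced
  field loss was an exclusion criterion);
* utilities: per-arm per-visit targets equal to the published trajectory
  means/SDs, drawn from a **censored normal** on [−0.594, 1] whose
  location is solved numerically so the post-censoring mean hits the
  target (plain truncation would undershoot the mean by ≈0.03 at these
  levels). A shared within-patient latent (weight 0.6) induces serial
  correlation; the mass at 1 mimics the EQ-5D ceiling. SDs are matched
  only approximately (censoring shrinks them slightly);
* one aggregate subsequent-surgery event per patient, Weibull time to
  event per arm (shape 1.3; scales giving ≈30 % of standard-care and ≈9 %
  of lens-arm patients an event by 36 months), with the procedure kind
  drawn from a per-arm mix; remaining procedure counts are Poisson with
  rates **back-solved from published mean category costs divided by unit
  tariffs**, and are therefore approximate summaries, not observed rates;
* medication: Bernoulli any-treatment × scaled-beta duration, calibrated
  to mean category costs; primary-care visit counts Poisson per
  questionnaire period;
* mortality from the packaged life table (≈4 % die within 36 months at
  these ages), truncating later observations;
* missingness: each follow-up utility cell and each period's resource
  questionnaire is deleted independently with probability
  expit(a + 0.2·[standard care] − 1.5·prior utility), a = −1.62 — a
  missing-at-random mechanism in which sicker patients respond less,
  calibrated to ≈63 % complete cases. The pre-deletion copy is always
  returned alongside.

What passing tests on this generator do **not** show: real EQ-5D data are
multimodal with tariff-specific gaps, real resource use is overdispersed
and correlated across categories, missingness in practice is partly
monotone dropout, and centre effects exist. Estimator performance on the
synthetic cohorts is evidence about the implementation, not about the
clinical question.

## 7. Numerical conventions and problem sizes

Occupancy vectors are renormalised against accumulated round-off and
checked to 1e-12; probability transforms are exact at their fixed points;
the cycle-probability round trip holds to machine precision. Surgery times
at exactly zero are floored at 1e-6 months before survival fitting.
Default problem sizes used in the test suite and acceptance script:
trial-sized cohorts n=285; parameter recovery n=10 000; model-selection
consistency 100 replicates of n=5 000; microsimulation oracle 200 000
walkers (Monte Carlo SE on ΔE ≈ 0.004); bootstrap B=1000; PSA 1000
iterations; MI m=20 (m=5–10 in the heavier resampling paths).

## 8. Known limitations

* No half-cycle correction; no tunnel states for time since surgery; a
  single surgery per modelled patient.
* Mortality is independent of severity and arm, and the packaged life
  table is a synthetic Gompertz stand-in.
* The generator's resource-use intensities are back-solved from published
  means, so cost *variances* (and hence bootstrap interval widths) are not
  calibrated to the source data.
* MI uncertainty by bootstrap-then-impute is computationally heavy at full
  m and is run at reduced m by default.
* The model's incremental QALYs inherit the sampling noise of per-arm
  utility means at n=285; across generator seeds the extrapolated ΔE
  varies substantially, which is a faithful property of trial-based
  extrapolation rather than an implementation artefact.
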