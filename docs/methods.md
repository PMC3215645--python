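# Methods

This note documents the statistical methods, the synthetic-data model, the
numerical conventions, and the design decisions behind `phenoval`.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The validation design

The unit of analysis is a patient bundle from a computerized clinical record:
coded ICPC episodes, plasma-glucose measurements, per-visit blood-pressure
readings, medication records and structured history notes.  The coded
diagnosis (T90 for diabetes; K86/K87 for hypertension) plays the role of the
diagnostic *test*; the *gold standard* is the guideline criteria applied to
the raw measurements (ADA 2003 for diabetes, JNC 7 for hypertension).

Two arms are built per disease: a simple random sample of coded adults and an
uncoded arm constructed by individual matching (exact sex, age within ±2
years by default) to the coded arm.  Sample size uses the binomial precision
formula n = z² p(1−p)/d² at maximum indetermination (p = 0.5): with 95%
confidence and ±5% precision the base size is 384 (the formula gives 384.15;
the base is rounded to the nearest integer, which is the convention that
reproduces both published sizes), inflated by ceil(n·(1+loss)) to 423 at a
10% anticipated loss.  After matching, patients whose records cannot support
the gold standard are excluded: no plasma glucose at all for diabetes,
blood pressure on fewer than two office visits for hypertension.  The
therapy-plus-history criteria require no measurement, so patients satisfying
them stay eligible (and positive) without labs or readings.  Dropped pairs
are not re-matched; frames only shrink, and each exclusion carries a reason
(`no_glucose`, `insufficient_bp`, `unmatched_reference`).

## 2. Gold-standard engines

All thresholds are inclusive (≥) and live in a single exported table
(`CRITERIA_THRESHOLDS`); rule code contains no numeric literals.

Diabetes is positive on any of: fasting glucose ≥ 126 mg/dl; documented
hyperglycemia symptoms with random glucose ≥ 200 mg/dl; 75-g OGTT 2-h value
≥ 200 mg/dl; antidiabetic therapy with a prior DM diagnosis in the record;
the gestational pattern (pregnancy flag plus ≥ 2 of the four 100-g OGTT
points at 95/180/155/140 mg/dl, all from the same test date, so two partial
tests cannot be mixed); or antidiabetic therapy with a prior gestational-DM
diagnosis.

Hypertension averages the per-visit means of all readings across visits with
at least one reading and requires at least two such visits; the grand mean is
compared with 140/90 mmHg, or 130/80 when the patient has diabetes or chronic
kidney disease.  The office-BP rule is deliberately operationalised as
*unweighted mean of per-visit means*: it respects the per-visit averaging the
guideline describes while needing only the stated minimum of two recorded
measurements.  Antihypertensive therapy plus a documented hypertension
diagnosis is a standalone positive criterion.

Two ascertainment details are modelling choices, not guideline content: the
"previous diagnosis in medical records" concept is a structured history note
(free-text processing is out of scope), and chronic kidney disease is a
boolean patient flag because it is only ever used to pick the threshold pair.
No temporal window is applied — every record in the bundle counts regardless
of date, since the validation is cross-sectional at an index date.

The diabetes status that selects the 130/80 threshold comes from the
gold-standard diabetes classification by default (keeping the gold standard
internally consistent); `htn_dm_source="code"` switches it to the T90 code.

## 3. Statistics

* **Margins.** Sn = TP/(TP+FN) (criteria-positive patients carrying the
  code), Sp = TN/(TN+FP), with the direct column ratios PPV = TP/(TP+FP),
  NPV = TN/(TN+FN).  Under code-based sampling the direct column ratios are
  design-conditional; population predictive values come from the Bayes step.
* **Proportion CIs.** Wilson score without continuity correction.  This
  choice is pinned empirically: it exactly reproduces the published
  validation-table intervals (e.g. 421/423 → 98.29–99.87%), identifying the
  method behind them.
* **Kappa.** κ = (p_o − p_e)/(1 − p_e) with p_e from the margins.  The CI
  uses the Fleiss–Cohen–Everitt large-sample standard error with
  z = 1.959964, truncated to [−1, 1]; this reproduces every published kappa
  interval, including the truncation at 1.  Labels: ≤ 0.20 slight, 0.21–0.40
  fair, 0.41–0.60 moderate, 0.61–0.80 substantial, ≥ 0.81 almost perfect.
* **Homogeneity.** The margin's (successes, failures) × stratum 2×2 table is
  tested with Pearson χ² *without* Yates correction when all expected counts
  are ≥ 5 (with correction the published p = 0.007 would become 0.011, so
  the uncorrected statistic is the pinned method), otherwise the two-sided
  Fisher exact test.  P-values are reported raw; no multiplicity correction.
* **Prevalence adjustment.** Rogan–Gladen:
  p_true = (p_apparent + Sp − 1)/(Sn + Sp − 1), clamped to [0, 1], undefined
  when Sn + Sp = 1.  The under-registration percentage is
  100·(p_true − p_apparent)/p_apparent.
* **Predictive values.** PPV(p) = pSn/(pSn + (1−p)(1−Sp)) and
  NPV(p) = (1−p)Sp/((1−p)Sp + p(1−Sn)) evaluated with *unrounded* Sn/Sp over
  a prevalence grid (4%–15% in 0.5–1 point steps, then 20%–50%); PPV is
  strictly increasing and NPV strictly decreasing in p whenever
  0 < Sn, Sp < 1.  Approximate intervals for these quantities propagate the
  Wilson variances of Sn and Sp through a delta method on the logit scale;
  this is the package's own approximation and is labelled as such in the
  report — it does not claim to reproduce any published predictive-value
  interval, whose method is unknown.
* **Display rounding.** Percentages to 2 decimals and kappa to 3 in rendered
  tables; all internal computation is at full precision (several grid values
  only reproduce unrounded).

## 4. The synthetic cohort model

The generator emulates an adult primary-care population at a fixed index
date.  Defaults: 20,000 patients; 56% female; four age bands (18–39, 40–54,
55–69, 70–90 with weights 0.40/0.25/0.20/0.15); latent diabetes prevalence
5% with band relative risks 0.15/0.6/1.8/4.2 (normalised so the margin is
preserved), which puts roughly half of coded diabetics at age ≥ 70; latent
hypertension 17% nominal with relative risks 0.15/0.7/2.2/5.5 and a
conditional prevalence of 80% given diabetes (the realised margin is ≈ 16%
because diabetes concentrates in the older bands).  Coding is Bernoulli
against latent truth: diabetes sensitivity 0.975 / specificity 0.9997
(near-complete coding, coded prevalence ≈ 5%), hypertension sensitivity 0.82
/ specificity 0.998 (visible under-coding, coded prevalence ≈ 13–14%).
Missingness: 7.3% of patients have no glucose record; 22.9% have blood
pressure from fewer than two visits.  These rates, the prevalences and the
age structure are the study conditions of the emulated population and are
fixed defaults, configurable per run.

Measurement values are conventions — the guidelines specify thresholds, not
population distributions — drawn uniformly, clear of the thresholds: true
diabetics' fasting glucose on [130, 250] mg/dl (clipped at ≥ 127 after
noise), non-diabetics on [70, 118] (clipped ≤ 124); hypertensive visit means
above the applicable threshold pair and normotensive means below the
*stricter* pair the patient could be judged against.  Within-visit reading
noise is paired (mean ± e) so per-visit means are exact.  Consequently, on
every patient not selected for missingness, the criteria engines reproduce
the latent truth *exactly*, which the suite asserts record-for-record; the
generator therefore cannot test robustness to borderline or contradictory
measurements, which real records contain (dedicated boundary fixtures do
that).  It also does not model visit-to-visit BP variability, medication
dosing, temporal disease onset, or miscoded-but-plausible values.  The
gestational pattern (100-g OGTT with exactly two points above threshold) is
available behind `gdm_fraction`, default off, matching a general adult
population.  Therapy-plus-history records back 50% of true cases, which is
what lets some measurement-missing patients remain validly classifiable.

## 5. Recovering coding quality from the matched design

Sampling arms *by code status* makes the pooled TP/(TP+FN) of two equal-size
arms a design-conditional quantity: it mixes the coded and uncoded
populations at a 1:1 ratio instead of their true ratio, and the age/sex
matching evaluates the uncoded arm at the coded arm's (older) age
distribution.  It therefore does not estimate the population-level
P(code | gold-positive), and no choice of generator parameters makes it do
so.  For parameter recovery the package provides a design-corrected
estimator (`design_corrected_accuracy`): within post-strata (the generator's
age bands), each arm's sampled positivity is rescaled by the stratum's
population coded/uncoded counts — restricted to gold-standard-*eligible*
patients, because therapy-backed cases stay eligible under missingness,
making eligibility informative about the gold standard while coding given
truth is not.  The interval propagates per-stratum Wilson bounds
monotonically through the pooling ratio, which is conservative (wider than
exact).  The acceptance suite runs 100 seeded replicates of the full
pipeline (20,000-patient cohorts, 423/423 arms) and checks that the
intervals cover the configured coding sensitivity and specificity of both
diseases in at least 90% of replicates; the rare-event strata (young,
uncoded, gold-positive diabetics) are what keeps the diabetes-sensitivity
coverage below 100% — a handful of positives in a low-sampling-fraction
stratum moves the weighted estimate a lot, which the conservative interval
mostly, but not always, absorbs.

## 6. Numerical and engineering conventions

* z-quantiles come from the normal distribution at full precision
  (1.959964 at 95%), never the rounded 1.96; sample-size results are
  integer-rounded as described in §1.
* Degenerate inputs raise typed errors rather than returning NaN: zero
  denominators (`UndefinedStatisticError`), degenerate kappa margins
  (p_e = 1), the non-informative test Sn + Sp = 1, all-zero replay tables.
  An empty stratum margin inside a stratified run is flagged not-computable
  and the run continues.
* Determinism: a single root seed derives per-stage seeds through
  `numpy.random.SeedSequence`; identical configuration yields byte-identical
  extracts and reports.  All sampling uses `numpy.random.default_rng`.
* Extract IO is a six-file CSV schema with ISO dates; reading a written
  cohort is field-for-field identity, and a mmol/l option converts glucose
  on input at 18 mg/dl per mmol/l.
* The scale of the default synthetic population (20,000 patients) and of the
  replication study (100 replicates) was chosen as the smallest comfortably
  supporting the 423-per-arm design with stable stratum counts.

## 7. Known limitations

* The matched design identifies the design-conditional accuracy directly but
  population coding quality only through the corrected estimator, whose
  interval is conservative rather than exact.
* Predictive-value intervals at assumed prevalences are a delta-method
  approximation treating the prevalence as fixed.
* The generator's clean separation of values around thresholds means
  passing tests certify the machinery, not performance on noisy real-world
  records; adjudication by human reviewers (and inter-observer agreement) is
  outside the package's scope.
* Inclusion is restricted to adults (≥ 18 years) at the index date; pediatric
  criteria are not implemented.
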