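# Methods

This note records the modelling choices behind the package: what the rule
engines implement, how the synthetic cohort is constructed and calibrated,
how the survival statistics are computed, and what the tests do and do not
establish about real data.

## Risk classification

Both engines operate on a `GenotypeProfile`: cytogenetic feature flags
parsed from an ISCN-like karyotype string plus curated mutation flags
(mutation positivity = variant allele fraction ≥ 2%, configurable). Rule
precedence is an explicit ordered list evaluated top-down:

1. core-binding-factor translocations (t(8;21), inv(16)/t(16;16)) —
   favorable in both editions, overriding everything else;
2. adverse cytogenetics for the edition;
3. the remaining favorable-defining lesions (2017: mutated *NPM1* without a
   high-allelic-ratio FLT3-ITD; biallelic *CEBPA*. 2022: in-frame bZIP
   *CEBPA*, mono- or biallelic; mutated *NPM1* without FLT3-ITD);
4. molecular adverse markers (TP53; myelodysplasia-related genes — only
   *RUNX1*/*ASXL1* in 2017; wild-type-*NPM1* high-ratio FLT3-ITD in 2017
   only);
5. intermediate by default.

Consequences of this ordering, chosen deliberately:

* A favorable-defining lesion suppresses co-occurring molecular adversity in
  both editions (a CBF patient with *ASXL1*, or an *NPM1*-without-ITD
  patient with *SRSF2*, stays favorable). The suppression is recorded in
  the rule trace; the TP53-under-CEBPA case is convention-dependent and
  flagged as such.
* Adverse cytogenetics defeat the NPM1 and CEBPA rules but not CBF.
* t(9;11) is intermediate and takes precedence over co-occurring adverse
  markers in the 2017 engine (cytogenetic and molecular); in the 2022 engine
  only over the cytogenetic tie, with gene-mutation adversity still applying.

Numeric conventions: the 2017 allelic-ratio split is at 0.5 (low < 0.5);
TP53 adversity in 2022 requires VAF ≥ 10%, with an absent VAF treated as
qualifying (logged). The 2017 engine refuses to classify an FLT3-ITD
carrier without an allelic ratio — the rules cannot be evaluated — whereas
the 2022 engine never reads the ratio.

Karyotype conventions (the parser accepts a deliberately small ISCN
dialect — comma-separated tokens, optional clone sizes, clones flattened to
the union of abnormalities): complex = ≥ 3 abnormalities not counting
favorable-defining translocations; monosomal = ≥ 2 autosomal monosomies or
one plus a structural abnormality; hyperdiploid = modal count ≥ 49 with ≥ 3
numerical gains; loss of Y and constitutional (`c`) abnormalities are
ignored; unrecognized tokens count toward the abnormality total and are
logged. Which abnormality-count convention defines "complex" in any given
published cohort is rarely stated; ≥ 3 is the common choice and is what the
tests assume.

## Synthetic cohort

**Genotypes.** The default blueprint lists 23 archetypes (templates ×
counts, 624 patients total) chosen as one consistent completion of the
published marginal genotype counts and reclassification flows of a real
validation cohort. The blueprint stores no risk labels; the documented
group structure (205/295/124 under 2022; 134 reclassified; flows
31/3/21/46/33) must emerge from the classifier, which keeps every
classification test non-circular. Notable placements: the two TP53 and
three *ASXL1* carriers inside the 2022 favorable column are attached to CBF
archetypes (inv(16) and t(8;21) respectively) — attaching them to NPM1
carriers would work equally well; one complex-karyotype patient carries
*U2AF1* to complete the 78 adverse-column carriers of
myelodysplasia-related mutations. Lesion-free patients receive 1–3
passenger mutations (*DNMT3A*, *TET2*, *NRAS*) so that the IO path is
exercised with realistic nonempty call lists; passengers never affect
classification. Clinical covariates (age, sex, WBC, blast %) are drawn from
plausible marginals and are independent of outcome by design.

**Outcomes.** Per patient, the 2022 engine assigns the group internally
(never stored). Death and relapse times are exponential — the published
material gives no shape information, and exponential hazards make every
calibration closed-form:

* death hazard: λ_fav · HR_g with λ_fav = −ln(0.55)/60 per month (five-year
  favorable survival 0.55) and HR = (1, 2.340, 4.380);
* relapse hazard: −ln(0.65)/60 · HR_g, clocked from the CR time;
* CR drawn Bernoulli(0.922 / 0.854 / 0.661), realized only if the patient
  survives to the response-assessment time (uniform on 0.5–2 months): the
  realized CR rate is therefore the configured rate times a closed-form
  survival factor (≈ 0.99 favorable, ≈ 0.95 adverse), and tests assert
  against that product;
* transplant: among CR patients with probability 0.449, at a uniform 3–9
  month time, taken only if the patient is alive and under follow-up then;
  afterwards both hazards are multiplied by (1.0, 0.5, 0.5) per group —
  no benefit in the favorable group, a halved hazard elsewhere;
* administrative censoring uniform on 24–144.8 months, whose median (84.4)
  is what the reverse-KM median follow-up estimates;
* non-CR patients get an event-free-survival event at an induction-failure
  time uniform on 0.5–2 months (no published timing; any small window
  works), and never receive transplant.

Because CR assessment always precedes the earliest transplant time,
survival past assessment depends only on the pre-transplant hazard; the
generator exploits this to decide CR from the raw exponential draw and
apply the hazard break only where transplant can actually occur, keeping
all observables mutually consistent. All outcome invariants (EFS ≤ OS,
HCT ≤ OS, RFS present iff CR) hold by construction for every seed.

**Calibration recovery.** The hazard-ratio recovery checks simulate with
the post-transplant multipliers set to 1 — that is the definition of the
calibration (group-specific exponential hazards plus administrative
censoring). With the default multipliers active, the *marginal* hazard
ratios are attenuated below 2.340/4.380, since roughly a third of each
non-favorable group spends most of its person-time at half hazard; that
attenuated fit is the realistic-analysis output, not the calibration check.

**What the generator does not emulate.** Genotype co-occurrence beyond the
published marginals; covariate–outcome associations (age, sex, WBC and
blast are pure noise here, so the multivariable screen correctly drops
them); non-proportional or non-exponential hazards; relapse-then-salvage
dynamics. Passing tests therefore certify the rule engines and the
statistical machinery, not any clinical claim about real cohorts.

## Survival statistics

* **Kaplan–Meier**: product-limit over distinct event times; Greenwood
  variance; pointwise CIs on the log(−log) scale, which respects [0, 1] and
  matches the bounded intervals reported in practice. Step evaluation past
  the last follow-up carries the last value forward with a truncation flag.
* **Reverse KM**: the event indicator is inverted and the KM median of the
  censoring distribution is reported; undefined (flagged) when not reached.
* **Log-rank**: k-group observed−expected with hypergeometric covariance,
  χ² on k−1 df; the pairwise variant reports the three two-group tests
  unadjusted (a Holm adjustment can be applied downstream).
* **Cox**: Newton–Raphson on the partial likelihood, Efron ties by default
  (Breslow available for oracle comparisons), step-halving on overshoot,
  relative log-likelihood tolerance 1e−9, cap 100 iterations. Constant
  covariates and event-free data are rejected; monotone likelihoods
  (perfect separation) are detected by coefficient divergence and reported
  rather than returned. The global score test at β = 0 is exposed; with a
  single group indicator and Breslow ties it equals the log-rank statistic
  (a classical identity the tests verify).
* **Time-dependent exposure**: rather than episode-splitting, the fitter
  accepts a per-subject state-entry time defining one binary covariate
  evaluated as 1[entry ≤ t] at each event time. This is algebraically the
  counting-process fit, avoids degenerate zero-length episodes when entry
  ties the event time (ties resolve to exposed), and gives the Mantel–Byar
  test as the score test of that covariate. In the multivariable model the
  transplant indicator uses this mechanism; coding transplant as a baseline
  covariate would credit pre-transplant survival to the transplanted state
  (immortal-time bias). For RFS the transplant clock is approximated by the
  diagnosis-scale transplant time (CR dates are not part of the interchange
  format; the offset is at most the 2-month assessment window).
* **Censoring at an intervening event** (sensitivity analysis): time
  replaced, event cleared; a tie between death and transplant resolves to
  censored — the subject did reach transplant.
* **Harrell's C**: exhaustive pair counting (vectorized); a pair is usable
  when the event order is identifiable under censoring; score ties count
  1/2. **compare_c** reports ΔC with a leave-one-out jackknife standard
  error of the paired difference — asymptotically equivalent to the
  closed-form U-statistic variance of the usual paired test and far easier
  to verify by resampling (the tests cross-check it against a bootstrap).
* **NRI**: category NRI at a horizon, with cell-wise KM estimates of the
  event probability (the estimator reduces exactly to the closed-form
  up/down × event/non-event counts when no censoring precedes the horizon).
  Percentile bootstrap CI over subjects, seeded, 1000 replicates by
  default; empty up/down cells contribute zero weight and are flagged.
  A restricted variant confines the computation to reclassified subjects.

## Pipeline conventions

Age enters the multivariable model per decade, WBC on the natural-log
scale, blast percentage raw; covariates pass a univariable screen at
p < 0.05 and the survivors are entered jointly with no further selection.
JSON outputs round floats to 6 significant digits so identical config and
seed give byte-identical reports; the manifest records the config hash,
seed and library versions. Degenerate inputs (empty groups, inestimable
fits, undefined tests) produce flags in place of numbers rather than
aborting the run.

## Problem sizes used by the checks

The classification checks run the full 624-patient blueprint (deterministic,
seconds). Statistical null calibrations use 1000 replicates at n = 100–180;
parameter recovery averages 200 outcome simulations of the 624-patient
cohort. These sizes give binomial/sampling tolerances comfortably tighter
than the assertion bands while keeping the whole suite fast.

## Known limitations

* The karyotype dialect covers the lesion vocabulary the risk rules need,
  not full ISCN (no idem/sl/sdl, uncertain bands, or derivative-chromosome
  band arithmetic); t(9;11) is recognized by its chromosome pair rather
  than requiring the q23 band.
* The 45-gene panel vocabulary is only partially reconstructable from
  published material; unknown gene symbols are accepted with a warning.
* The blueprint is one consistent completion of published marginal counts,
  not a reconstruction of the real cohort's joint genotype distribution.
* Exponential outcomes cannot express late-plateau survival; calibration
  targets are limited to printed summary parameters (hazard ratios, CR
  rates, median follow-up), not curve shapes.
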