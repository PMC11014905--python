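# eln-aml-strat

Genetic risk stratification of acute myeloid leukemia (AML) under the
European LeukemiaNet (ELN) 2017 and 2022 recommendations, together with the
survival statistics needed to validate and compare the two stratifications
on censored cohort data.

The package is aimed at hematology biostatisticians and methodologists who
want to study how the 2022 revision reshuffles patients between the
favorable, intermediate and adverse risk groups, and what that reshuffling
is worth prognostically — without access to identifiable patient data. It
provides:

* **Rule engines.** Deterministic implementations of both editions. The
  engines consume a genotype profile (cytogenetic feature flags parsed from
  an ISCN-like karyotype string, plus curated mutation calls) and emit a
  risk group with a full trace of the rules that fired. The editions differ
  in five mechanisms: the FLT3-ITD allelic ratio (used only in 2017, with
  the low/high split at 0.5), the CEBPA rule (biallelic in 2017 vs in-frame
  bZIP in 2022), myelodysplasia-related gene mutations (*ASXL1*, *BCOR*,
  *EZH2*, *RUNX1*, *SF3B1*, *SRSF2*, *STAG2*, *U2AF1*, *ZRSR2* —
  adverse-defining in 2022 unless a favorable-defining lesion co-occurs),
  adverse cytogenetics overriding mutated *NPM1*, and the 2022 changes to
  the cytogenetic adverse list (adding t(3q26.2;v) and t(8;16), exempting
  hyperdiploid karyotypes from the complex-karyotype rule).
* **Survival statistics**, implemented from first principles and verified
  against independent oracles: Kaplan–Meier with Greenwood variance and
  log(−log) confidence intervals, reverse-KM median follow-up, (pairwise)
  log-rank tests, Cox proportional-hazards regression (Newton–Raphson,
  Efron/Breslow ties, optional binary time-dependent covariate), the
  Mantel–Byar test, Harrell's C with a paired jackknife comparison, and the
  censored category NRI (net reclassification improvement).
* **A synthetic-cohort generator.** A label-free blueprint of genotype
  archetypes that, once pushed through the rule engines, reproduces the
  reclassification structure of a published 624-patient validation cohort;
  outcomes follow group-calibrated exponential hazards with complete
  remission, transplant, and administrative censoring.
* **A validation pipeline and CLI** tying it all together into
  machine-readable reports.

## The statistics in brief

For a risk score built from the ordered groups (favorable < intermediate <
adverse), Harrell's C is the probability that, of a comparable patient pair
under censoring, the higher-scored patient fails first; ties in score count
1/2. The category NRI at horizon *t* is

    NRI(t) = [P(up | event by t) − P(down | event by t)]
           + [P(down | no event by t) − P(up | no event by t)]

with the cell-wise event probabilities estimated by Kaplan–Meier so that
censoring before *t* is handled consistently. The Cox model maximizes the
partial likelihood; the Mantel–Byar test is its score test for a binary
time-dependent exposure (here: transplant), crediting pre-transplant
person-time to the untransplanted state.

## Worked example

```python
python examples/02_classify_crosstab.py
```

```
rows: 2017 group / columns: 2022 group
                   favorable  intermediate       adverse
     favorable           184            31             3
  intermediate            21           231            46
       adverse             0            33            75

2022 group sizes: {'favorable': 205, 'intermediate': 295, 'adverse': 124}
reclassified: 134 (21.5%)

example patient P0002:
  2017: favorable ('npm1_with_low_ar_flt3_itd',)
  2022: intermediate ('npm1_with_flt3_itd',)
```

Each row of the table is a 2017 risk group, each column its 2022
destination: 31 patients with mutated *NPM1* and a low-allelic-ratio
FLT3-ITD drop from favorable to intermediate (the trace above shows why),
46 carriers of myelodysplasia-related mutations move from intermediate to
adverse, and 33 patients with wild-type *NPM1* and a high-ratio FLT3-ITD
move up from adverse to intermediate. In total 134/624 (21.5%) patients
change groups.

`examples/03_survival_comparison.py` continues with outcomes (seed 42):

```
five-year overall survival by 2022 group:
     favorable: 55.2% (95% CI 47.7%-62.1%)
  intermediate: 37.1% (95% CI 31.4%-42.9%)
       adverse: 10.9% (95% CI 5.8%-17.8%)
...
Harrell's C: 2017 = 0.586, 2022 = 0.620, delta = 0.034 (p = 0.000)
NRI at 5 years: +0.133 (95% CI +0.056 to +0.205)
```

i.e. on this synthetic draw the 2022 stratification orders survival better
than the 2017 one, and the five-year NRI is positive: the revision moves
patients who die toward higher risk and survivors toward lower risk more
often than the reverse. `examples/04_transplant_effect.py` shows the
transplant pattern that motivates the exercise: a time-dependent hazard
ratio near 1 in the favorable group and about 0.5 elsewhere.

The same analyses run from the shell:

```
eln-aml-strat simulate --seed 42 --out cohort/
eln-aml-strat classify --patients cohort/patients.tsv --mutations cohort/mutations.tsv --out calls/
eln-aml-strat validate --out report/ --seed 42
```

## Layout

```
src/eln_aml_strat/
  cohort.py      patient/mutation/outcome types, TSV interchange
  karyotype.py   ISCN-like parsing into cytogenetic feature flags
  classify.py    the 2017/2022 rule engines and the cross-tab
  survival.py    KM, log-rank, Cox, Mantel-Byar, C-index, NRI
  simulate.py    blueprint-driven synthetic cohort generator
  pipeline.py    orchestrated validation runs with JSON reports
  cli.py         eln-aml-strat simulate|classify|survstats|validate
docs/methods.md  modelling assumptions, calibration, limitations
examples/        narrative scripts, one per capability
```
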