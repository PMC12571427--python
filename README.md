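# phenoequiv

Tools for comparing rule-based type 2 diabetes (T2D) computable phenotypes on
patient-level EHR-style data, estimating stratified prevalence, and testing
equivalence of prevalence estimates with the two one-sided tests (TOST)
procedure for two independent proportions.

The package implements:

* **`phenoequiv.datamodel`** — a six-table patient-level data model
  (patients, encounters, diagnoses, labs, medications, pregnancies) with CSV
  round-trip, validation, and ICD code normalization / textbox-style pattern
  matching (`E11.x` prefix patterns, `250.x0` fixed-wildcard patterns).
* **`phenoequiv.cp1`** — a broad phenotype using labs (HbA1c ≥ 6.5 %,
  fasting glucose ≥ 126, random glucose ≥ 200 on ≥ 2 dates in a 2-year
  window), diagnosis codes (ICD-9 250.x; ICD-10 E10.x/E11.x/E14.x on ≥ 2
  dates), insulin outside pregnancy, and 29 non-insulin antidiabetic
  ingredients; type-1 exclusion via C-peptide, autoantibodies, urine acetone
  test strips, and T1D:T2D code-ratio rules.
* **`phenoequiv.cp2`** — a two-step phenotype: wide-net candidate capture
  over a 3-year window, diabetes confirmation by diagnosis codes only
  (250.x0/250.x2, E08.x/E10.x/E11.x/E13.x), then a T2D decision from the
  type-1-to-total code ratio (with both the literal three-clause OR rule and
  the ratio-only variant).
* **`phenoequiv.prevalence`** — eligibility windows (2-year catchment-
  restricted vs. 3-year open), ages 18–44, and stratified
  numerator/denominator prevalence tables by age group, sex and
  race/ethnicity.
* **`phenoequiv.tost`** — unpooled-Wald TOST with a ±2.5 percentage-point
  margin and 90 % CIs; the `printed_table` convention reproduces the
  published stratum table cell-for-cell, `analytic` is the default for new
  analyses.
* **`phenoequiv.table1`** — the published stratum counts embedded as a
  fixture, with a cell-level reproduction check.
* **`phenoequiv.simulate`** — a synthetic EHR generator with known truth
  labels, per-domain capture probabilities, type-miscoding noise, pregnancy
  intervals and a configurable two-system catchment, built on common random
  numbers so observation parameters can be varied with clinical truth held
  fixed.
* **`phenoequiv.pipeline` / CLI** — simulate → phenotype → prevalence → TOST
  orchestration with a run manifest.

## CLI

```sh
# generate a synthetic bundle (six CSV tables + truth.csv)
phenoequiv simulate --config sim.yaml --out data/

# label patients with either phenotype
phenoequiv phenotype --algorithm cp1 --year 2022 --in data/ --out cp1_labels.csv
phenoequiv phenotype --algorithm cp2 --year 2022 --mode or_printed --in data/ --out cp2_labels.csv

# stratified prevalence and equivalence
phenoequiv prevalence --labels cp1_labels.csv --in data/ --cp cp1 --year 2022 --out cp1_prev.csv
phenoequiv prevalence --labels cp2_labels.csv --in data/ --cp cp2 --year 2022 --out cp2_prev.csv
phenoequiv tost --cp1 cp1_prev.csv --cp2 cp2_prev.csv --convention analytic --out equivalence.csv

# recompute the published stratum table from embedded counts
phenoequiv reproduce-table1

# or run everything end-to-end from one YAML config
phenoequiv run --config pipeline.yaml
```

A minimal `sim.yaml`:

```yaml
n_patients: 10000
prevalence_year: 2022
true_t2d_prev: 0.06
catchment_fraction: 0.7
seed: 20220101
```

A minimal `pipeline.yaml`:

```yaml
out_dir: out/
prevalence_year: 2022
simulate:
  n_patients: 10000
  seed: 20220101
convention: analytic
```

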