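# pgstrend

Tools for asking whether a polygenic score's predictive power changes across
birth cohorts. The package covers the full analysis path:

- **`pgstrend.scoring`** — polygenic score construction from a GWAS weight
  table (TSV) and a biallelic genotype VCF: id-based variant matching,
  removal of strand-ambiguous (A/T, C/G) records, effect-allele orientation
  with complement-dosage flips, mean imputation of missing dosages, no
  p-value thresholding, and mean-0/SD-1 standardization.
- **`pgstrend.structure`** — genotype PCA (PLINK-style `2p(1-p)` scaling)
  on a designated reference subset, projection of all samples, and OLS
  residualization of scores on the top components (default 10).
- **`pgstrend.phenotypes`** — wave-long to per-person phenotype derivation:
  mean BMI, max height, ever-reported heart disease, log(mean CESD + 1),
  pass-through education years.
- **`pgstrend.trend`** — the penetrance model: OLS of phenotype on
  intercept, standardized score, centered birth year, and score x year;
  CR1 cluster-robust (Huber-White) covariance by household; SIMEX
  simulation-extrapolation correction for score measurement error; and a
  Brown-Forsythe variance-homogeneity check across equal-frequency birth
  cohort bins.
- **`pgstrend.figure`** — fitted lines at +/-1 score SD and binned means by
  score sign across 20 equal-count birth-year bins, plus plotting.
- **`pgstrend.simulate`** — a synthetic-cohort generator (Balding-Nichols
  subpopulation structure, Hardy-Weinberg dosages, noisy published weights,
  spousal household clustering, assortative-mating and mortality-selection
  knobs) with known ground truth, so the whole pipeline is testable without
  restricted survey genotype data.
- **`pgstrend.pipeline`** — one-call orchestration producing a
  deterministic JSON report per phenotype.

## Command line

```sh
pgstrend simulate --config sim.yaml --out data/ --seed 1
pgstrend score --vcf data/genotypes.vcf --weights data/weights.tsv --out scores.csv
pgstrend adjust --scores scores.csv --vcf data/genotypes.vcf --k 10 --out adj_scores.csv
pgstrend phenotypes --in data/phenotypes.csv --out persons.csv
pgstrend trend --scores adj_scores.csv --phenotypes persons.csv \
    --phenotype bmi --simex-reliability 0.8 --bins 8 --out report.json
pgstrend figure --scores adj_scores.csv --phenotypes persons.csv \
    --phenotype bmi --bins 20 --out fig1.png
```

`simulate` reads a YAML file mirroring `pgstrend.simulate.SimConfig`; all
keys are optional. `score` writes a `person_id,raw_score,std_score` CSV and
a `.match.json` sidecar with the variant-matching tallies. `trend` emits a
JSON block with coefficients, classical and cluster-robust standard errors
and p-values, the SIMEX-corrected interaction, and the variance-by-cohort
report. `figure` also writes the binned means as `<out>.bins.csv`.

## File formats

- genotypes: VCF v4.2, biallelic SNPs, GT genotypes (missing as `./.`)
- weights: tab-delimited with header
  `snp  effect_allele  other_allele  beta  se  pval` (`NA` for missing)
- phenotypes: wave-long CSV with header
  `person_id,household_id,birth_year,wave,educ,bmi,height,heart,cesd`
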