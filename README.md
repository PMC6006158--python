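# hetgwis

Genome-wide gene-by-smoking interaction scans of longitudinal lung function
(FEV1) with linear mixed models that allow **stratum-specific residual
covariance** (heteroscedasticity by smoking status).

The pipeline implements:

- **Filtering step** — per-SNP screening (minor-allele frequency, exact
  Hardy–Weinberg test), ancestry adjustment via principal components of the
  genetic relationship matrix, and a summed stratified likelihood-ratio
  statistic: a 2-DF LRT (SNP + SNP×pack-years) in ever smokers plus a 1-DF
  LRT (SNP) in never smokers, referred to chi-square(3). A pooled
  *homoscedastic* 3-DF LRT is computed alongside as the comparison arm.
- **Testing step** — pooled heteroscedastic mixed-model fits of the
  top-ranked SNPs with per-coefficient Wald tests (SNP main effect,
  SNP×smoking-status, SNP×pack-years) and an overall F test.
- **Calibration** — genomic-control inflation factors and QQ-plot tables
  from genome-wide p-value vectors.
- **Model selection & replication** — AIC selection over smoking codings
  (never-vs-ever, three-level, smokers-only) and covariance structures
  (independence, random intercept + diagonal, unstructured marginal), on
  SNP-free models only; one-tailed replication tests whose direction is
  fixed by the discovery coefficients.
- **Synthetic cohorts** — a first-class generator producing longitudinal
  cohorts with Hardy–Weinberg genotypes, smoking strata, group-specific
  covariance and configurable SNP main/interaction effects, including
  presets mimicking common study designs (three biennial visits,
  cross-sectional, smokers-only).

Estimation is maximum likelihood with fixed effects profiled out by GLS and
covariance parameters optimized on unconstrained scales (log-variances,
log-Cholesky), so every reachable covariance matrix is positive definite.

## Python API

```python
from hetgwis import (SimScenario, simulate_genotypes, simulate_cohort,
                     RunConfig, run_gwis, genomic_inflation)

sc = SimScenario(n_subjects=1000, n_snps=500, seed=1)
geno = simulate_genotypes(sc)
pheno = simulate_cohort(sc, geno)          # null cohort
res = run_gwis(geno, pheno, RunConfig(n_pcs=10, filter_top_k=4))
res.filter_table                            # per-SNP MAF/HWE/3-DF/homoscedastic p
res.testing_table                           # top-k pooled heteroscedastic fits
genomic_inflation(res.filter_table.p_3df).lambda_vif
```

## Command line

Each subcommand reads a YAML config and writes TSV tables plus a JSON run
manifest (seed, config hash, version); identical (config, seed) pairs give
byte-identical outputs.

```bash
hetgwis simulate  --config sim.yaml --out out/sim --seed 1
hetgwis gwis      --config gwis.yaml --out out/scan
hetgwis calibrate --config cal.yaml --out out/cal
hetgwis replicate --config rep.yaml --out out/rep
```

Minimal configs:

```yaml
# sim.yaml
scenario: {preset: kare_like, n_snps: 1000, seed: 1}
# gwis.yaml
genotypes: out/sim/genotypes.tsv
phenotypes: out/sim/phenotypes.tsv
n_pcs: 10
filter_top_k: 4
covariance: unstructured_marginal   # or random_intercept / independence
# cal.yaml
results: out/scan/filter_table.tsv
column: p_3df
# rep.yaml
genotypes: cohort_geno.tsv
phenotypes: cohort_pheno.tsv
snps: [snp00042]
directions: {snp00042: {snp: "-", "snp:status[ever]": "-"}}
```

Genotypes are accepted as PLINK `.raw` additive exports
(`genotype_dialect: plink_raw`) or as a plain TSV with a `sample_id` column
(optionally preceded by a `#alleles` line). Phenotypes are long-format TSV
with columns `subject_id, visit, time, fev1, age0, sex, height, bmi,
smoking, pack_years` (one row per subject-visit; smoking in
never/former/current; pack-years 0 for never smokers).

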