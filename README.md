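# ssblup

Variance-component estimation and single-step genomic prediction for
composite (multi-breed) populations, with a synthetic population generator
for fully reproducible end-to-end testing.

The package covers the complete analysis chain for single-trait animal
models in a four-type composite population:

- **`ssblup.simpop`** — synthetic composite-population generator: multi-
  generation pedigree with breed fractions, gene-dropped unlinked SNP
  genotypes, phenotypes under a configurable fixed + additive + residual
  model, true breeding values, and (selective) genotyping.
- **`ssblup.pedigree`** — pedigree ingestion and recoding, inbreeding
  (Meuwissen–Luo), tabular numerator relationship matrix A and subsets
  (A22), Henderson's sparse A⁻¹, breed-composition propagation, summary
  statistics.
- **`ssblup.crosscov`** — combined and pairwise heterosis and recombination
  covariates from parental breed compositions.
- **`ssblup.genomic`** — coded SNP file reader/writer, marker QC (call
  rate, MAF, monomorphism, heterozygosity deviation), genomic relationship
  matrix (observed-frequency centering), G blending, and single-step
  H⁻¹ assembly.
- **`ssblup.mme_reml`** — design matrices for the five model
  parameterisations (M1–M5), REML log-likelihood via the mixed-model
  equations, AI-REML with EM fallback, BLUP/GBLUP solutions,
  heritability with delta-method SEs.
- **`ssblup.model_compare`** — AIC, BIC, likelihood-ratio tests, and
  delta-AIC support classification.
- **`ssblup.lr_validation`** — forward-validation splits and the LR-method
  statistics: accuracy, dispersion, bias.
- **`ssblup.pipeline`** / **`ssblup.cli`** — experiment-grid orchestration
  (models × relationship sources) and the command-line interface.

## Command-line usage

```sh
# simulate a population into ./sim
ssblup simulate --seed 1 --out sim

# SNP quality control
ssblup qc --snp-file sim/genotypes.txt --out sim/genotypes_qc.txt --report qc.yaml

# variance components for model M3 with the single-step H matrix
ssblup fit --pedigree sim/pedigree.csv --phenotypes sim/phenotypes.csv \
    --model M3 --relationship H --snp-file sim/genotypes_qc.txt --out m3h.yaml

# compare fitted models, forward-validate, summarise the pedigree
ssblup compare --fits m1a.yaml --fits m3h.yaml --out comparison.csv
ssblup validate --pedigree sim/pedigree.csv --phenotypes sim/phenotypes.csv \
    --model M1 --sigma-u2 0.4 --sigma-e2 1.6 --last-years 2 --out lr.csv
ssblup summary --pedigree sim/pedigree.csv

# full 5-model x {A, H} grid with reports
ssblup report --seed 1 --out results/
```

## File formats

All artefacts are plain text: pedigree/phenotype/covariate/truth CSVs, a
coded SNP file (`id` + contiguous `0/1/2` string, `5` = missing), YAML
configs and reports.
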