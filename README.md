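# prsport

Polygenic risk score (PRS) construction and portability evaluation for sleep
traits, exercisable end-to-end on a synthetic two-cohort experiment.

The pipeline takes GWAS summary statistics from a discovery cohort, scores a
target cohort, and measures how much of the target trait the score explains:

1. **`prsport.sumstats`** — summary-statistic reading, validation, filtering
   (INFO > 0.8, MAF > 0.01, strand-ambiguous and multiallelic exclusion) and
   allele harmonization against the target's counted alleles.
2. **`prsport.cohort`** — target genotype/sample QC: INFO ≥ 0.9 and
   autosome-only variant filters, heterozygosity F coefficients with ±3 SD
   outlier removal, a genomic relationship matrix, and greedy relatedness
   pruning at 0.125.
3. **`prsport.structure`** — LD r², window-based LD pruning, and principal
   components (default 6) on the pruned variants for structure covariates.
4. **`prsport.clumping`** — greedy p-value-ordered LD clumping
   (p < 5e-4, ±250 kb, r² 0.1) and weighted-allele scoring (average and sum
   forms, frequency mean-imputation of missing dosages).
5. **`prsport.evaluate`** — phenotype preparation (sleep-duration cuts,
   seeded selection among repeated questionnaire answers), trait
   dichotomization rules, incremental R² from nested OLS, McFadden pseudo-R²
   (1 − d1/d0) from nested logistic fits, Welch group comparisons, and
   5%-tail contrasts with nearest-rank quantiles.
6. **`prsport.simulate`** — synthetic two-cohort generator: AR(1)
   latent-threshold LD-blocked genotypes, additive phenotypes at a configured
   heritability with a shared causal architecture, marginal discovery GWAS,
   and ordinal questionnaire-style traits.
7. **`prsport.pipeline`** — end-to-end orchestration from a flat YAML config
   with a machine-readable manifest and reports.

## CLI

```sh
# generate a synthetic experiment
prsport simulate --config sim.yaml --seed 1 --out simdir/

# per-stage commands
prsport sumstats-qc --sumstats ss.tsv --out kept.tsv --report qc.json
prsport cohort-qc --geno-dosages d.tsv --geno-variants v.tsv --out-prefix qc
prsport clump --sumstats kept.tsv --geno-dosages qc.dosages.tsv \
    --geno-variants qc.variants.tsv --p-max 5e-4 --window-kb 250 --r2 0.1 \
    --out clumps.tsv
prsport score --sumstats kept.tsv --clumps clumps.tsv \
    --geno-dosages qc.dosages.tsv --geno-variants qc.variants.tsv \
    --mode average --out scores.tsv
prsport evaluate --scores scores.tsv --pheno pheno.tsv --pcs pcs.tsv \
    --trait sleep_duration --model linear --tails 0.05 --out report.json

# full pipeline from a config (use a `simulate:` stanza or `inputs:` paths)
prsport run --config run.yaml --out rundir/
```

A minimal `run.yaml`:

```yaml
seed: 42
simulate:
  n_discovery: 20000
  n_target: 5000
  n_variants: 2000
  m_causal: 100
  h2: 0.098
```

All QC/clumping thresholds default to the study values (INFO 0.8/0.9,
MAF 0.01, 3 SD heterozygosity, 0.125 relatedness, p 5e-4, 250 kb, r² 0.1,
6 PCs, 5% tails) and can be overridden per section in the config.

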