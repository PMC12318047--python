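# rareburden

Rare-coding-variant gene discovery for stratified case-control exome studies,
with trio de novo support and gene-set enrichment:

- **Variant model** (`rareburden.variants`) — consequence/MPC variant-class
  taxonomy (PTV; PTV + missense MPC > 3; PTV + missense MPC > 2; missense
  MPC > 2; synonymous; MPC 2–3), ultra-rarity filters (cohort MAC ≤ 5 and
  reference-panel MAC ≤ 5), singleton definition, exome-wide burden counts.
- **Case-control burden** (`rareburden.cmh`) — per-gene, per-class stratified
  2×2 carrier tables (with male/female splitting for X non-PAR genes), gene
  inclusion rules (≥ 2 strata with carriers or the designated largest
  stratum; clonal-haematopoiesis gene exclusion), two-sided
  Cochran–Mantel–Haenszel chi-square with continuity correction,
  Mantel–Haenszel odds ratio with Robins–Breslow–Greenland 95% CI.
- **De novo + meta-analysis** (`rareburden.meta`) — exact one-sided Poisson
  enrichment tests against per-gene expectations, Fisher combination
  (chi-square, 4 df) gated at case-control P < 0.01, min-P final statistic
  with an explicit multiplicity ledger (Bonferroni over case-control + meta
  tests), Benjamini–Hochberg q-values, and locus-restricted Bonferroni.
- **Gene-set tests** (`rareburden.geneset`) — Firth-penalized logistic
  regression of phenotype on set burden with PCs, sex and exome-wide burden
  as covariates; penalized-LRT p-values, finite estimates under separation.
- **Synthetic studies** (`rareburden.simulate`) — seeded generator of
  complete studies (stratified samples, ultra-rare variant records with
  reference-panel MACs, constrained-gene annotations, trio de novo counts,
  nuisance covariates) with configurable planted odds ratios.
- **Pipeline + CLI** (`rareburden.pipeline`, `rareburden.cli`).

## CLI

```sh
# generate a synthetic study
rareburden simulate --n-genes 200 --n-strata 3 --risk-gene 0:ptv:8 \
    --seed 42 --out-dir scratch/study

# case-control burden scan, then de novo meta-analysis
rareburden burden --variants scratch/study/variants.tsv \
    --samples scratch/study/samples.tsv --genes scratch/study/genes.tsv \
    --out scratch/burden.tsv
rareburden meta --burden-results scratch/burden.tsv \
    --denovo scratch/study/denovo.tsv --out scratch/final.tsv \
    --ledger-out scratch/ledger.tsv

# gene-set enrichment and QQ uniformity check
rareburden geneset --variants ... --samples ... --genesets sets.tsv --out gs.tsv
rareburden qq --pvalues pvals.txt

# full pipeline from a flat YAML config
rareburden run --config examples/demo_config.yaml --out-dir scratch/demo
```

All inputs/outputs are headered TSV (`variants.tsv`, `samples.tsv`,
`genes.tsv`, `denovo.tsv`, `genesets.tsv`); `.` marks absent values.  A VCF
reader (`rareburden.io.variants_from_vcf`) ingests sites annotated with
`GENE`, `CSQ_CLASS` and `MPC` INFO keys.

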