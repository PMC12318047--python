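# Demo study: 3 strata, 200 genes, planted risk genes at OR >= 8.
# Run with:  rareburden run --config examples/demo_config.yaml --out-dir scratch/demo
n_genes: 200
n_strata: 3
stratum_sizes: [[1000, 1000], [1000, 1000], [1000, 1000]]
frac_constrained: 0.3
baseline_carrier_rate: 0.005
risk_genes:
  - [0, ptv, 8.0]
  - [1, ptv, 10.0]
  - [2, mpc_gt2, 8.0]
n_trios: 1000
denovo_rate_per_gene_class: 0.05
denovo_enrichment: 5.0
n_pcs: 10
seed: 42
# analysis settings
mac_cap: 5
meta_gate: 0.01
alpha: 0.05
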