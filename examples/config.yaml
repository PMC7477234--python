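# Demo pipeline: simulate a two-arm dataset, QC + cluster it, run pseudobulk
# differential expression, and discover co-expression modules.
out_dir: scratch/demo_out
seed: 1
stages:
  - name: simulate
    n_genes: 300
    n_cells_per_type: 50
    fraction_de: 0.1
  - name: qc
    min_genes: 30        # the simulated universe is small; real data uses 400
    n_variable_genes: 200
    n_pcs: 20
  - name: de
  - name: modules
    n_variable_genes: 200
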