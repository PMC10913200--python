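# Bundled default simulation run: the full seven-genotype study at a
# desk-scale gene count.  Override out_dir / seed on the command line.
seed: 1
out_dir: scratch/default_run
simulate:
  n_genes: 1200
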