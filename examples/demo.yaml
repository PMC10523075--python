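# Small synthetic demonstration study: 150 modern reference specimens,
# 50 archaeological unknowns, seeded end to end.
seed: 7
out_dir: demo_out
simulate:
  n_per_group: [90, 60, 26, 24]
  seed: 7
n_iter: 100
n_pcs: 20
n_perm: 999
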