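# Demo pipeline: two small synthetic studies, full chain.
# Run with: matfet run --config configs/demo.yaml
seed: 7
out_dir: matfet_demo_out
n_studies: 2
verify_meta: true
sim:
  n_individuals: 5000
  eaf: 0.3
  m: 0.05
  f: 0.03
  rho: 0.1
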