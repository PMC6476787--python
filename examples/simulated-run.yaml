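# Full pipeline on a simulated 11-transect survey.
# Run with:  tundradiv run --config examples/simulated-run.yaml
simulation:
  seed: 7
  drop_one_transect: true
band_edges: [700, 900, 1100, 1300]
n_reps: 200
seed: 7
outdir: tundradiv_out
stages: [alpha, beta, trends, metacom]
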