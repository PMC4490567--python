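# Small pipeline config for `oceanfootprint run --config examples/run_small.yaml --out <dir>`
seed: 42
grid:
  n_lat: 8
  n_lon: 16
  land_fraction: 0.1
years:
  start: 1990
  end: 2000
world:
  n_countries: 3
mc:
  n_trials: 200
bootstrap:
  n_trials: 100
  n_samples: 500
supply:
  n_sims: 500
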