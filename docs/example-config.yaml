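# Run with:  dynattractor run docs/example-config.yaml --out results/
# Any ModelParams field may be overridden under `params`; unknown keys are
# rejected. `experiment_args` are passed to the named builder.
experiment: evolution
experiment_args:
  frequency: 0.016666666666666666   # 1/60 a.u.
  count: 500
seed: 1
reps: 2
params:
  beta: 0.0025
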