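# Fixture-backed counterpart of the first validation experiment
# (n = 1000, uniform +-25%, 50 output times on [0, 50], r = 4): the
# original cell-cycle network's equations are not part of this package,
# so the logistic growth fixture stands in to exercise the same pipeline.
model: logistic
n: 1000
seed: 20150601
time_grid: {t_ini: 0.0, t_end: 50.0, points: 50}
initial_state: [1.0]
r: 4
alpha: 0.01
key_parameters: [r]
parameters:
  r: {baseline: 1.0,   var_pct: 25, nonnegative: true}
  K: {baseline: 100.0, var_pct: 25, nonnegative: true}
output_dir: cellcycle_fixture_out
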