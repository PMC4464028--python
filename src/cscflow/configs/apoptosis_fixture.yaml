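# Fixture-backed counterpart of the second validation experiment
# (n = 1000, uniform, 500 output times on [0, 500], r = 4): the original
# apoptosis network is not part of this package; the bistable cubic
# fixture reproduces the bistable-switch analysis path, with its control
# parameter sampled on the full admissible range like the stress input.
model: bistable_toy
n: 1000
seed: 20150601
time_grid: {t_ini: 0.0, t_end: 500.0, points: 500}
initial_state: [1.2]
r: 4
alpha: 0.01
key_parameters: [p]
bifurcation:
  - {parameter: p, min: 0.1, max: 0.9, points: 81}
parameters:
  p: {min: 0.0, max: 1.0}
output_dir: apoptosis_fixture_out
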