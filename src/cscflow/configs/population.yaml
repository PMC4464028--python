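# Population-model experiment: n = 1000 uniform samples, +-50% around the
# shipped baselines (the symmetric-division probability is sampled on its
# full admissible range [0, 1]), 200 output times on [0, 200], r = 4 levels.
# Baselines are the package defaults — a documented calibration, not ground
# truth from the original study.
model: csc
n: 1000
seed: 20150601
time_grid: {t_ini: 0.0, t_end: 200.0, points: 200}
initial_state: [100.0, 2000.0, 7900.0, 80000.0, 10000.0]
r: 4
alpha: 0.01
key_parameters: [P_sy]
combinations: ["P_sy*omega_CSC", "P_sy*omega_CSC-eta_1"]
scatter_times: [200.0]
bifurcation:
  - {parameter: P_sy, min: 0.0, max: 1.0, points: 201}
plot: {scale: log, formats: [png]}
parameters:
  P_sy:      {min: 0.0, max: 1.0}
  omega_CSC: {baseline: 1.0,    var_pct: 50, nonnegative: true}
  omega_PC:  {baseline: 0.4,    var_pct: 50, nonnegative: true}
  eta_1:     {baseline: 0.015,  var_pct: 50, nonnegative: true}
  eta_2:     {baseline: 0.05,   var_pct: 50, nonnegative: true}
  eta_3:     {baseline: 0.1,    var_pct: 50, nonnegative: true}
  gamma_PC:  {baseline: 0.005,  var_pct: 50, nonnegative: true}
  delta_1:   {baseline: 0.01,   var_pct: 50, nonnegative: true}
  delta_2:   {baseline: 0.01,   var_pct: 50, nonnegative: true}
  delta_3:   {baseline: 0.1,    var_pct: 50, nonnegative: true}
  delta_4:   {baseline: 0.3,    var_pct: 50, nonnegative: true}
  h_CSC:     {baseline: 1.0e-3, var_pct: 50, nonnegative: true}
  h_PC:      {baseline: 1.0e-3, var_pct: 50, nonnegative: true}
output_dir: population_out
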