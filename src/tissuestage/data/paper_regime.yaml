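tissue:
  phi: 0.0129
  Y: 5000.0
  R_m: 4.0e-05
  r0: 1.0e-07
  C0: 5.0e-10
  dP: 100.0
  f: 1.0
  T: 310.0
  delta: 1000.0
  Lambda: 2.5e+19
  lam: 1.0e-05
  a: 0.0322
  b: 0.0003
species:
  D0: 7.0e-10
  D_a: 1.0e-07
  k: 0.05
  c_star: 5.0
  K_ch: 1.0e-05
  c_cell: 0.0
  dz_a: 500.0
  dz_r: 500.0
grid:
  L_factor: 4
  nx: 128
  steps_per_period: 64
  n_periods_max: 60
  tol_sigma: 0.001
sweep:
  Y_min: 2000.0
  Y_max: 150000.0
  n_Y: 200
  spacing: log
  n_periods: 10
  rel_smooth: 0.001
staging:
  Y_healthy: 5000.0
  Y_cancer: 45500.0
  n_mol: 1.2278697219017524e-13
  c_k: 5.909639267824191e-09
  D_Y: 1.0
  dG_r: 0.0
  mode: expansion
  drift: driven
  prominence_rel: 5.0e-05
  stable_tol: 0.05
seed: 0
outdir: results
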