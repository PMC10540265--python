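# Base run of the nickase-gated circuit: built-in default constants,
# reference conditions (base + fuel/enzyme grids), noiseless sampling.
circuit: nickase
options:
  assembly: sequential
  enzyme_law: linear
constants: default
conditions: reference
calibration:
  slope: 150.0
  background: 10.0
solver:
  rtol: 1.0e-8
  atol: 1.0e-12
withdrawal_times: [0, 1, 2, 4, 6, 8, 10]
seed: 0
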