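# Exo III circuit with 5% proportional measurement noise on the readout.
circuit: exoiii
constants: default
conditions: reference
noise:
  kind: proportional_gaussian
  sigma_prop: 0.05
  seed: 7
seed: 7
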