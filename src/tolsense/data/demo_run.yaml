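# Demo cohort: 2 frail + 2 non-frail synthetic subjects, standardized protocol.
cohort:
  seed: 7
  n_frail: 2
  n_nonfrail: 2
  protocol: standardized
  noise_std_g: 0.05
pipeline: {}
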