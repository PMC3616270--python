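# Noise robustness: 20 trials per (sigma_b, sigma_d) cell
include: default
experiment: robustness
drive:
  - {segment: 8, strength: 1.7, onset: 0, duration: 1.2}
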