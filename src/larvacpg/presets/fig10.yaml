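# Two-sided synchrony phase diagram; sustained asymmetric drives
include: default
experiment: two_sided
contralateral_kind: EE
contralateral_weight: 2
t_end: 35
drive:
  - {segment: 8, strength: 1.7, onset: 0, duration: 35, side: left}
  - {segment: 8, strength: 1.72, onset: 0, duration: 35, side: right}
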