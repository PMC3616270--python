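# Sensory feedback sweep; drive 2.5 t.u.
include: default
experiment: sensory
alpha: 25
beta: 20
gamma: 17
drive:
  - {segment: 8, strength: 1.7, onset: 0, duration: 2.5}
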