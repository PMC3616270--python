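# Rescue of a weak-excitation network by sensory feedback
include: default
experiment: rescue
b: 16
alpha: 25
beta: 40
gamma: 0
drive:
  - {segment: 8, strength: 1.7, onset: 0, duration: 1.2}
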