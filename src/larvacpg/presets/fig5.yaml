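# Intersegmental coupling grid; validated single-wave drive
include: default
experiment: coupling
drive:
  - {segment: 8, strength: 1.7, onset: 0, duration: 1.2}
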