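# Drive strength x duration sweep (onset delay and wave counts)
include: default
experiment: drive
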