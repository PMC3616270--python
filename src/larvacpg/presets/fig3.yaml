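# Single forward wave: drive the posterior segment for 2 t.u.
include: default
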