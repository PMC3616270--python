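# Reference parameter set for peristaltic wave propagation
a: 16
b: 20
c: -12
d: -20
e: 15
f: -3
tau_E: 0.5
tau_I: 0.5
tau_S: 0.5
P_ext: 1.7
b_E: 1.3
b_I: 2
b_S: 1.3
theta_E: 4
theta_I: 3.7
theta_S: 2
n_segments: 8
threshold: 0.3
t_end: 15
drive:
  - {segment: 8, strength: 1.7, onset: 0, duration: 2}
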