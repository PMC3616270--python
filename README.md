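# larvacpg

A central-pattern-generator (CPG) model of peristaltic crawling in
*Drosophila* larvae: coupled Wilson–Cowan excitatory/inhibitory (EI)
population units, one per abdominal segment, with nearest-neighbour
chain coupling, optional stretch-sensor feedback, and an optional
mirrored left/right (two-sided) network — together with the wave
metrics and scripted experiments used to characterize the model.

It is written for computational neuroscientists studying segmented
locomotor circuits: the package simulates the network, extracts
segmental "contractions" (suprathreshold excitatory activity), and
quantifies wave propagation the way crawling behaviour is quantified
from video — normalized contraction durations and intersegmental phase
lags — so model output can be compared directly against pooled
behavioural statistics that ship with the package.

## The model

Each abdominal segment A*i* (A8 posterior … A1 anterior) is one EI unit:

```
τ_E Ė_i = −E_i + (k_E − E_i) G_E( a E_i + c I_i + b (E_{i−1} + E_{i+1})
                                  + d (I_{i−1} + I_{i+1}) + β S_i + P_ext,i )
τ_I İ_i = −I_i + (k_I − I_i) G_I( e E_i + f I_i + γ S_i )
τ_S Ṡ_i = −S_i + G_S( α [E_{i+1} − E_i]_+ + α [E_{i−1} − E_i]_+ )
```

with the shifted sigmoid `G(x) = 1/(1+e^{−λ(x−θ)}) − 1/(1+e^{λθ})`
(so `G(0) = 0` and rest is an equilibrium), response ceilings
`k = 1 − 1/(1+e^{λθ})`, signed weights (inhibitory weights negative),
and missing-neighbour terms dropped at the chain ends.  `[x]_+` is
rectification; the S populations model stretch-sensitive sensory
neurons driven by activity differences between neighbouring segments.
A rectangular external drive `P_ext` on the posterior (anterior)
excitatory population launches a forward (backward) wave.  The
two-sided variant duplicates the chain and adds one same-segment
commissural connection of kind E→E, I→E, E→I or I→I.

Default parameters: a=16, b=20, c=−12, d=−20, e=15, f=−3,
τ_E=τ_I=τ_S=0.5, P_ext=1.7, λ_E=1.3, λ_I=2, λ_S=1.3, θ_E=4, θ_I=3.7,
θ_S=2 (all dimensionless; time in model time units, t.u.).

A "contraction" is excitatory activity above the threshold θ_C
(default 0.3; 0.2 in low-activity high-inhibition regimes).  From the
contraction intervals the package computes wave duration, per-segment
normalized contraction durations, intersegmental phase lags, wave
counts under sustained drive, propagation-validity classification and
left/right synchrony.

## Worked example

```python
import numpy as np
from larvacpg import (
    DriveProtocol, default_network, simulate, count_waves,
    normalized_durations, intersegmental_phase_lags,
)

spec = default_network()                       # 8-segment reference chain
protocol = DriveProtocol.single(segment_index=8, strength=1.7, duration=2.0)
traj = simulate(spec, protocol, t_end=15.0)
n, tables = count_waves(traj, threshold=0.3, direction="forward")
durs, wave_duration = normalized_durations(tables[0])
lags = intersegmental_phase_lags(tables[0])
print(f"waves counted: {n}")
print(f"wave duration: {wave_duration:.3f} t.u.")
print("normalized durations (A1..A8):", np.round(durs, 3))
print("phase lags (A8-A7 .. A2-A1):  ", np.round(lags, 3))
```

prints

```
waves counted: 1
wave duration: 1.080 t.u.
normalized durations (A1..A8): [0.266 0.425 0.448 0.453 0.466 0.495 0.552 0.656]
phase lags (A8-A7 .. A2-A1):   [0.082 0.107 0.108 0.108 0.108 0.108 0.112]
```

A single wave sweeps from A8 to A1 in about 1.1 t.u.; the driven
posterior segment stays contracted longest (0.656 of the wave) and the
anterior segment shortest (0.266), and consecutive segments activate
about a tenth of a wave apart — the same range as the phase lags
measured in crawling larvae (0.087 ± 0.050).  Adding stretch-sensor
feedback (α=25, β=20, γ=17) equalizes the contraction durations at a
mean of 0.374, within one standard deviation of the behavioural
0.415 ± 0.076:

```python
from larvacpg import SensorySpec, wave_metrics, compare_to_reference
from larvacpg.reference_data import get_reference

sens = default_network(sensory=SensorySpec(25.0, 20.0, 17.0))
straj = simulate(sens, DriveProtocol.single(8, 1.7, duration=2.5), 15.0)
_, stables = count_waves(straj, 0.3, "forward")
m = wave_metrics(stables[0], "forward", "endpoint_relaxed")
report = compare_to_reference(m, get_reference("normalized_contraction_duration"))
print(f"sensory-feedback mean duration: {m.mean_normalized_duration:.3f}")
print(f"deviation from behaviour: {report.standardized_deviation:+.2f} SD")
# sensory-feedback mean duration: 0.374
# deviation from behaviour: -0.54 SD
```

## Command line

```
larvacpg simulate --preset fig3 --out-dir out/       # baseline forward wave
larvacpg metrics out/trajectory.csv --threshold 0.3
larvacpg sweep robustness --preset fig6 --seed 11
```

Presets `default, fig3 … fig10` package the named experiment protocols;
every command writes a `manifest.json` (resolved config, seed, version)
sufficient to reproduce its outputs.

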