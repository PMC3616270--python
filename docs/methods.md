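# Methods

## Model

Each abdominal segment of the larva (A8 posterior through A1 anterior)
is represented by one Wilson–Cowan unit: a pair of firing-rate
variables for the joint excitatory (E) and inhibitory (I) neuronal
populations of that segment's crawling circuit.  The rate equations
use the shifted logistic response

```
G(x) = 1/(1 + e^{−λ(x−θ)}) − 1/(1 + e^{λθ}),
```

whose subtraction of `G(0)` makes the all-zero state an exact
equilibrium of every model variant: a silent network stays silent until
driven.  The factor `(k − x)` in front of `G` saturates activity at the
response ceiling `k = 1 − 1/(1+e^{λθ})`, the supremum of `G`
(`k_E ≈ 0.9945`, `k_I ≈ 0.9994` at the default slopes/thresholds).
Nothing prevents small negative excursions — `G` is negative for
negative input — and trajectories do transiently undershoot zero by
`~10⁻⁴`; this is a property of the rate model, not a numerical
artifact.

Within a segment, four signed weights couple E and I (self-excitation
a=16, I→E c=−12, E→I e=15, I→I f=−3).  Between segments, two
nearest-neighbour connection types propagate and terminate activity:
excitatory E→E weights b=20 on each undirected neighbour pair, applied
in both directions, and inhibitory weights d=−20 from each segment's I
population onto both neighbouring E populations.  All weights are
stored signed and enter sigmoid arguments with plus signs.  Parameter
files written in the alternative unsigned convention (magnitudes with
the inhibitory sign implied) load via `negate_inhibitory_weights: true`;
both readings give identical dynamics for the default values.

The chain is bidirectionally symmetric, so one network supports both
forward waves (rectangular drive `P_ext = 1.7` on E₈) and their exact
mirror, backward waves (drive on E₁).  Drive pulses are ideal
rectangles starting at t=0 unless configured otherwise; no input ever
reaches inhibitory populations.

**Sensory feedback.**  One stretch-sensor population per segment is
driven by the rectified activity difference to each neighbour,
`α[E_nb − E_i]_+` (ends have a single neighbour), passed through a
sigmoid with a lower activation threshold than E (θ_S=2 < θ_E=4) so
sensors lead the excitatory populations.  S feeds back with weight β
onto E and γ onto I of its own segment.  The S equations carry no
`(k − S)` saturation factor; S is bounded by its sigmoid's ceiling
through the dynamics alone.

**Two-sided model.**  The chain is duplicated into left and right
hemisegment networks sharing all parameters, plus exactly one
same-segment commissural connection type: E→E, I→E, E→I or I→I, with a
signed scalar weight applied identically in every segment.  To avoid
the two deterministic sides starting perfectly aligned, the standard
protocol drives them slightly asymmetrically (1.7 left, 1.72 right).

## Numerics

Integration uses scipy's adaptive RK45 (rtol 1e−8, atol 1e−10) with
dense output, or a classical fixed-step RK4 at step 1e−3.  Both
integrate piecewise between drive-pulse edges with the drive frozen at
each window's midpoint value, so adaptive steps never straddle the
rectangular discontinuity.  Trajectories are resampled on a uniform
grid (default 0.005 t.u.); threshold crossings are then refined by
linear interpolation between samples, making every wave metric
insensitive to the sampling (checked to <1e−3 t.u. against a 10× finer
grid and 10× tighter tolerances).  A sample lying exactly on the
threshold counts as suprathreshold.  The default initial condition is
rest, the natural pre-wave state.

The forward/backward mirror test runs on the fixed-step integrator:
with deterministic steps the mirrored system is the exact mirror image
in floating point (neighbour sums are two-term additions, which are
commutative), so the 1e−6 agreement bound is met with no slack from
step-size control.

## Wave quantification

A contraction is suprathreshold E activity at threshold θ_C, default
0.3; 0.2 is used in high-inhibition two-sided regimes whose activity
peaks below 0.3.  θ_C is an explicit argument of every metric
operation.  For a single wave: wave duration = terminal segment's
contraction offset − initiating segment's onset; normalized durations =
per-segment contraction duration / wave duration; phase lags =
consecutive onset differences / wave duration, ordered from the
initiating end.

Validity classification follows the propagation criterion of the
robustness protocol: onsets and offsets must both follow the
initiating→terminal order (`strict`), with the `endpoint_relaxed`
variant additionally accepting the terminal segment deactivating before
its neighbour — without sensory feedback the terminal segment receives
no onward excitation and routinely switches off early.  One caveat
found in exploration: under the 2 t.u. reference drive the driven
segment A8 outlasts A7 by ~0.02 t.u., an offset-order inversion caused
by the sustained drive itself; the offset-order rule is therefore
applied on the 1.2 t.u. single-wave protocol (where only the terminal
exception occurs), and experiments that use longer drives report
measured metrics alongside the validity flag rather than suppressing
them.

Wave counting under sustained drive: one wave is counted per
suprathreshold excursion of the initiating segment that is followed by
ordered onsets of all remaining segments before the initiating
segment's next excursion.  Under very strong drive (above ≈3.1) the
initiating segment latches into one prolonged contraction; that
excursion counts as a single wave, with the prolonged interval visible
in the returned table.

Left/right synchrony: after discarding a transient (default: all but
the final 9 t.u. of sustained-drive runs), the k-th post-transient
excursion of each segment on one side is paired with the k-th on the
other, and the statistic is the mean absolute onset difference over
matched pairs; unmatched excursions are never silently dropped — they
block the `synchronous` label.  Two thresholds govern classification:
`sync_tolerance` (default 0.1 t.u.) for calling a run synchronous, and
`discard_above` (default 1.0 t.u.) marking runs too misaligned to
analyze.  `alternating` requires the two sides' excursions to strictly
interleave; a silent side yields `no_wave`.

## Experiments

Sweeps are embarrassingly parallel, deterministic given grid and seed,
and every no-wave cell carries a 0 sentinel plus a machine-readable
reason.  Drive durations follow the protocol that defined each
experiment: 2 t.u. for the reference wave, 1.2 t.u. for the validated
single-wave/robustness protocols and the coupling grids, 2.5 t.u. for
the sensory-feedback sweeps, 0.8 t.u. for the over-coupled rescue
regime, 35 t.u. (sustained) for two-sided runs.  Runs simulate 12 t.u.
past the end of the pulse so the last wave can complete.

Noise robustness perturbs the intersegmental weights b and d with
Gaussian noise drawn once per undirected neighbour pair and applied
symmetrically, preserving the chain's bidirectional-symmetry premise
(a per-directed-edge option exists for exploring the alternative
reading).  Samples that would flip the mean's sign are redrawn
(rejection, not clipping, which would pile mass at zero); sampling is
seeded and bit-reproducible.  A trial succeeds when the 1.7/1.2 t.u.
drive initiates exactly one wave passing the endpoint-relaxed rule.

The mistuned regimes of the rescue experiment are not printed in any
reference table; the packaged stand-ins were chosen by search:
weak-excitation b=16 (no wave alone; restored to a valid wave by
α=25, β=40, γ=0) and over-coupled b=30, d=−30, where α=25, β=45, γ=55
moves the mean normalized duration from 0.609 to 0.398, toward the
behavioural 0.415 — the phase lag moves slightly away, so only the
duration improvement is treated as established.

## Problem sizes

The packaged defaults keep every experiment at laptop scale: the
drive-threshold search scans strengths 1.0–4.0 in steps of 0.05
against nine durations spanning 1–30 t.u. (durations tested
longest-first with early exit, since the longest drive is the most
wave-prone); coupling grids use unit-to-2 steps; robustness uses 20
trials per cell; two-sided sweeps use unit weight steps.  The full
test suite runs in ~2.5 minutes and the acceptance script in ~1 minute
on a single core.

## Behavioural reference data

The package carries pooled summary statistics of crawling behaviour as
a read-only, checksum-pinned table: normalized contraction duration
0.415 ± 0.076 and intersegmental phase lag 0.087 ± 0.050 (35 forward
waves, 12 animals, 25°C), absolute wave duration 1.39 ± 0.25 s, duty
cycle 0.83 ± 0.22, and wave/animal counts for the 34°C forward and
backward recordings (whose per-quantity means were published only
graphically and are carried count-only).  Comparisons are pooled-level
standardized deviations, `(model mean − reference mean)/reference SD`.

## What the model does and does not capture

Passing tests show that an 8-unit chain with symmetric nearest-neighbour
coupling reproduces single and repeated peristaltic waves in either
direction with phase lags in the behavioural range, that stretch-sensor
feedback speeds propagation and equalizes contraction durations toward
the observed values, and that E→E or I→E commissural coupling can
synchronize two such chains.  They do not speak to: duty cycles and
inter-wave head/thorax movements (outside the modelled segments),
spiking or biophysical motorneuron/muscle dynamics, connectivity beyond
nearest neighbours, turning or decision-making, or combinations of
several commissural connection types acting at once.  Per-segment
behavioural curves are not packaged, so model-to-behaviour comparison
is possible only at the pooled level.
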