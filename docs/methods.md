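# Methods

`polyphone` simulates a feedforward spiking model of the ascending
auditory pathway and measures two properties of its activity: the
prevalence of reproducible spatio-temporal firing patterns
(polychronization index, PI) and the stimulus information carried by
temporal versus rate codes (MLP-decoder mutual information, MI).  This
note records the model equations, the measurement procedures, the
synthetic input generator, and the numerical and design choices that
were genuinely open.

## Neuron model

Every simulated cell is an Izhikevich quadratic neuron

    dv/dt = 0.04 v² + 5 v + 140 − u + I
    du/dt = a (b v − u),        v ≥ 30 mV  ⇒  v ← c, u ← u + d

integrated by a single forward-Euler step at dt = 0.1 ms (the
two-half-step variant of the original reference implementation is not
used).  Three presets are built in:

| preset                   | a    | b    | c   | d    | role |
|--------------------------|------|------|-----|------|------|
| `excitatory_cortical`    | 0.01 | 0.2  | −65 | 8    | spike-frequency adaptation; A1/Belt excitatory |
| `excitatory_subcortical` | 0.02 | −0.1 | −55 | 6    | Class 1 (graded f–I); CN/IC excitatory |
| `inhibitory`             | 0.02 | 0.25 | −55 | 0.05 | phasic bursting; all interneurons |

All presets share the 30 mV cutoff.  Populations start at the preset's
analytic resting point (the hyperpolarised root of
`0.04 v² + (5 − b) v + 140 = 0`, with `u = b v`), which is an exact
fixed point of the discrete update at `I = 0`.

Synapses deliver Dirac-delta current pulses: a spike of weight `w` (nA)
arriving on a step adds `w` to that step's `I` and nothing afterwards,
so the membrane charge per event is `w·dt`.  One nA of weight is mapped
to one unit of the dimensionless `I` in the equation above.

Two numerical guards apply.  Non-finite states raise immediately
(blow-up is an error, never clamped away).  Separately, `v` is floored
at −100 mV: the quadratic membrane equation is only valid in a basin
around rest, and a strong delta pulse of inhibition (the one-to-all
inhibitory feedback can deliver hundreds of nA in one step) would
otherwise push `v` into the region where the `v²` term produces a
spurious rebound spike, making inhibition excitatory.  The floor keeps
inhibition monotone; it is invisible in normal operation.

## Simulation loop

All populations are concatenated into one state vector and integrated
synchronously: currents accumulated while processing step *k* are
integrated at step *k*+1, so every connection — including the nominally
zero-delay subcortical ones — has a minimum transmission latency of one
0.1 ms step.  Conduction delays are drawn once at build time, quantised
to the dt grid, and realised with per-projection ring buffers; a spike
with delay Δ is delivered exactly `max(1, ceil(Δ/dt))` steps after
emission.  Delivered current uses the weight at emission time; with the
small per-pairing updates of the learning rule the difference from
lookup-at-arrival is far below every tolerance used here.

Neuron states, input currents and plasticity ledgers are reset at each
presentation onset.  The inter-word silence appended to every
presentation serves segmentation and lets delayed activity play out;
with the reset, presentations are exchangeable and runs are
bit-reproducible for a fixed build seed.

## Architectures

`preset_config("full")` reproduces the reference parameter table: an
auditory-nerve (AN) input layer of 1000 fibres; cochlear-nucleus
subpopulations CH (chopper: Gaussian tonotopic input, σ = 26 fibres,
weights U[25, 30]), PL (primary-like: one-to-one, 1000 nA) and ON
(onset: sparse wide-band input, 46% dead synapses, 26 nA); convergence
in IC (CH→IC Gaussian σ = 2 at 400 nA, PL→IC one-to-one 400 nA, ON→IC
full 3 nA); and two plastic cortical stages A1 and Belt with full
connectivity, initial weights U[30, 35] nA, conduction delays
U[0, 50] ms, and mixed STDP.  Within every simulated layer each
excitatory cell drives a dedicated inhibitory partner (w_EI) and each
inhibitory cell projects to all excitatory cells (w_IE ≤ 0); CH and PL
have this feedback disabled (w_EI = w_IE = 0), ON uses −75 nA, A1 and
Belt −6 nA.  `preset_config("reduced")` removes CN and IC: AN projects
straight to A1 (and A1 to Belt) with the same plastic connectivity and
a stronger LTD magnitude (−0.033 instead of −0.015).

The AN→ON sparsity follows the parameter table (0.46 *dead* synapses).
The alternative reading found in the accompanying text (34% live
connectivity, i.e. 0.66 dead) can be requested by overriding `p_dead`
in the config dictionary.

### Miniature instances

`size_factor < 1` scales every population count for desk-scale work.
Weights cannot all scale the same way, because different projections
implement different computations:

* projections whose afferent count grows with the source population
  (full, sparse, the wide AN→CH Gaussian) scale their weights by
  `1/size_factor`, preserving the summed drive per target cell; the
  one-to-all inhibitory weight scales likewise;
* AN→ON scales by `sqrt(1/size_factor)`: onset cells are synchrony
  (fluctuation) detectors, and √N compensation keeps the z-score of a
  synchronous volley constant across scales, whereas full compensation
  tips miniature instances across the bifurcation into tonic firing;
* the narrow CH→IC convergence keeps σ = 2 and its weight (its
  afferent count is a handful of cells at any scale), as do all
  one-to-one projections;
* the plastic cortical projections keep the reference weights, ceiling
  and STDP constants exactly: they are coincidence detectors, and the
  per-event quantum (dt·w) must stay well below the distance to
  threshold for selectivity to be possible at all.

At `size_factor = 1` the reference table is reproduced verbatim.

## Plasticity

The mixed exponential STDP rule (LTP multiplicative towards the ceiling
`w_max`, LTD additive with a hard floor at 0 nA):

    f(s) = α_p e^(−s/τ_p)   s > 0 (LTP)      w ← w + (w_max − w) f(s)
    f(s) = α_d e^(s/τ_d)    s < 0 (LTD)      w ← max(0, w + w_max f(s))

with `s = t_post − (t_pre + Δ)` computed on *arrival* times.  Defaults:
τ_p = 15 ms, τ_d = 25 ms, α_p = 0.005, α_d = −0.015 (full model) or
−0.033 (reduced), w_max = 60 nA.  Since |α_d|·τ_d = 0.375 > α_p·τ_p =
0.075, uncorrelated activity drifts weights downward; only reliably
pre-before-post synapses escape the drift.  That depression dominance
is the engine of the pattern-from-noise mechanism.

Pairing is nearest-neighbour with a first-spike-only burst rule, and
three details were left open by the source description:

* **Burst window.**  Later spikes of the same pre-synaptic cell within
  τ_p (15 ms) of its registered arrival count as the same burst and are
  ignored; a spike beyond that re-registers (and overwrites the pending
  arrival), so pairing remains nearest-neighbour between distinct
  firing events.  An alternative reading — suppressing re-registration
  for the whole 7·τ truncation horizon — throttles plasticity to a few
  pairings per second per synapse and destroys credit assignment.
* **Ties.**  `s = 0` exactly (arrival and post spike on the same step)
  produces no update; the arrival stays pending.
* **LTD symmetry.**  Each registered arrival pairs for LTD with the
  most recent preceding post spike; whether the source intended a
  first-spike restriction on the post side as well is unstated, and the
  symmetric nearest-neighbour reading is used.

Pairings with |s| beyond 7·max(τ_p, τ_d) are skipped (the scale factor
is below 10⁻³ of α); updates are applied online at pairing time, not
batched per stimulus.

## Synthetic auditory-nerve input

The cochlear front end is replaced by a generative surrogate
(`vowel_templates` + `generate_dataset`) that keeps the statistics the
learning mechanisms rely on, modelled on nerve responses to voiced
speech: at every cycle of a fundamental period, a contiguous band of
fibres (10% of the tonotopic axis) fires a volley of 3 spikes per fibre
at 1 ms spacing; the band centre follows a smooth sinusoidal trajectory
across the axis.  **Class identity is the phase of that trajectory**
(which tonotopic regions activate in which order); **the fundamental
period is the speaker latent**, swept smoothly over 8–12 ms
(10 ms ± 20%) by linear interpolation between anchor pronunciations —
speakers with longer periods traverse the same trajectory more slowly.
Because all classes share the trajectory shape, time-averaged per-fibre
rates are nearly class-independent, and class identity lives in the
spatio-temporal structure.  Equal per-class spike budgets stand in for
loudness normalisation.  Dense speaker sampling makes nearest
neighbours of an exemplar other exemplars of the same class (the
continuous-transformation constraint), which the test suite checks
directly.

Fibre noise has four degrees of freedom: Gaussian temporal jitter of
pattern spikes (truncated at ±3 s.d.), spatial "volley-principle"
jitter relocating a spike to a uniformly chosen fibre within a
neighbourhood, random deletion of pattern spikes, and additive
background Poisson firing during the stimulus portion.  The experiment
defaults — background 8 Hz, jitter 2.5 ms, spatial range 4 fibres,
deletion 0.45 — sit deliberately in the stress regime the subcortical
stages exist to overcome (jitter of a few ms, additive noise
approaching 10 Hz, loss of almost half the pattern spikes): at these
levels the raw AN rasters are unstable enough that direct cortical
learning largely fails, while the CH/ON/IC chain still recovers the
class structure.  No background is generated during the silent tail.

What the generator does **not** emulate: cochlear filtering and
phase-locking fine structure, refractoriness, rate adaptation,
across-trial rate drift, and realistic speech variability beyond a 1-D
pronunciation manifold.  Passing tests therefore demonstrate the
network-and-measurement machinery under controlled statistics, not
performance on real speech.

`masquelier_benchmark` generates the single-neuron control stream: time
is tiled into 40 ms segments, each independently hosting a frozen
pattern with probability 0.25 over half of 200 afferents; the pattern
template is itself one Poisson draw at the background rate, so pattern
segments are rate-matched to the background to first order (up to the
one frozen draw's sampling error), and only the repeating alignment
distinguishes them.

The single detector neuron trained on this stream must sit in a
fluctuation-driven regime: its mean drive stays below rheobase and
spikes arise from density peaks, so its firing carries the input
correlations the learning rule needs.  The working operating point is
a Class-1 cell with 200 plastic afferents initialised at U[40, 45] nA
(w_max 60) on a 25 Hz stream, with benchmark-specific learning
magnitudes α_p = 0.05, α_d = −0.025, τ_d = 20 ms — per-event LTP and
LTD roughly balanced, as in the original single-neuron study.  With the
word model's much smaller, depression-heavy constants the detector
either never breaks symmetry or silences itself before latching; with
supra-rheobase drive it fires on its intrinsic rhythm, decorrelated
from the input, and cannot latch either.  Latching is stochastic
(roughly 40% of 250 s streams): a latched detector fires several Hz
inside pattern windows and essentially never outside, an unlatched one
fires rarely everywhere, so detection quality is summarised by in- vs
out-of-pattern firing rates pooled across seeds.

## Polychronization index

For each reference cell *j* and each presentation in which it fires,
one of its spikes is sampled uniformly and the other cells' spikes are
binned at 1 ms into a (layer size × 101) matrix over the ±50 ms window
(the maximum conduction delay).  Matrices are averaged over the
exemplars of a class, the centre element (cell *j*, lag 0) is excluded,
and `a_s` is the mean of the ten largest elements divided by the
layer's mean firing statistic *f*; `PI = max_s a_s`.  Open details
resolved here: *f* is the mean spike count per cell per 1 ms bin pooled
over all analysed presentations (making `a_s` dimensionless and PI → 1
the asymptotic chance level); the ten maxima are not constrained to
distinct cells; ties break by (count desc, lag asc, cell asc);
presentations where *j* is silent are skipped and counted, not
zero-filled; windows overlapping presentation edges are zero-padded.

Two scale caveats matter when reading PI values.  The top-ten statistic
of a finitely-averaged matrix sits above *f* by an extreme-value excess
that shrinks slowly (∝ 1/√K over K exemplars), so PI under a Poisson
null is well above 1 for small K.  And because *f* normalises by rate,
sparsely and periodically firing layers (e.g. the reduced model's
cortex at miniature scale) can post large PI values without carrying
any stimulus information — PI measures reproducibility, not
informativeness.  For this reason the qualitative denoising claim is
asserted as PI(IC) dominating PI(AN) in the full model, and no
assertion is made about the reduced model's cortical PI.

## Information analysis

Temporal features: for each of J = 100 sampled reference cells, every
presentation is summarised by the (100 × 101) windowed matrix over the
same cell sample around one sampled reference spike, compressed to 100
row sums + 101 column sums (201 values).  Rate features: mean firing
rates (Hz) of 201 sampled cells.  One MLP per reference cell (hidden
layer of 20 tanh units ≈ 10% of the input size, cross-entropy loss,
L-BFGS to convergence — any convergent method on that objective is
acceptable) is trained on a stratified 50/50 presentation split; the
ensemble prediction for a held-out presentation is the majority vote,
with silent-reference abstentions and ties resolving to the lowest
class index.  Votes fill the 2 × 2 joint table
`p(r, s) = #{predict r | class s} / (#class-s presentations × 2)`,
from which I(S;R) is computed with 0·log 0 = 0; the ceiling is
H(S) = 1 bit for two equiprobable classes and the plug-in bias
`#bins / (2 N ln 2)` is reported alongside (≈ 0.004 bits at N = 752,
negligible, and not subtracted).  The procedure repeats over fresh cell
subsamples to yield a distribution.  The decoder is a measurement
instrument; no claim is made that the brain implements it.

## The comparison study

`run_comparison_study` packages the end-to-end protocol at miniature
scale (defaults: size_factor 0.2, i.e. 200 cells per layer; 120 ms
patterns + 60 ms silence; 4 training speakers presented 10 times in a
fixed interleaved schedule; 4 test speakers × 4 repetitions = 32
held-out presentations; J = 25 decoder cells, 6 subsamples per
condition).  Problem sizes were chosen once as the smallest instance in
which every stage of the full model is active (under the default noise:
CH ≈ 8 Hz, ON ≈ 2 Hz, PL ≈ 14 Hz, IC ≈ 17 Hz, A1 ≈ 6 Hz); they are the
package's scaled study conditions.  The qualitative claims asserted as medians over ≥10 seeds
in the acceptance suite: IC's PI exceeds AN's (subcortical denoising);
the trained full model's A1 carries more temporal MI than the untrained
network and than the reduced model's A1; temporal MI ≥ rate MI;
training shifts the plastic weight median down while leaving a
strengthened tail above the initial band in the full model; and
rate-matched patternless input (every pattern spike deleted, its rate
folded into the background — the analogue of per-step spike
permutation) drives the reduced model's weights far below the band.

Two findings of the full-scale study do **not** survive the 5× scale
reduction, and the suite documents rather than hides this.  The
shuffled-weight control is not reliably below the trained network at
200 afferents: permuting the trained weights preserves their pruned-
plus-strengthened *distribution*, which at this scale carries most of
the transmission benefit on its own (the control separates assignment
from distribution only when an unselective cortex is uninformative, as
at 1000 cells).  And the second cortical stage (Belt) is
coincidence-starved (≈ 2–3 Hz) with MI at the estimator floor, so MI
assertions are made at A1, with Belt still simulated and reported.

## Known limitations

* The miniature-scale compensation rules are heuristic; only
  `size_factor = 1` reproduces the reference table exactly, and
  absolute PI/MI values at miniature scale are not comparable to
  full-scale values.
* MI estimates from ~12 held-out presentations are coarsely quantised;
  only orderings of medians over seeds are meaningful.
* The generator's pronunciation manifold is one-dimensional; real
  speaker variability is not.
* Training uses presentation-boundary resets, so no information
  crosses word boundaries.
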