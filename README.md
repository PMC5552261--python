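# polyphone

A spiking neural network model of the ascending auditory pathway for
studying how *temporal* spike codes — reproducible spatio-temporal
firing patterns known as polychronous groups (PGs) — can come to carry
word-category information through unsupervised learning, and the
measurement tools to quantify that: a per-cell **polychronization
index** (PI) and a temporal-vs-rate **mutual-information** (MI)
decoding protocol.  It is aimed at computational neuroscientists who
want a desk-scale, fully reproducible re-implementation of this class
of model: Izhikevich point neurons, conduction delays, and mixed
spike-timing-dependent plasticity, driven by a synthetic
auditory-nerve surrogate.

## The model in brief

Every cell follows the Izhikevich quadratic dynamics

    dv/dt = 0.04 v² + 5v + 140 − u + I,   du/dt = a(bv − u),
    v ≥ 30 mV ⇒ v ← c, u ← u + d,

integrated at dt = 0.1 ms, with synapses delivering Dirac-delta current
pulses after per-synapse conduction delays Δᵢⱼ ∈ [0, 50] ms.  The
**full** architecture is AN → CN(chopper, primary-like, onset) → IC →
A1 → Belt; the **reduced** control skips the subcortical stages
(AN → A1 → Belt).  The cortical projections learn by the mixed STDP
rule on arrival-time differences s = tᵢ − (tⱼ + Δᵢⱼ):

    LTP:  w ← w + (w_max − w)·α_p e^(−s/τ_p)      (s > 0)
    LTD:  w ← max(0, w + w_max·α_d e^(s/τ_d))     (s < 0)

with τ_p = 15 ms, τ_d = 25 ms, α_p = 0.005, α_d = −0.015 (full) /
−0.033 (reduced), w_max = 60 nA, nearest-neighbour pairing and a
first-spike-only burst rule.  Depression dominates for uncorrelated
activity (|α_d|τ_d > α_p τ_p), so only synapses that reliably predict
their target's firing survive — the mechanism by which a repeating
spatio-temporal pattern is picked out of statistically identical noise.

The **PI** of a cell is the mean of the ten largest elements of its
exemplar-averaged ±50 ms co-firing matrix, normalised by the layer's
mean firing statistic and maximised over stimulus classes; values near
1 are chance, large values indicate participation in reproducible
firing patterns.  The **MI protocol** trains one small MLP (20 tanh
hidden units) per sampled reference cell on 201-element temporal
feature vectors (row + column sums of the windowed co-firing matrix) or
a single MLP on 201 cells' firing rates, majority-votes the ensemble on
held-out presentations, and converts the resulting 2×2 confusion table
into bits (ceiling H(S) = 1 bit for two balanced classes, plug-in bias
#bins/(2N ln 2) reported alongside).

Real speech and a cochlear model are out of scope; the synthetic module
generates auditory-nerve-like rasters with class-specific volley
patterns, a smooth one-dimensional speaker manifold, and controllable
temporal/spatial jitter, deletions and background firing.  See
`docs/methods.md` for the full account.

## Worked example

A miniature full-vs-reduced comparison (200 cells per layer, two
synthetic word classes, ten training passes):

```python
from polyphone import run_comparison_study

stats = run_comparison_study(seed=2)
for key in ("pi_an_full", "pi_ic_full",
            "mi_full_untrained_temporal", "mi_full_trained_temporal",
            "mi_full_trained_rate", "mi_reduced_trained_temporal"):
    print(f"{key:32s} {stats[key]:.3f}")
```

which prints (seed 2, about 90 s):

```
pi_an_full                       26.844
pi_ic_full                       66.930
mi_full_untrained_temporal       0.311
mi_full_trained_temporal         0.633
mi_full_trained_rate             0.311
mi_reduced_trained_temporal      0.049
```

Reading: the inferior-colliculus stage fires far more reproducibly than
the jittered auditory-nerve input (PI 67 vs 27) — the subcortical chain
denoises — and the trained full model's cortex carries an order of
magnitude more stimulus information than the reduced model that
receives raw nerve input (0.63 vs 0.05 bits of a 1-bit ceiling), with
the temporal read-out ahead of the rate read-out.  Estimates from 32
held-out presentations are coarse and seed-dependent; conclusions rest
on medians over many seeds (see the acceptance suite).

The same pipeline is scriptable from the shell:

```bash
polyphone synth --n-fibres 200 --n-speakers 4 --seed 1 --out scratch/an
polyphone train --preset full --size-factor 0.2 --seed 1 \
    --raster scratch/an --out scratch/response
polyphone pi   --raster scratch/response --layer IC --layer-size 200 \
    --seed 1 --out scratch/pi_ic.csv
polyphone info --raster scratch/response --layer A1 --layer-size 200 \
    --mode temporal --seed 1 --out scratch/mi_a1.csv
```

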