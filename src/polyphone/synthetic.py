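"""Synthetic auditory-nerve-like spike rasters.

The real front end of the modelled pathway is a cochlear periphery
driving ~1000 auditory-nerve (AN) fibres.  For desk-scale work this
module replaces it with a generative surrogate that keeps the
statistical structure the learning mechanisms rely on:

* each stimulus class is a repeating spatio-temporal spike pattern over
  a subset of fibres ("the word");
* different speakers are smooth deformations of the class pattern,
  obtained by densely sampling a 1-D latent pronunciation factor between
  per-class anchor templates (the continuous-transformation constraint:
  nearest neighbours of an exemplar are same-class exemplars);
* fibre noise is modelled as Gaussian temporal jitter of pattern spikes,
  spatial ("volley") jitter relocating a spike to a neighbouring fibre,
  random deletion of pattern spikes, and additive background Poisson
  firing.

Presentations are followed by a silent tail (the 100 ms inter-word
silence) so that delayed activity can play out before the next onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import Presentation, SpikeRaster

AN_LAYER = "AN"


@dataclass
class PatternTemplate:
    """A class-specific repeating spatio-temporal pattern.

    ``anchor_times`` holds one row of canonical spike times per anchor
    pronunciation; a speaker with latent position ``lam`` in [0, 1]
    interpolates linearly between the anchors, which makes the exemplar
    manifold one-dimensional and smooth.
    """

    stimulus_class: int
    neurons: np.ndarray  # participating fibre per pattern spike
    anchor_times: np.ndarray  # (n_anchors, n_pattern_spikes) ms
    duration_ms: float

    def __post_init__(self) -> None:
        self.neurons = np.asarray(self.neurons, dtype=int)
        self.anchor_times = np.atleast_2d(np.asarray(self.anchor_times, float))
        if self.neurons.size == 0:
            raise ValueError("pattern must involve at least one fibre")
        if self.anchor_times.shape[1] != self.neurons.size:
            raise ValueError("anchor_times and neurons disagree in size")
        if (self.anchor_times < 0).any() or (self.anchor_times > self.duration_ms).any():
            raise ValueError("canonical times outside [0, duration]")

    def times_for(self, lam: float) -> np.ndarray:
        """Spike times for latent pronunciation position ``lam`` in [0, 1]."""
        n_anchors = self.anchor_times.shape[0]
        if n_anchors == 1:
            return self.anchor_times[0].copy()
        x = np.clip(lam, 0.0, 1.0) * (n_anchors - 1)
        lo = min(int(np.floor(x)), n_anchors - 2)
        frac = x - lo
        return (1 - frac) * self.anchor_times[lo] + frac * self.anchor_times[lo + 1]


@dataclass
class NoiseModel:
    """Degrees of freedom of the AN-surrogate noise.

    background_rate_hz : additive Poisson firing per fibre during the
        stimulus portion of a presentation (the robustness regime of the
        pattern-from-noise mechanism extends to ~10 Hz).
    temporal_jitter_ms : s.d. of Gaussian jitter on pattern spike times,
        truncated at +/- 3 s.d.
    spatial_jitter_fibres : a pattern spike may relocate to a uniformly
        chosen fibre within this many neighbours (volley principle).
    deletion_prob : probability that a pattern spike is dropped.
    """

    background_rate_hz: float = 5.0
    temporal_jitter_ms: float = 1.0
    spatial_jitter_fibres: int = 0
    deletion_prob: float = 0.0

    def __post_init__(self) -> None:
        if min(self.background_rate_hz, self.temporal_jitter_ms) < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.spatial_jitter_fibres < 0:
            raise ValueError("noise parameters must be non-negative")
        if not (0.0 <= self.deletion_prob <= 1.0):
            raise ValueError("deletion_prob must lie in [0, 1]")


def random_templates(
    n_classes: int,
    n_fibres: int,
    n_pattern_spikes: int,
    duration_ms: float,
    variation_ms: float,
    n_anchors: int = 2,
    seed: int | np.random.Generator = 0,
) -> list[PatternTemplate]:
    """Draw disjoint random class templates with smooth anchor variation.

    Every class receives the same number of pattern spikes so that the
    expected per-presentation spike count is equal across classes (the
    functional analogue of loudness normalisation).
    """
    rng = np.random.default_rng(seed)
    if n_classes * n_pattern_spikes > n_fibres:
        raise ValueError("not enough fibres for disjoint class patterns")
    fibre_pool = rng.permutation(n_fibres)
    templates = []
    for c in range(n_classes):
        neurons = np.sort(
            fibre_pool[c * n_pattern_spikes : (c + 1) * n_pattern_spikes]
        )
        base = rng.uniform(0.0, duration_ms, size=n_pattern_spikes)
        anchors = [base]
        for _ in range(n_anchors - 1):
            drift = rng.uniform(-variation_ms, variation_ms, size=n_pattern_spikes)
            anchors.append(np.clip(anchors[-1] + drift, 0.0, duration_ms))
        templates.append(
            PatternTemplate(
                stimulus_class=c,
                neurons=neurons,
                anchor_times=np.vstack(anchors),
                duration_ms=duration_ms,
            )
        )
    return templates


def vowel_templates(
    n_classes: int,
    n_fibres: int,
    duration_ms: float = 200.0,
    band_width: int = 10,
    base_period_ms: float = 10.0,
    period_spread: float = 0.2,
    spikes_per_volley: int = 3,
    seed: int | np.random.Generator = 0,
) -> list[PatternTemplate]:
    """Voiced-sound-like class templates: periodic volleys in a moving band.

    Emulates the gross structure of auditory-nerve responses to voiced
    speech: at every cycle of the fundamental period, a contiguous band
    of ``band_width`` fibres (the "formant" region, whose centre follows
    a smooth trajectory across the tonotopic axis) fires a
    near-synchronous volley of ``spikes_per_volley`` spikes per fibre at
    1 ms spacing (driven fibres sustain ~200 Hz and phase-lock to the
    cycle onset).

    Class identity is carried by the *phase* of the band trajectory (the
    order in which tonotopic regions activate), while the fundamental
    period is a speaker property: the anchor pronunciations of every
    class lie at ``base_period_ms * (1 -/+ period_spread)`` and the
    latent interpolation sweeps the period smoothly, time-warping the
    same trajectory.  Because all classes share the trajectory shape and
    amplitude, time-averaged per-fibre rates are similar across classes
    and class identity lives mainly in the spatio-temporal structure.
    """
    rng = np.random.default_rng(seed)
    templates = []
    T = float(base_period_ms)
    phase0 = rng.uniform(0, 2 * np.pi)
    amp = rng.uniform(0.2, 0.3) * n_fibres
    centre0 = 0.5 * n_fibres
    n_volleys = int(np.floor(duration_ms / (T * (1 + period_spread))))
    if n_volleys < 1:
        raise ValueError("duration too short for one volley")
    ks = np.arange(n_volleys)
    offsets = np.arange(band_width) - band_width // 2
    burst = np.tile(np.arange(spikes_per_volley), band_width)
    for c in range(n_classes):
        phase = phase0 + 2 * np.pi * c / n_classes
        # band centre as a function of normalised volley index: speakers
        # with longer periods traverse the same trajectory more slowly
        centres = centre0 + amp * np.sin(2 * np.pi * ks / n_volleys + phase)
        neurons = np.clip(
            (centres[:, None] + offsets[None, :]).astype(int), 0, n_fibres - 1
        ).ravel()
        neurons = np.repeat(neurons, spikes_per_volley)
        anchors = []
        for a_period in (T * (1 - period_spread), T * (1 + period_spread)):
            times = np.repeat(ks * a_period, band_width * spikes_per_volley)
            times = times + np.tile(burst, n_volleys)
            anchors.append(np.clip(times, 0.0, duration_ms))
        templates.append(
            PatternTemplate(
                stimulus_class=c,
                neurons=neurons,
                anchor_times=np.vstack(anchors),
                duration_ms=duration_ms,
            )
        )
    return templates


def _render_presentation(
    template: PatternTemplate,
    lam: float,
    noise: NoiseModel,
    n_fibres: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One noisy exemplar: (neurons, times) during the stimulus portion."""
    times = template.times_for(lam)
    neurons = template.neurons.copy()
    if noise.deletion_prob > 0:
        keep = rng.random(times.size) >= noise.deletion_prob
        times, neurons = times[keep], neurons[keep]
    if noise.temporal_jitter_ms > 0 and times.size:
        sd = noise.temporal_jitter_ms
        jit = np.clip(rng.normal(0.0, sd, size=times.size), -3 * sd, 3 * sd)
        times = np.clip(times + jit, 0.0, template.duration_ms)
    if noise.spatial_jitter_fibres > 0 and neurons.size:
        shift = rng.integers(
            -noise.spatial_jitter_fibres,
            noise.spatial_jitter_fibres + 1,
            size=neurons.size,
        )
        neurons = np.clip(neurons + shift, 0, n_fibres - 1)
    if noise.background_rate_hz > 0:
        mean = noise.background_rate_hz * template.duration_ms / 1000.0 * n_fibres
        n_bg = rng.poisson(mean)
        bg_neurons = rng.integers(0, n_fibres, size=n_bg)
        bg_times = rng.uniform(0.0, template.duration_ms, size=n_bg)
        neurons = np.concatenate([neurons, bg_neurons])
        times = np.concatenate([times, bg_times])
    order = np.argsort(times, kind="stable")
    return neurons[order], times[order]


def generate_dataset(
    templates: list[PatternTemplate],
    noise: NoiseModel,
    n_speakers: int,
    n_repetitions: int,
    n_fibres: int,
    silence_ms: float = 100.0,
    seed: int | np.random.Generator = 0,
) -> SpikeRaster:
    """Interleaved presentation schedule of noisy class exemplars.

    Speakers are latent positions spread evenly over [0, 1] (dense
    sampling of the pronunciation manifold); every repetition re-draws
    the jitter, deletions and background, emulating trial-to-trial AN
    stochasticity.  Presentation duration = pattern duration + silence.
    """
    rng = np.random.default_rng(seed)
    for t in templates:
        if t.neurons.max() >= n_fibres:
            raise ValueError("template fibre index exceeds n_fibres")
    lams = (
        np.linspace(0.0, 1.0, n_speakers) if n_speakers > 1 else np.array([0.5])
    )
    events: list[tuple[int, str, int, float]] = []
    presentations: list[Presentation] = []
    pid = 0
    for rep in range(n_repetitions):
        for sp in range(n_speakers):
            for template in templates:
                neurons, times = _render_presentation(
                    template, lams[sp], noise, n_fibres, rng
                )
                duration = template.duration_ms + silence_ms
                events.extend(
                    (pid, AN_LAYER, int(n), float(t))
                    for n, t in zip(neurons, times)
                )
                presentations.append(
                    Presentation(
                        presentation_id=pid,
                        stimulus_class=template.stimulus_class,
                        exemplar=sp,
                        repetition=rep,
                        duration_ms=duration,
                    )
                )
                pid += 1
    return SpikeRaster.from_events(events, presentations)


@dataclass
class MasquelierStream:
    """A continuous spike stream with a recurring embedded pattern."""

    raster: SpikeRaster
    pattern_mask: np.ndarray  # per event row: True if a pattern spike
    window_starts_ms: np.ndarray  # onsets of pattern occurrences
    pattern_ms: float
    pattern_fibres: np.ndarray


def masquelier_benchmark(
    n_input: int,
    pattern_fraction: float,
    noise: NoiseModel,
    seed: int | np.random.Generator = 0,
    duration_s: float = 20.0,
    pattern_ms: float = 40.0,
    occurrence_prob: float = 0.25,
) -> MasquelierStream:
    """Single-neuron pattern-from-noise benchmark stream.

    Time is tiled into consecutive segments of ``pattern_ms``; each
    segment independently hosts the pattern with ``occurrence_prob``.
    Inside a pattern segment the pattern fibres replay a fixed template
    (drawn once from the same Poisson statistics as the background, so
    first-order rates match) with fresh temporal jitter; all other
    fibres, and all fibres outside pattern segments, fire homogeneous
    Poisson at ``noise.background_rate_hz``.
    """
    if not (0.0 < pattern_fraction <= 1.0):
        raise ValueError("pattern_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    rate = noise.background_rate_hz
    total_ms = duration_s * 1000.0
    n_segments = int(np.floor(total_ms / pattern_ms))
    n_pat_fibres = max(1, int(round(pattern_fraction * n_input)))
    pattern_fibres = np.arange(n_pat_fibres)

    # Fixed pattern template: one Poisson draw at the background rate, so
    # pattern segments are rate-matched to the background to first order
    # (fibres that happen to draw zero spikes sit the pattern out).
    counts = rng.poisson(rate * pattern_ms / 1000.0, size=n_pat_fibres)
    tmpl_neurons = np.repeat(pattern_fibres, counts)
    tmpl_times = rng.uniform(0.0, pattern_ms, size=tmpl_neurons.size)

    is_pattern_segment = rng.random(n_segments) < occurrence_prob

    neurons_all: list[np.ndarray] = []
    times_all: list[np.ndarray] = []
    mask_all: list[np.ndarray] = []
    for seg in range(n_segments):
        t0 = seg * pattern_ms
        if is_pattern_segment[seg]:
            sd = noise.temporal_jitter_ms
            times = tmpl_times.copy()
            if sd > 0:
                jit = np.clip(rng.normal(0, sd, size=times.size), -3 * sd, 3 * sd)
                times = np.clip(times + jit, 0.0, pattern_ms - 1e-9)
            neurons_all.append(tmpl_neurons)
            times_all.append(t0 + times)
            mask_all.append(np.ones(tmpl_neurons.size, dtype=bool))
            free_fibres = np.arange(n_pat_fibres, n_input)
        else:
            free_fibres = np.arange(n_input)
        if free_fibres.size and rate > 0:
            mean = rate * pattern_ms / 1000.0 * free_fibres.size
            n_bg = rng.poisson(mean)
            neurons_all.append(rng.choice(free_fibres, size=n_bg))
            times_all.append(t0 + rng.uniform(0.0, pattern_ms, size=n_bg))
            mask_all.append(np.zeros(n_bg, dtype=bool))

    neurons = np.concatenate(neurons_all) if neurons_all else np.empty(0, int)
    times = np.concatenate(times_all) if times_all else np.empty(0)
    mask = np.concatenate(mask_all) if mask_all else np.empty(0, bool)
    order = np.argsort(times, kind="stable")
    neurons, times, mask = neurons[order], times[order], mask[order]

    events = [(0, AN_LAYER, int(n), float(t)) for n, t in zip(neurons, times)]
    raster = SpikeRaster.from_events(
        events,
        [
            Presentation(
                presentation_id=0,
                stimulus_class=0,
                exemplar=0,
                repetition=0,
                duration_ms=n_segments * pattern_ms,
            )
        ],
    )
    return MasquelierStream(
        raster=raster,
        pattern_mask=mask,
        window_starts_ms=np.arange(n_segments)[is_pattern_segment] * pattern_ms,
        pattern_ms=pattern_ms,
        pattern_fibres=pattern_fibres,
    )
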