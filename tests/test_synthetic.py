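"""Synthetic AN-surrogate generator: templates, noise model, benchmark."""

import numpy as np
import pytest

from polyphone.synthetic import (
    NoiseModel,
    PatternTemplate,
    generate_dataset,
    masquelier_benchmark,
    random_templates,
    vowel_templates,
)

ZERO_NOISE = NoiseModel(0.0, 0.0, 0, 0.0)


class TestTemplates:
    def test_template_validation(self):
        with pytest.raises(ValueError):
            PatternTemplate(0, np.array([], int), np.empty((1, 0)), 100.0)
        with pytest.raises(ValueError):
            PatternTemplate(0, np.array([1]), np.array([[150.0]]), 100.0)

    def test_latent_interpolation_is_linear(self):
        t = PatternTemplate(
            0, np.array([3, 7]), np.array([[10.0, 20.0], [30.0, 40.0]]), 100.0
        )
        np.testing.assert_allclose(t.times_for(0.0), [10.0, 20.0])
        np.testing.assert_allclose(t.times_for(1.0), [30.0, 40.0])
        np.testing.assert_allclose(t.times_for(0.25), [15.0, 25.0])

    def test_random_templates_disjoint_and_matched(self):
        tms = random_templates(3, 300, 40, 200.0, 10.0, seed=0)
        sets = [set(t.neurons.tolist()) for t in tms]
        assert sets[0].isdisjoint(sets[1]) and sets[1].isdisjoint(sets[2])
        # equal spike budget per class (loudness-normalisation analogue)
        assert len({t.neurons.size for t in tms}) == 1

    def test_vowel_templates_share_rate_statistics(self):
        """Classes differ in trajectory phase, not in overall occupancy."""
        tms = vowel_templates(2, 200, duration_ms=120.0, band_width=20, seed=0)
        assert tms[0].neurons.size == tms[1].neurons.size
        # per-class fibre-occupancy histograms heavily overlap
        h0 = np.bincount(tms[0].neurons, minlength=200)
        h1 = np.bincount(tms[1].neurons, minlength=200)
        overlap = np.minimum(h0, h1).sum() / h0.sum()
        assert overlap > 0.5
        # within a class, anchors differ only in timing
        assert tms[0].anchor_times.shape[0] == 2
        assert not np.allclose(tms[0].anchor_times[0], tms[0].anchor_times[1])


class TestGenerateDataset:
    def test_zero_noise_single_speaker_reproducible(self):
        tms = random_templates(2, 100, 20, 200.0, 0.0, seed=1)
        r = generate_dataset(tms, ZERO_NOISE, 1, 3, 100, seed=2)
        pres = r.presentations
        assert len(pres) == 6  # 2 classes x 1 speaker x 3 repetitions
        # all repetitions of a class are identical rasters
        for cls in (0, 1):
            pids = pres[pres["stimulus_class"] == cls]["presentation_id"]
            frames = [
                r.presentation_events(p, "AN")[["neuron", "time_ms"]]
                .reset_index(drop=True)
                for p in pids
            ]
            for f in frames[1:]:
                assert f.equals(frames[0])

    def test_interleaved_schedule_and_silence(self):
        tms = random_templates(2, 100, 10, 200.0, 5.0, seed=1)
        r = generate_dataset(tms, ZERO_NOISE, 2, 1, 100, silence_ms=100.0, seed=2)
        assert list(r.presentations["stimulus_class"]) == [0, 1, 0, 1]
        assert (r.presentations["duration_ms"] == 300.0).all()
        # the silent tail carries no events
        assert (r.events["time_ms"] <= 200.0).all()

    def test_background_poisson_count(self):
        """10 Hz x 0.5 s x 1000 fibres -> ~5000 background spikes."""
        tms = random_templates(1, 1000, 1, 500.0, 0.0, seed=1)
        noise = NoiseModel(background_rate_hz=10.0)
        r = generate_dataset(tms, noise, 1, 4, 1000, silence_ms=0.0, seed=3)
        per_pres = r.events.groupby("presentation_id").size() - 1  # pattern spike
        mean = per_pres.mean()
        assert mean == pytest.approx(5000, abs=4 * np.sqrt(5000))

    def test_deletion_probability(self):
        """Deletion 0.5 keeps about half of the pattern spikes."""
        tms = random_templates(1, 400, 200, 300.0, 0.0, seed=1)
        noise = NoiseModel(0.0, 0.0, 0, 0.5)
        r = generate_dataset(tms, noise, 1, 30, 400, seed=4)
        counts = r.events.groupby("presentation_id").size()
        assert counts.mean() == pytest.approx(100, abs=10)

    def test_spatial_jitter_moves_within_range(self):
        tms = random_templates(1, 100, 50, 200.0, 0.0, seed=1)
        noise = NoiseModel(0.0, 0.0, 2, 0.0)
        r = generate_dataset(tms, noise, 1, 10, 100, seed=5)
        base = np.sort(tms[0].neurons)
        for pid in r.presentation_ids:
            moved = np.sort(r.presentation_events(pid, "AN")["neuron"].to_numpy())
            assert np.abs(moved - base).max() <= 2

    def test_determinism_and_out_of_range_errors(self):
        tms = random_templates(2, 100, 10, 200.0, 5.0, seed=1)
        noise = NoiseModel(5.0, 1.0, 1, 0.1)
        a = generate_dataset(tms, noise, 2, 2, 100, seed=9)
        b = generate_dataset(tms, noise, 2, 2, 100, seed=9)
        assert a.events.equals(b.events)
        with pytest.raises(ValueError, match="exceeds"):
            generate_dataset(tms, noise, 1, 1, 50, seed=9)


class TestMasquelierBenchmark:
    def test_pure_pattern_stream(self):
        s = masquelier_benchmark(
            50, 1.0, NoiseModel(20.0, 0.0, 0, 0.0), seed=0,
            duration_s=2.0, occurrence_prob=1.0,
        )
        assert s.pattern_mask.all()
        assert s.window_starts_ms.size == int(2000 / s.pattern_ms)

    def test_mask_marks_exactly_the_pattern_events(self):
        s = masquelier_benchmark(100, 0.5, NoiseModel(30.0, 0.0, 0, 0.0),
                                 seed=1, duration_s=10.0)
        ev = s.raster.events
        t = ev["time_ms"].to_numpy()
        seg = (t // s.pattern_ms) * s.pattern_ms
        in_window = np.isin(seg, s.window_starts_ms)
        on_fibre = ev["neuron"].to_numpy() < s.pattern_fibres.size
        np.testing.assert_array_equal(s.pattern_mask, in_window & on_fibre)

    def test_rate_matched_first_order_statistics(self):
        """Pattern and noise segments have matching mean rates."""
        s = masquelier_benchmark(200, 0.5, NoiseModel(40.0, 1.0, 0, 0.0),
                                 seed=2, duration_s=60.0)
        t = s.raster.events["time_ms"].to_numpy()
        seg = (t // s.pattern_ms) * s.pattern_ms
        n_pat_seg = s.window_starts_ms.size
        n_seg = int(s.raster.presentations["duration_ms"].iloc[0] / s.pattern_ms)
        in_pat = np.isin(seg, s.window_starts_ms)
        rate_pat = in_pat.sum() / n_pat_seg
        rate_noise = (~in_pat).sum() / (n_seg - n_pat_seg)
        # the template is a single frozen Poisson draw, so pattern segments
        # deviate from the noise rate by that one draw's sampling error
        # (sigma = sqrt(expected template count))
        sigma = np.sqrt(rate_noise)
        assert rate_pat == pytest.approx(rate_noise, abs=4 * sigma)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            masquelier_benchmark(10, 0.0, ZERO_NOISE, seed=0)


def test_class_separability_controllable():
    """Zero noise: distinct class rasters; heavy noise: spike-count
    vectors become statistically indistinguishable between classes."""
    tms = vowel_templates(2, 100, duration_ms=100.0, band_width=10, seed=6)
    clean = generate_dataset(tms, ZERO_NOISE, 1, 1, 100, seed=7)
    e0 = clean.presentation_events(0, "AN")
    e1 = clean.presentation_events(1, "AN")
    assert not e0[["neuron", "time_ms"]].reset_index(drop=True).equals(
        e1[["neuron", "time_ms"]].reset_index(drop=True)
    )
    noisy = generate_dataset(
        tms, NoiseModel(200.0, 5.0, 30, 1.0), 1, 20, 100, seed=8
    )
    counts = []
    for pid in noisy.presentation_ids:
        v = np.bincount(
            noisy.presentation_events(pid, "AN")["neuron"], minlength=100
        )
        counts.append((noisy.class_of(pid), v))
    c0 = np.stack([v for c, v in counts if c == 0])
    c1 = np.stack([v for c, v in counts if c == 1])
    # class-mean spike-count profiles differ by less than the within-class
    # sampling noise (deletion 1.0 removed every pattern spike)
    diff = np.abs(c0.mean(0) - c1.mean(0)).mean()
    spread = c0.std(0).mean()
    assert diff < spread


def test_smooth_variation_nearest_neighbour_property():
    """Adjacent-speaker exemplars of a class are closer than exemplars of
    the other class (continuous-transformation data constraint)."""
    tms = vowel_templates(2, 200, duration_ms=120.0, band_width=20, seed=10)
    r = generate_dataset(tms, NoiseModel(2.0, 0.5, 1, 0.05), 8, 1, 200, seed=11)
    # time-binned population vectors as a crude spike-train distance
    feats, labels = [], []
    for pid in r.presentation_ids:
        ev = r.presentation_events(pid, "AN")
        m = np.zeros((200, 12))
        bins = np.minimum((ev["time_ms"] // 10).astype(int), 11)
        np.add.at(m, (ev["neuron"], bins), 1.0)
        feats.append(m.ravel())
        labels.append(r.class_of(pid))
    feats = np.stack(feats)
    labels = np.array(labels)
    same, hits = 0, 0
    for i in range(len(feats)):
        d = np.linalg.norm(feats - feats[i], axis=1)
        d[i] = np.inf
        j = int(np.argmin(d))
        same += 1
        hits += labels[j] == labels[i]
    assert hits / same >= 0.8
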