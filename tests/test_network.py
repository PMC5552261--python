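"""Architecture construction and the discrete-time simulation loop."""

import numpy as np
import pytest

from polyphone.network import (
    build_network,
    connect_gaussian,
    preset_config,
    run_simulation,
    weight_histogram,
)
from polyphone.neuron import DT_MS, preset, step_neuron
from polyphone.raster import Presentation, SpikeRaster

from conftest import make_raster


class TestPresets:
    def test_full_architecture(self):
        net = build_network("full", seed=0)
        assert net.order == ["AN", "CH", "PL", "ON", "IC", "A1", "Belt"]
        sizes = net.layer_sizes
        assert sizes["AN"] == 1000 and sizes["ON"] == 100
        plastic = {f"{p.source}->{p.target}" for p in net.plastic_projections()}
        assert plastic == {"IC->A1", "A1->Belt"}
        for p in net.plastic_projections():
            assert p.stdp.alpha_d == -0.015
            assert p.stdp.w_max == 60.0
            live = p.W[p.mask]
            assert live.min() >= 30.0 and live.max() <= 35.0

    def test_reduced_architecture(self):
        net = build_network("reduced", seed=0)
        assert net.order == ["AN", "A1", "Belt"]
        for p in net.plastic_projections():
            assert p.stdp.alpha_d == -0.033

    def test_inhibitory_wiring_parameters(self):
        cfg = preset_config("full")
        by_name = {l["name"]: l for l in cfg["layers"]}
        assert by_name["CH"]["w_EI"] == 0.0 and by_name["CH"]["w_IE"] == 0.0
        assert by_name["ON"]["w_IE"] == -75.0
        assert by_name["A1"]["w_EI"] == 1000.0 and by_name["A1"]["w_IE"] == -6.0
        assert by_name["AN"]["n_inhibitory"] == 0

    def test_size_factor_reproduces_reference_at_one(self):
        cfg = preset_config("full", size_factor=1.0)
        an_ch = next(p for p in cfg["projections"] if p["target"] == "CH")
        assert an_ch["sigma"] == 26.0 and an_ch["weight"] == [25.0, 30.0]
        an_on = next(p for p in cfg["projections"] if p["target"] == "ON")
        assert an_on["weight"] == pytest.approx(26.0)
        assert an_on["p_dead"] == 0.46

    def test_unknown_preset_and_bad_params(self):
        with pytest.raises(ValueError):
            preset_config("tiny")
        with pytest.raises(ValueError):
            connect_gaussian(10, 10, sigma=0.0, seed=0)

    def test_degenerate_custom_network(self):
        cfg = {
            "name": "one",
            "input_layer": "IN",
            "layers": [{"name": "IN", "n_excitatory": 5, "n_inhibitory": 0}],
            "projections": [],
        }
        net = build_network(cfg, seed=0)
        assert net.layer_sizes == {"IN": 5}


class TestGaussianConnectivity:
    def test_modal_afferent_is_aligned(self):
        """Census over seeds: target i connects most often to source i."""
        acc = np.zeros((21, 21))
        for seed in range(200):
            acc += connect_gaussian(21, 21, sigma=3.0, seed=seed)
        assert (np.argmax(acc, axis=1) == np.arange(21)).mean() > 0.9

    def test_small_sigma_approaches_one_to_one(self):
        mask = connect_gaussian(50, 50, sigma=1e-3, seed=1)
        np.testing.assert_array_equal(mask, np.eye(50, dtype=bool))

    def test_edges_truncate_without_wraparound(self):
        acc = np.zeros((30, 30))
        for seed in range(100):
            acc += connect_gaussian(30, 30, sigma=2.0, seed=seed)
        assert acc[0, -1] == 0 and acc[-1, 0] == 0

    def test_unequal_sizes_align_linearly(self):
        acc = np.zeros((10, 100))
        for seed in range(100):
            acc += connect_gaussian(100, 10, sigma=2.0, seed=seed)
        modal = np.argmax(acc, axis=1)
        np.testing.assert_allclose(modal, np.arange(10) * 11, atol=3)

    def test_one_to_one_size_mismatch_is_error(self, micro_config):
        cfg = micro_config()
        cfg["layers"][0]["n_excitatory"] = 3
        with pytest.raises(ValueError, match="one-to-one"):
            build_network(cfg, seed=0)


def _one_spike_raster(t=5.0, duration=40.0, layer="IN"):
    return make_raster([(0, layer, 0, t)], [(0, 0, duration)])


class TestSimulation:
    def test_empty_input_means_total_silence(self, micro_config):
        net = build_network(micro_config(), seed=0)
        out = run_simulation(net, make_raster([], [(0, 0, 50.0)]))
        assert len(out["rasters"].layer_events("OUT")) == 0

    def test_strong_one_to_one_relays_single_spike(self, micro_config):
        """A 1000 nA one-to-one synapse converts one input spike into
        exactly one output spike, at the time the single-neuron oracle
        (step_neuron driven by a one-step 1000 nA pulse) predicts."""
        net = build_network(micro_config(weight=1000.0), seed=0)
        out = run_simulation(net, _one_spike_raster(t=5.0))
        ev = out["rasters"].layer_events("OUT")
        assert len(ev) == 1
        # oracle: the pulse is integrated one step after the input event
        p = preset("excitatory_subcortical")
        state = p.rest_state()
        spike_step = None
        for step in range(400):
            current = 1000.0 if step == 51 else 0.0
            state, spiked = step_neuron(state, p, current)
            if spiked:
                spike_step = step
                break
        assert ev["time_ms"].iloc[0] == pytest.approx(spike_step * DT_MS)

    @pytest.mark.parametrize("delay", [1.0, 7.3, 25.0])
    def test_delay_contract(self, micro_config, delay):
        """Earliest response follows the pre spike by at least the delay,
        and shifting the delay shifts the response by exactly as much."""
        cfg0 = micro_config(weight=1000.0)
        t0 = run_simulation(
            build_network(cfg0, seed=0), _one_spike_raster()
        )["rasters"].layer_events("OUT")["time_ms"].iloc[0]
        cfg = micro_config(weight=1000.0, delay=[delay, delay])
        td = run_simulation(
            build_network(cfg, seed=0), _one_spike_raster()
        )["rasters"].layer_events("OUT")["time_ms"].iloc[0]
        assert td - t0 == pytest.approx(np.ceil(delay / DT_MS - 1e-9) * DT_MS - DT_MS)
        assert td >= 5.0 + delay

    def test_input_index_out_of_bounds(self, micro_config):
        net = build_network(micro_config(), seed=0)
        bad = make_raster([(0, "IN", 7, 1.0)], [(0, 0, 10.0)])
        with pytest.raises(ValueError, match="exceeds"):
            run_simulation(net, bad)

    def test_learning_off_freezes_weights(self, micro_config):
        cfg = micro_config(weight=[30.0, 35.0], delay=[0.0, 20.0],
                           plastic=True, n_in=20, n_out=5)
        net = build_network(cfg, seed=1)
        events = [(0, "IN", int(i % 20), float(1 + i)) for i in range(30)]
        raster = make_raster(events, [(0, 0, 60.0)])
        out = run_simulation(net, raster, learning=False)
        for key in out["weights_before"]:
            np.testing.assert_array_equal(
                out["weights_before"][key], out["weights_after"][key]
            )

    def test_learning_on_changes_weights(self, micro_config):
        cfg = micro_config(weight=[45.0, 50.0], delay=[0.0, 10.0],
                           plastic=True, n_in=40, n_out=4)
        net = build_network(cfg, seed=1)
        rng = np.random.default_rng(0)
        events = [
            (0, "IN", int(rng.integers(0, 40)), float(t))
            for t in np.sort(rng.uniform(0, 150, 1500))
        ]
        raster = make_raster(events, [(0, 0, 200.0)])
        out = run_simulation(net, raster, learning=True)
        assert len(out["rasters"].layer_events("OUT")) > 0
        (key,) = out["weights_before"].keys()
        assert not np.array_equal(out["weights_before"][key],
                                  out["weights_after"][key])
        assert out["weights_after"][key].min() >= 0.0
        assert out["weights_after"][key].max() <= 60.0

    def test_bit_reproducibility(self):
        net_a = build_network("full", seed=7, size_factor=0.05)
        net_b = build_network("full", seed=7, size_factor=0.05)
        rng = np.random.default_rng(3)
        events = [
            (0, "AN", int(rng.integers(0, 50)), float(t))
            for t in np.sort(rng.uniform(0, 100, 300))
        ]
        raster = make_raster(events, [(0, 0, 150.0)])
        out_a = run_simulation(net_a, raster, learning=True)
        out_b = run_simulation(net_b, raster, learning=True)
        assert out_a["rasters"].events.equals(out_b["rasters"].events)
        for key in out_a["weights_after"]:
            np.testing.assert_array_equal(
                out_a["weights_after"][key], out_b["weights_after"][key]
            )

    def test_inhibition_monotonically_suppresses(self, micro_config):
        """Raising |w_IE| never increases the excitatory spike count."""
        rng = np.random.default_rng(5)
        events = [
            (0, "IN", int(rng.integers(0, 30)), float(t))
            for t in np.sort(rng.uniform(0, 100, 600))
        ]
        raster = make_raster(events, [(0, 0, 120.0)])
        counts = []
        for w_ie in (0.0, -10.0, -100.0, -1000.0):
            cfg = {
                "name": "inh",
                "input_layer": "IN",
                "layers": [
                    {"name": "IN", "n_excitatory": 30, "n_inhibitory": 0},
                    {
                        "name": "OUT",
                        "n_excitatory": 30,
                        "n_inhibitory": 30,
                        "excitatory_preset": "excitatory_subcortical",
                        "inhibitory_preset": "inhibitory",
                        "w_EI": 1000.0,
                        "w_IE": w_ie,
                    },
                ],
                "projections": [
                    {"source": "IN", "target": "OUT", "kind": "one_to_one",
                     "weight": 1000.0}
                ],
            }
            out = run_simulation(build_network(cfg, seed=2), raster)
            counts.append(len(out["rasters"].layer_events("OUT")))
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] < counts[0]

    def test_presentation_reset_makes_presentations_exchangeable(
        self, micro_config
    ):
        """The same input presented twice yields identical responses."""
        net = build_network(micro_config(weight=1000.0), seed=0)
        raster = make_raster(
            [(0, "IN", 0, 5.0), (1, "IN", 0, 5.0)],
            [(0, 0, 40.0), (1, 0, 40.0)],
        )
        out = run_simulation(net, raster)["rasters"]
        a = out.presentation_events(0, "OUT")["time_ms"].to_numpy()
        b = out.presentation_events(1, "OUT")["time_ms"].to_numpy()
        np.testing.assert_array_equal(a, b)


class TestWeightHistogram:
    def test_untrained_histograms_identical(self):
        net = build_network("reduced", seed=0, size_factor=0.05)
        snap = net.weight_snapshot()
        hists = weight_histogram(snap, snap, bins=30)
        for h in hists.values():
            np.testing.assert_array_equal(h["before"], h["after"])
            assert h["before"].sum() == h["after"].sum()

    def test_initial_mass_in_declared_band(self):
        net = build_network("reduced", seed=0, size_factor=0.05)
        snap = net.weight_snapshot()
        h = weight_histogram(snap, snap, bins=60, w_max=60.0)["AN->A1"]
        centres = 0.5 * (h["edges"][:-1] + h["edges"][1:])
        occupied = centres[h["before"] > 0]
        assert occupied.min() >= 30.0 - 1.0 and occupied.max() <= 35.0 + 1.0

    def test_total_count_conserved_and_missing_key_rejected(self):
        net = build_network("reduced", seed=0, size_factor=0.05)
        before = net.weight_snapshot()
        after = {k: np.clip(v * 0.5, 0, 60) for k, v in before.items()}
        hists = weight_histogram(before, after, bins=20, w_max=60.0)
        for k, h in hists.items():
            assert h["before"].sum() == h["after"].sum()
        with pytest.raises(KeyError):
            weight_histogram(before, {})
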