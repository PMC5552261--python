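"""Seeded experiment orchestration: data -> training -> PI/MI evaluation.

An :class:`ExperimentConfig` fully determines a run: the architecture
preset and scale, the synthetic-dataset parameters, the number of
training passes (ten by default, matching the training protocol of the
word-discrimination study design), and the evaluation settings.  Every
stochastic stage draws its own sub-seed from the master seed through a
label-based derivation, so adding a stage never perturbs the randomness
of earlier stages, and identical configs give byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .info import evaluate_model
from .network import Network, build_network, preset_config, run_simulation, weight_histogram
from .polychrony import layer_pi
from .raster import SpikeRaster
from .synthetic import NoiseModel, generate_dataset, random_templates, vowel_templates

log = logging.getLogger("polyphone")


def subseed(master: int, label: str) -> int:
    """Stable per-stage sub-seed derived from the master seed.

    Uses a label hash rather than a counter so that inserting a new
    stage leaves every existing stage's randomness untouched.
    """
    h = zlib.crc32(label.encode())
    ss = np.random.SeedSequence([int(master), h])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one training + evaluation run."""

    model: str = "full"  # 'full' or 'reduced'
    size_factor: float = 1.0
    seed: int = 0
    # synthetic dataset
    n_classes: int = 2
    template_kind: str = "vowel"  # 'vowel' (periodic volleys) or 'random'
    band_width_frac: float = 0.1  # volley band as a fraction of the axis
    spikes_per_volley: int = 3
    n_pattern_spikes: int = 40  # 'random' templates only
    pattern_duration_ms: float = 120.0
    variation_ms: float = 10.0  # 'random' templates: anchor drift
    silence_ms: float = 100.0
    # AN-surrogate noise: the stress regime the subcortical stages are
    # there to overcome (heavy jitter, volley-principle relocation, loss
    # of almost half the pattern spikes, additive background firing)
    background_rate_hz: float = 8.0
    temporal_jitter_ms: float = 2.5
    spatial_jitter_fibres: int = 4
    deletion_prob: float = 0.45
    n_speakers: int = 4
    n_test_repetitions: int = 4
    # training
    epochs: int = 10
    # evaluation
    eval_layers: list[str] | None = None
    eval_modes: tuple[str, ...] = ("temporal", "rate")
    n_subsamples: int = 20
    j_cells: int | None = None
    pi_cells: int | None = None  # None: every cell in the layer
    evaluate_untrained: bool = False
    shuffled_control: bool = False
    record_layers: list[str] | None = None
    network_overrides: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["eval_modes"] = list(self.eval_modes)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        if "eval_modes" in d:
            d["eval_modes"] = tuple(d["eval_modes"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def noise_model(self) -> NoiseModel:
        return NoiseModel(
            background_rate_hz=self.background_rate_hz,
            temporal_jitter_ms=self.temporal_jitter_ms,
            spatial_jitter_fibres=self.spatial_jitter_fibres,
            deletion_prob=self.deletion_prob,
        )


def shuffle_weights(
    network: Network,
    projections: list[str] | None = None,
    seed: int | np.random.Generator = 0,
) -> Network:
    """Permute plastic weights in place across each projection's synapses.

    The weight multiset of every named projection is preserved exactly;
    only the assignment of values to (realised) synapses changes.
    Returns the same network object for chaining.
    """
    rng = np.random.default_rng(seed)
    names = {f"{p.source}->{p.target}": p for p in network.plastic_projections()}
    targets = projections if projections is not None else sorted(names)
    for name in targets:
        if name not in names:
            raise KeyError(f"no plastic projection named {name}")
        proj = names[name]
        idx = np.nonzero(proj.mask)
        vals = proj.W[idx]
        proj.W[idx] = rng.permutation(vals)
    return network


def _evaluate(
    cfg: ExperimentConfig,
    network: Network,
    test_raster: SpikeRaster,
    stage: str,
) -> dict[str, Any]:
    """Simulate the held-out set and run the PI + MI measurements."""
    sim = run_simulation(
        network, test_raster, learning=False, record_layers=cfg.record_layers
    )
    rasters = sim["rasters"]
    sizes = network.layer_sizes
    layers = cfg.eval_layers if cfg.eval_layers is not None else list(sizes)
    pi_tables = {}
    for layer in layers:
        n = sizes[layer]
        cells = None
        if cfg.pi_cells is not None and cfg.pi_cells < n:
            pi_rng = np.random.default_rng(subseed(cfg.seed, f"pi-cells-{stage}-{layer}"))
            cells = pi_rng.choice(n, size=cfg.pi_cells, replace=False)
        pi_tables[layer] = layer_pi(
            rasters, layer, n, cells=cells,
            seed=subseed(cfg.seed, f"pi-{stage}-{layer}"),
        )
    mi_table = evaluate_model(
        rasters,
        sizes,
        modes=cfg.eval_modes,
        layers=layers,
        n_subsamples=cfg.n_subsamples,
        j_cells=cfg.j_cells,
        seed=subseed(cfg.seed, f"mi-{stage}"),
    )
    return {"rasters": rasters, "pi": pi_tables, "mi": mi_table}


def run_experiment(cfg: ExperimentConfig) -> dict[str, Any]:
    """Generate data, train the network, and measure PI and MI.

    Returns a bundle with the train/test rasters, before/after weight
    snapshots and histograms, PI tables and MI tables per evaluation
    stage ('trained' always; 'untrained' and 'shuffled' on request), and
    a manifest recording the config, its hash and all stage sub-seeds.
    """
    t0 = time.perf_counter()
    net_config = preset_config(cfg.model, size_factor=cfg.size_factor)
    for key, value in cfg.network_overrides.items():
        net_config[key] = value
    n_fibres = next(
        l["n_excitatory"] for l in net_config["layers"] if l["name"] == "AN"
    )

    stage_seeds = {
        s: subseed(cfg.seed, s)
        for s in ("templates", "train-data", "test-data", "network", "shuffle")
    }
    log.info("experiment %s: generating data", cfg.config_hash)
    if cfg.template_kind == "vowel":
        templates = vowel_templates(
            n_classes=cfg.n_classes,
            n_fibres=n_fibres,
            duration_ms=cfg.pattern_duration_ms,
            band_width=max(2, int(round(cfg.band_width_frac * n_fibres))),
            spikes_per_volley=cfg.spikes_per_volley,
            seed=stage_seeds["templates"],
        )
    elif cfg.template_kind == "random":
        templates = random_templates(
            n_classes=cfg.n_classes,
            n_fibres=n_fibres,
            n_pattern_spikes=cfg.n_pattern_spikes,
            duration_ms=cfg.pattern_duration_ms,
            variation_ms=cfg.variation_ms,
            seed=stage_seeds["templates"],
        )
    else:
        raise ValueError(f"unknown template_kind {cfg.template_kind!r}")
    noise = cfg.noise_model()
    train_raster = generate_dataset(
        templates, noise, cfg.n_speakers, 1, n_fibres,
        silence_ms=cfg.silence_ms, seed=stage_seeds["train-data"],
    )
    test_raster = generate_dataset(
        templates, noise, cfg.n_speakers, cfg.n_test_repetitions, n_fibres,
        silence_ms=cfg.silence_ms, seed=stage_seeds["test-data"],
    )

    network = build_network(net_config, seed=stage_seeds["network"])
    results: dict[str, Any] = {
        "config": cfg,
        "train_raster": train_raster,
        "test_raster": test_raster,
    }

    if cfg.evaluate_untrained:
        log.info("evaluating untrained network")
        results["untrained"] = _evaluate(cfg, network, test_raster, "untrained")

    weights_before = network.weight_snapshot()
    log.info("training: %d passes over %d presentations",
             cfg.epochs, len(train_raster.presentations))
    for epoch in range(cfg.epochs):
        run_simulation(network, train_raster, learning=True, record_layers=[])
    weights_after = network.weight_snapshot()

    log.info("evaluating trained network")
    results["trained"] = _evaluate(cfg, network, test_raster, "trained")
    results["weights_before"] = weights_before
    results["weights_after"] = weights_after
    results["weight_histograms"] = weight_histogram(weights_before, weights_after)

    if cfg.shuffled_control:
        log.info("evaluating shuffled-weight control")
        shuffle_weights(network, seed=stage_seeds["shuffle"])
        results["shuffled"] = _evaluate(cfg, network, test_raster, "shuffled")

    results["manifest"] = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash,
        "stage_seeds": stage_seeds,
        "n_train_presentations": int(len(train_raster.presentations)),
        "n_test_presentations": int(len(test_raster.presentations)),
        "stages": sorted(
            k for k in ("untrained", "trained", "shuffled") if k in results
        ),
    }
    log.info("experiment done in %.1f s", time.perf_counter() - t0)
    return results


def run_comparison_study(
    seed: int,
    size_factor: float = 0.2,
    n_speakers_train: int = 4,
    n_speakers_test: int = 4,
    n_test_repetitions: int = 4,
    epochs: int = 10,
    duration_ms: float = 120.0,
    silence_ms: float = 60.0,
    j_cells: int = 25,
    n_subsamples: int = 6,
    mi_layer: str = "A1",
    noise: NoiseModel | None = None,
) -> dict[str, float]:
    """Full-vs-reduced architecture comparison at miniature scale.

    Runs, for one seed: (i) the full subcortical+cortical model trained
    on the synthetic two-word dataset, evaluated before training, after
    training, and after a shuffled-weight control; (ii) the reduced
    model trained on the same dataset; (iii) the reduced model trained
    on patternless input (every pattern spike deleted, background only)
    to expose the depression-dominant weight drift in isolation.

    Returns a flat dict of summary statistics: median PI per layer,
    median MI per condition/mode at ``mi_layer``, and plastic-weight
    summaries (medians and the fraction strengthened above the initial
    band).
    """
    if noise is None:
        noise = ExperimentConfig().noise_model()
    rs = lambda label: subseed(seed, label)
    net_cfg = preset_config("full", size_factor=size_factor)
    n_fibres = next(
        l["n_excitatory"] for l in net_cfg["layers"] if l["name"] == "AN"
    )
    templates = vowel_templates(
        n_classes=2,
        n_fibres=n_fibres,
        duration_ms=duration_ms,
        band_width=max(2, int(round(0.1 * n_fibres))),
        seed=rs("templates"),
    )
    train = generate_dataset(
        templates, noise, n_speakers_train, 1, n_fibres,
        silence_ms=silence_ms, seed=rs("train-data"),
    )
    test = generate_dataset(
        templates, noise, n_speakers_test, n_test_repetitions, n_fibres,
        silence_ms=silence_ms, seed=rs("test-data"),
    )
    # rate-matched patternless control: delete every pattern spike and
    # fold the deleted rate back into the background, so only the
    # repeating structure (not the overall drive) is removed
    pattern_rate_hz = (
        templates[0].neurons.size
        * (1.0 - noise.deletion_prob)
        * 1000.0
        / (duration_ms * n_fibres)
    )
    patternless = generate_dataset(
        templates,
        dataclasses.replace(
            noise,
            deletion_prob=1.0,
            background_rate_hz=noise.background_rate_hz + pattern_rate_hz,
        ),
        n_speakers_train, 1, n_fibres,
        silence_ms=silence_ms, seed=rs("noise-data"),
    )
    init_lo, init_hi = net_cfg["projections"][-1]["weight"]

    def mi_median(raster, net, mode, label):
        tbl = evaluate_model(
            raster, net.layer_sizes, modes=(mode,), layers=[mi_layer],
            n_subsamples=n_subsamples, j_cells=j_cells, seed=rs(label),
        )
        return float(tbl["mi_bits"].median())

    out: dict[str, float] = {}

    # --- full model -------------------------------------------------
    full = build_network(net_cfg, seed=rs("net-full"))
    sim = run_simulation(full, test, learning=False)
    out["mi_full_untrained_temporal"] = mi_median(
        sim["rasters"], full, "temporal", "mi-full-untrained"
    )
    for _ in range(epochs):
        run_simulation(full, train, learning=True, record_layers=[])
    W = full.weight_snapshot()["IC->A1"]
    out["w_full_ic_a1_median"] = float(np.median(W[W >= 0]))
    out["w_full_ic_a1_frac_strengthened"] = float(np.mean(W > init_hi))
    sim = run_simulation(full, test, learning=False)
    rast = sim["rasters"]
    for layer in ("AN", "IC"):
        tbl = layer_pi(rast, layer, full.layer_sizes[layer],
                       seed=rs(f"pi-{layer}"))
        out[f"pi_{layer.lower()}_full"] = float(np.nanmedian(tbl["pi"]))
    out["mi_full_trained_temporal"] = mi_median(
        rast, full, "temporal", "mi-full-trained-t"
    )
    out["mi_full_trained_rate"] = mi_median(
        rast, full, "rate", "mi-full-trained-r"
    )
    shuffle_weights(full, seed=rs("shuffle"))
    sim = run_simulation(full, test, learning=False)
    out["mi_full_shuffled_temporal"] = mi_median(
        sim["rasters"], full, "temporal", "mi-full-shuffled"
    )

    # --- reduced model on the same data -----------------------------
    reduced = build_network(
        preset_config("reduced", size_factor=size_factor), seed=rs("net-red")
    )
    for _ in range(epochs):
        run_simulation(reduced, train, learning=True, record_layers=[])
    sim = run_simulation(reduced, test, learning=False)
    rast = sim["rasters"]
    tbl = layer_pi(rast, "A1", reduced.layer_sizes["A1"], seed=rs("pi-red-A1"))
    out["pi_a1_reduced"] = float(np.nanmedian(tbl["pi"]))
    out["mi_reduced_trained_temporal"] = mi_median(
        rast, reduced, "temporal", "mi-red-trained-t"
    )
    out["mi_reduced_trained_rate"] = mi_median(
        rast, reduced, "rate", "mi-red-trained-r"
    )

    # --- reduced model on patternless input (depression drift) ------
    blank = build_network(
        preset_config("reduced", size_factor=size_factor), seed=rs("net-blank")
    )
    for _ in range(epochs):
        run_simulation(blank, patternless, learning=True, record_layers=[])
    Wb = blank.weight_snapshot()["AN->A1"]
    out["w_reduced_patternless_median"] = float(np.median(Wb[Wb >= 0]))
    out["w_init_lo"], out["w_init_hi"] = float(init_lo), float(init_hi)
    return out


def save_results(results: dict[str, Any], outdir: str | Path) -> None:
    """Write manifest, PI/MI tables, weight histograms and rasters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(results["manifest"], fh, indent=2, sort_keys=True)
    results["test_raster"].save(outdir / "test_raster")
    for stage in ("untrained", "trained", "shuffled"):
        if stage not in results:
            continue
        bundle = results[stage]
        bundle["mi"].to_csv(outdir / f"mi_{stage}.csv", index=False)
        for layer, table in bundle["pi"].items():
            table.to_csv(outdir / f"pi_{stage}_{layer}.csv", index=False)
    if "weight_histograms" in results:
        rows = []
        for name, h in results["weight_histograms"].items():
            for i in range(len(h["before"])):
                rows.append(
                    {
                        "projection": name,
                        "bin_lo": h["edges"][i],
                        "bin_hi": h["edges"][i + 1],
                        "before": int(h["before"][i]),
                        "after": int(h["after"][i]),
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "weight_histograms.csv", index=False)
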