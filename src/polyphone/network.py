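"""Hierarchical spiking-network architectures and the simulation loop.

Two architectures are provided as presets.  The full model mirrors the
ascending auditory pathway: auditory nerve (AN) feeding three cochlear
nucleus subpopulations -- chopper (CH, narrow tonotopic Gaussian input),
primary-like (PL, strong one-to-one input) and onset (ON, sparse
wide-band input) -- which converge on the inferior colliculus (IC);
IC projects fully, with uniformly distributed conduction delays and
mixed STDP, to primary auditory cortex (A1), and A1 likewise to the
belt area.  The reduced control model wires AN straight to A1 and Belt
with the same plastic connectivity, skipping the subcortical de-noising
stages (and uses a stronger LTD magnitude, -0.033 instead of -0.015).

Within every simulated layer, each excitatory cell drives a dedicated
inhibitory partner one-to-one, and each inhibitory cell projects back
to all excitatory cells, implementing tightly balanced within-layer
competition.

The input layer is an event source, not a simulated population: AN
spikes are injected at their listed times.  All other cells are
Izhikevich neurons advanced synchronously by forward Euler at
dt = 0.1 ms.  Synapses deliver Dirac-delta current pulses; conduction
delays are quantised to the dt grid and realised with per-projection
ring buffers, so a spike with delay D arrives max(1, ceil(D/dt)) steps
after emission -- every connection, including the nominally zero-delay
subcortical ones, has a minimum transmission latency of one step.

Neuron states, currents and STDP pairing ledgers are reset at each
presentation onset, making presentations exchangeable; the silent tail
of every presentation lets delayed activity play out first.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from .neuron import DT_MS, SPIKE_THRESHOLD_MV, V_FLOOR_MV, NeuronArray, preset
from .plasticity import STDPParams
from .raster import Presentation, SpikeRaster

# ---------------------------------------------------------------------------
# Configuration presets (full and reduced architecture parameter tables)
# ---------------------------------------------------------------------------

_LAYER_TABLE = {
    # name: (n_exc, n_inh, w_EI, w_IE, exc preset)
    "AN": (1000, 0, 0.0, 0.0, None),
    "CH": (1000, 1000, 0.0, 0.0, "excitatory_subcortical"),
    "PL": (1000, 1000, 0.0, 0.0, "excitatory_subcortical"),
    "ON": (100, 100, 1000.0, -75.0, "excitatory_subcortical"),
    "IC": (1000, 1000, 1000.0, 0.0, "excitatory_subcortical"),
    "A1": (1000, 1000, 1000.0, -6.0, "excitatory_cortical"),
    "Belt": (1000, 1000, 1000.0, -6.0, "excitatory_cortical"),
}

#: Dead-synapse proportion for the sparse AN->ON projection.  The
#: alternative documented reading (34% live connectivity, i.e. 0.66 dead)
#: can be requested through a config override.
AN_ON_P_DEAD = 0.46

PLASTIC_DELAY_RANGE = (0.0, 50.0)
PLASTIC_INIT_RANGE = (30.0, 35.0)


def _layer_cfg(name: str, size_factor: float) -> dict[str, Any]:
    n_e, n_i, w_ei, w_ie, exc = _LAYER_TABLE[name]
    scale = lambda n: max(1, int(round(n * size_factor)))
    return {
        "name": name,
        "n_excitatory": scale(n_e),
        "n_inhibitory": scale(n_i) if n_i else 0,
        "excitatory_preset": exc,
        "inhibitory_preset": "inhibitory" if n_i else None,
        "w_EI": w_ei,
        # I->E is one-to-all, so its weight scales inversely with the
        # population count to keep the summed inhibition comparable
        "w_IE": w_ie / size_factor,
    }


def preset_config(name: str, size_factor: float = 1.0) -> dict[str, Any]:
    """Parameter dictionary for the ``full`` or ``reduced`` architecture.

    ``size_factor`` scales every population count, for miniature desk-
    scale instances of the same architecture.  Weights are compensated
    per projection according to what each computes: 1/size_factor where
    the afferent count scales with the source population (full, sparse,
    the wide AN->CH gaussian, the one-to-all inhibition), sqrt of that
    for the synchrony-detecting AN->ON input, and no compensation for
    the narrow CH->IC convergence, one-to-one projections, or the
    plastic cortical projections (whose coincidence-detection regime
    and STDP constants must stay fixed).  At ``size_factor = 1`` the
    reference parameter table is reproduced exactly.
    """
    if name not in ("full", "reduced"):
        raise ValueError(f"unknown preset {name!r}; expected 'full' or 'reduced'")
    sf = float(size_factor)
    if sf <= 0:
        raise ValueError("size_factor must be positive")
    inv = 1.0 / sf

    def stdp(alpha_d: float) -> dict[str, float]:
        return {
            "tau_p": 15.0,
            "tau_d": 25.0,
            "alpha_p": 0.005,
            "alpha_d": alpha_d,
            "w_max": 60.0,
        }

    # Plastic cortical projections keep their reference weights and ceiling
    # at every scale: they are coincidence detectors, and the per-event
    # quantum (0.1 ms * w) must stay well below the distance to threshold
    # for selectivity to be possible at all.
    def plastic(source: str, target: str, alpha_d: float) -> dict[str, Any]:
        return {
            "source": source,
            "target": target,
            "kind": "full",
            "weight": list(PLASTIC_INIT_RANGE),
            "delay": list(PLASTIC_DELAY_RANGE),
            "plastic": True,
            "stdp": stdp(alpha_d),
        }

    if name == "full":
        layers = [_layer_cfg(n, sf) for n in _LAYER_TABLE]
        # weights of projections whose afferent count shrinks with the
        # population (wide gaussian, sparse, full) are scaled by 1/sf to
        # keep the summed drive per cell comparable; the narrow CH->IC
        # convergence and the one-to-one projections keep their absolute
        # width and weight (their afferent counts do not scale)
        projections = [
            {
                "source": "AN",
                "target": "CH",
                "kind": "gaussian",
                "sigma": max(26.0 * sf, 1.0),
                "weight": [25.0 * inv, 30.0 * inv],
            },
            {"source": "AN", "target": "PL", "kind": "one_to_one", "weight": 1000.0},
            {
                # onset cells are fluctuation (synchrony) detectors, not
                # mean-drive integrators: sqrt compensation keeps the
                # z-score of a synchronous volley constant across scales,
                # whereas full 1/sf compensation tips miniature instances
                # across the bifurcation into tonic firing
                "source": "AN",
                "target": "ON",
                "kind": "sparse",
                "p_dead": AN_ON_P_DEAD,
                "weight": 26.0 * inv**0.5,
            },
            {
                "source": "CH",
                "target": "IC",
                "kind": "gaussian",
                "sigma": 2.0,
                "weight": 400.0,
            },
            {"source": "PL", "target": "IC", "kind": "one_to_one", "weight": 400.0},
            {"source": "ON", "target": "IC", "kind": "full", "weight": 3.0 * inv},
            plastic("IC", "A1", alpha_d=-0.015),
            plastic("A1", "Belt", alpha_d=-0.015),
        ]
    else:
        layers = [_layer_cfg(n, sf) for n in ("AN", "A1", "Belt")]
        projections = [
            plastic("AN", "A1", alpha_d=-0.033),
            plastic("A1", "Belt", alpha_d=-0.033),
        ]
    return {
        "name": name,
        "input_layer": "AN",
        "layers": layers,
        "projections": projections,
    }


# ---------------------------------------------------------------------------
# Connectivity constructors
# ---------------------------------------------------------------------------


def connect_gaussian(
    source_n: int,
    target_n: int,
    sigma: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Tonotopic Bernoulli connectivity mask of shape (target_n, source_n).

    Each target cell i draws afferents from source cells j with
    probability exp(-(j - c_i)^2 / (2 sigma^2)) where c_i linearly aligns
    the two index ranges; the profile peaks at probability 1 on the
    aligned source index and is truncated (not wrapped) at the edges.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    tgt = np.arange(target_n)[:, None]
    src = np.arange(source_n)[None, :]
    centre = tgt * ((source_n - 1) / (target_n - 1)) if target_n > 1 else (
        np.full((target_n, 1), (source_n - 1) / 2.0)
    )
    p = np.exp(-((src - centre) ** 2) / (2.0 * sigma**2))
    return rng.random((target_n, source_n)) < p


def _connection_mask(
    kind: str,
    source_n: int,
    target_n: int,
    rng: np.random.Generator,
    sigma: float | None = None,
    p_dead: float | None = None,
) -> np.ndarray:
    if kind == "gaussian":
        return connect_gaussian(source_n, target_n, float(sigma), rng)
    if kind == "one_to_one":
        if source_n != target_n:
            raise ValueError(
                "one-to-one projection requires equal layer sizes "
                f"({source_n} != {target_n})"
            )
        return np.eye(target_n, dtype=bool)
    if kind == "sparse":
        if p_dead is None or not (0.0 <= p_dead <= 1.0):
            raise ValueError("sparse projection needs p_dead in [0, 1]")
        return rng.random((target_n, source_n)) >= p_dead
    if kind == "full":
        return np.ones((target_n, source_n), dtype=bool)
    raise ValueError(f"unknown connectivity kind {kind!r}")


# ---------------------------------------------------------------------------
# Realised network
# ---------------------------------------------------------------------------


@dataclass
class Layer:
    name: str
    n_excitatory: int
    n_inhibitory: int
    w_EI: float
    w_IE: float
    exc: NeuronArray | None  # None for the input layer
    inh: NeuronArray | None


class Projection:
    """A realised between-layer excitatory projection."""

    def __init__(
        self,
        source: str,
        target: str,
        weights: np.ndarray,
        delays_ms: np.ndarray,
        plastic: bool,
        stdp: STDPParams | None,
    ):
        self.source = source
        self.target = target
        self.W = weights  # (n_post, n_pre), 0 where unconnected
        self.mask = weights != 0.0
        # synchronous update: the minimum transmission latency is one step,
        # so a delay D is delivered max(1, ceil(D/dt)) steps after emission
        self.delay_steps = np.maximum(
            np.ceil(delays_ms / DT_MS - 1e-9).astype(np.int64), 1
        )
        self.plastic = plastic
        self.stdp = stdp
        if plastic and stdp is None:
            raise ValueError("plastic projection requires STDP parameters")
        n_post = weights.shape[0]
        self._delayed = bool(np.any(delays_ms > 0))
        self.max_delay_steps = int(self.delay_steps.max(initial=1))
        if self._delayed:
            self._ring = np.zeros((self.max_delay_steps + 1, n_post))
        if plastic:
            self._window_steps = int(np.ceil(stdp.window_ms / DT_MS))
            self._burst_steps = int(np.ceil(stdp.burst_ms / DT_MS))
            if self._delayed:
                # per pre cell: realised post rows grouped by delay offset,
                # with the matching column array precomputed, so LTD
                # processing at arrival time needs no searching/allocation
                self._delay_groups: list[list[tuple[int, np.ndarray, np.ndarray]]] = []
                for j in range(self.W.shape[1]):
                    rows = np.flatnonzero(self.mask[:, j])
                    d = self.delay_steps[rows, j]
                    order = np.argsort(d, kind="stable")
                    rows, d = rows[order], d[order]
                    cuts = np.flatnonzero(np.diff(d)) + 1
                    self._delay_groups.append(
                        [
                            (int(dg[0]), rg, np.full(rg.size, j, dtype=np.int64))
                            for dg, rg in zip(np.split(d, cuts), np.split(rows, cuts))
                        ]
                    )
        self.reset_buffers()

    # -- per-presentation state ------------------------------------

    def reset_buffers(self) -> None:
        if self._delayed:
            self._ring[:] = 0.0
            self._arrival_buckets: dict[int, list[int]] = {}
        if self.plastic:
            n_post, n_pre = self.W.shape
            self._active_emission = np.full(n_pre, -(10**9), dtype=np.int64)
            self._unused = np.zeros((n_post, n_pre), dtype=bool)
            self._last_post = np.full(n_post, -(10**9), dtype=np.int64)

    # -- simulation-time operations --------------------------------

    def emit(
        self, pre_spikes: np.ndarray, step: int, learn: bool = False
    ) -> np.ndarray | None:
        """Handle pre-synaptic spikes at ``step``.

        Returns the current vector to add to the target *this* step for
        the zero-delay case, or None when delivery is buffered.
        """
        if pre_spikes.size == 0:
            return None
        if self.plastic and learn:
            self._register_emissions(pre_spikes, step)
        if not self._delayed:
            return self.W[:, pre_spikes].sum(axis=1)
        L = self._ring.shape[0]
        posts = np.arange(self.W.shape[0])
        for j in pre_spikes:
            arrive = (step + self.delay_steps[:, j]) % L
            self._ring[arrive, posts] += self.W[:, j]
        return None

    def collect(self, step: int) -> np.ndarray | None:
        """Currents arriving at ``step`` from the delay ring buffer."""
        if not self._delayed:
            return None
        k = step % self._ring.shape[0]
        out = self._ring[k].copy()
        self._ring[k] = 0.0
        return out

    # -- STDP ------------------------------------------------------

    def _register_emissions(self, pre_spikes: np.ndarray, step: int) -> None:
        for j in pre_spikes:
            # first-spike-only: later spikes of the same burst are ignored
            # for plasticity (current is still delivered); spikes beyond
            # the burst window re-register, keeping pairing nearest.
            if step - self._active_emission[j] < self._burst_steps:
                continue
            self._active_emission[j] = step
            self._unused[:, j] = self.mask[:, j]
            if self._delayed:
                # schedule per-synapse LTD processing at the arrival steps
                buckets = self._arrival_buckets
                for off, rows, cols in self._delay_groups[j]:
                    key = step + off
                    entry = buckets.get(key)
                    if entry is None:
                        buckets[key] = entry = ([], [])
                    entry[0].append(rows)
                    entry[1].append(cols)
            else:
                # all arrivals land one step after emission; no post spike
                # for that step exists yet, but a coincident one would be an
                # s = 0 tie (no update), so LTD can be applied right away
                rows = np.flatnonzero(self.mask[:, j])
                self._apply_ltd(rows, np.full(rows.size, j), step + 1)

    def _apply_ltd(
        self, rows: np.ndarray, cols: np.ndarray, arrival_step: int
    ) -> None:
        """LTD for the synapses (rows, cols) whose arrival is now."""
        p = self.stdp
        s_steps = self._last_post[rows] - arrival_step  # <= 0 for LTD
        sel = (s_steps < 0) & (-s_steps <= self._window_steps)
        if not sel.any():
            return
        rows, cols = rows[sel], cols[sel]
        dw = p.w_max * p.alpha_d * np.exp(s_steps[sel] * DT_MS / p.tau_d)
        self.W[rows, cols] = np.maximum(0.0, self.W[rows, cols] + dw)

    def process_arrivals(self, step: int) -> None:
        """Run LTD for arrivals scheduled at this step (one batched pass)."""
        if not (self.plastic and self._delayed):
            return
        entry = self._arrival_buckets.pop(step, None)
        if entry is None:
            return
        row_parts, col_parts = entry
        if len(row_parts) == 1:
            rows, cols = row_parts[0], col_parts[0]
        else:
            rows = np.concatenate(row_parts)
            cols = np.concatenate(col_parts)
        self._apply_ltd(rows, cols, step)

    def process_post_spikes(self, post_spikes: np.ndarray, step: int) -> None:
        """LTP pairing of post spikes with pending unused arrivals."""
        if not self.plastic or post_spikes.size == 0:
            return
        p = self.stdp
        arrivals = self._active_emission[None, :] + self.delay_steps[post_spikes, :]
        s_steps = step - arrivals
        sel = self._unused[post_spikes, :] & (s_steps > 0) & (
            s_steps <= self._window_steps
        )
        if sel.any():
            rows, cols = np.nonzero(sel)
            s_ms = s_steps[rows, cols] * DT_MS
            scale = p.alpha_p * np.exp(-s_ms / p.tau_p)
            idx = (post_spikes[rows], cols)
            self.W[idx] += (p.w_max - self.W[idx]) * scale
            self._unused[idx] = False
        self._last_post[post_spikes] = step


class Network:
    """Layers plus projections; built once, simulated per presentation."""

    def __init__(
        self,
        layers: list[Layer],
        projections: list[Projection],
        input_layer: str,
        config: dict[str, Any],
    ):
        self.layers = {l.name: l for l in layers}
        self.order = [l.name for l in layers]  # topological (build order)
        self.projections = projections
        self.input_layer = input_layer
        self.config = config
        self._incoming: dict[str, list[Projection]] = {n: [] for n in self.order}
        self._outgoing: dict[str, list[Projection]] = {n: [] for n in self.order}
        for p in projections:
            self._incoming[p.target].append(p)
            self._outgoing[p.source].append(p)

    @property
    def layer_sizes(self) -> dict[str, int]:
        return {n: l.n_excitatory for n, l in self.layers.items()}

    def plastic_projections(self) -> list[Projection]:
        return [p for p in self.projections if p.plastic]

    def weight_snapshot(self) -> dict[str, np.ndarray]:
        return {
            f"{p.source}->{p.target}": p.W.copy()
            for p in self.projections
            if p.plastic
        }


def build_network(
    config: str | dict[str, Any],
    seed: int | np.random.Generator = 0,
    size_factor: float = 1.0,
) -> Network:
    """Realise a network from a preset name or a config dictionary."""
    if isinstance(config, str):
        config = preset_config(config, size_factor=size_factor)
    config = copy.deepcopy(config)
    rng = np.random.default_rng(seed)

    layers: list[Layer] = []
    for lc in config["layers"]:
        is_input = lc["name"] == config.get("input_layer")
        n_e, n_i = int(lc["n_excitatory"]), int(lc.get("n_inhibitory", 0))
        exc = None
        inh = None
        if not is_input:
            exc = NeuronArray([preset(lc["excitatory_preset"])] * n_e)
        if n_i:
            inh = NeuronArray([preset(lc["inhibitory_preset"])] * n_i)
        w_ie = float(lc.get("w_IE", 0.0))
        if w_ie > 0:
            raise ValueError("w_IE must be non-positive (inhibitory)")
        layers.append(
            Layer(
                name=lc["name"],
                n_excitatory=n_e,
                n_inhibitory=n_i,
                w_EI=float(lc.get("w_EI", 0.0)),
                w_IE=w_ie,
                exc=exc,
                inh=inh,
            )
        )
    by_name = {l.name: l for l in layers}

    projections: list[Projection] = []
    for pc in config["projections"]:
        src, tgt = by_name[pc["source"]], by_name[pc["target"]]
        mask = _connection_mask(
            pc["kind"],
            src.n_excitatory,
            tgt.n_excitatory,
            rng,
            sigma=pc.get("sigma"),
            p_dead=pc.get("p_dead"),
        )
        w_spec = pc["weight"]
        if np.isscalar(w_spec):
            W = np.where(mask, float(w_spec), 0.0)
        else:
            lo, hi = w_spec
            W = np.where(
                mask, rng.uniform(lo, hi, size=mask.shape), 0.0
            )
        d_spec = pc.get("delay")
        if d_spec is None:
            delays = np.zeros_like(W)
        else:
            lo, hi = d_spec
            delays = np.where(mask, rng.uniform(lo, hi, size=mask.shape), 0.0)
        stdp = (
            STDPParams(**pc["stdp"]) if pc.get("stdp") is not None else None
        )
        projections.append(
            Projection(
                source=pc["source"],
                target=pc["target"],
                weights=W,
                delays_ms=delays,
                plastic=bool(pc.get("plastic", False)),
                stdp=stdp,
            )
        )
    return Network(layers, projections, config["input_layer"], config)


# ---------------------------------------------------------------------------
# Simulation loop
# ---------------------------------------------------------------------------


def _input_spikes_by_step(
    events: pd.DataFrame, n_steps: int
) -> list[np.ndarray]:
    """Group input events into per-step neuron-index arrays."""
    steps = np.minimum(
        np.rint(events["time_ms"].to_numpy() / DT_MS).astype(np.int64),
        n_steps - 1,
    )
    neurons = events["neuron"].to_numpy()
    order = np.argsort(steps, kind="stable")
    steps, neurons = steps[order], neurons[order]
    out: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * n_steps
    if steps.size:
        bounds = np.flatnonzero(np.diff(steps)) + 1
        for chunk_steps, chunk in zip(
            np.split(steps, bounds), np.split(neurons, bounds)
        ):
            out[chunk_steps[0]] = chunk
    return out


class _GlobalState:
    """All simulated populations concatenated into one state vector.

    The update is synchronous: currents accumulated while processing step
    k are integrated at step k+1, so every connection (including the
    nominally zero-delay subcortical ones) has a minimum transmission
    latency of one 0.1 ms step.
    """

    def __init__(self, network: Network):
        self.network = network
        input_name = network.input_layer
        self.sim_layers = [n for n in network.order if n != input_name]
        self.e_off: dict[str, int] = {}
        self.i_off: dict[str, int] = {}
        parts_a, parts_b, parts_c, parts_d, parts_rest = [], [], [], [], []
        bounds = [0]
        pops: list[tuple[str, str]] = []  # (layer, 'E'|'I') per population
        off = 0
        for name in self.sim_layers:
            layer = network.layers[name]
            for kind, arr in (("E", layer.exc), ("I", layer.inh)):
                if arr is None:
                    continue
                (self.e_off if kind == "E" else self.i_off)[name] = off
                parts_a.append(arr.a)
                parts_b.append(arr.b)
                parts_c.append(arr.c)
                parts_d.append(arr.d)
                parts_rest.append(arr._v_rest)
                off += arr.n
                bounds.append(off)
                pops.append((name, kind))
        self.n = off
        self.a = np.concatenate(parts_a) if parts_a else np.empty(0)
        self.b = np.concatenate(parts_b) if parts_b else np.empty(0)
        self.c = np.concatenate(parts_c) if parts_c else np.empty(0)
        self.d = np.concatenate(parts_d) if parts_d else np.empty(0)
        self.adt = self.a * DT_MS
        self.v_rest = np.concatenate(parts_rest) if parts_rest else np.empty(0)
        self.bounds = np.array(bounds)
        self.pops = pops
        self.v = self.v_rest.copy()
        self.u = self.b * self.v_rest

    def reset(self) -> None:
        self.v[:] = self.v_rest
        self.u[:] = self.b * self.v_rest

    def step(self, I: np.ndarray) -> np.ndarray:
        """One synchronous Euler step; returns global spike indices."""
        v, u = self.v, self.u
        v_new = v + DT_MS * (0.04 * v**2 + 5.0 * v + 140.0 - u + I)
        u += self.adt * (self.b * v - u)
        spikes = np.flatnonzero(v_new >= SPIKE_THRESHOLD_MV)
        if spikes.size:
            v_new[spikes] = self.c[spikes]
            u[spikes] += self.d[spikes]
        np.maximum(v_new, V_FLOOR_MV, out=v_new)
        self.v = v_new
        return spikes

    def split(self, spikes: np.ndarray):
        """Yield (layer, kind, local indices) for a global spike vector."""
        cuts = np.searchsorted(spikes, self.bounds)
        for p, (name, kind) in enumerate(self.pops):
            lo, hi = cuts[p], cuts[p + 1]
            if hi > lo:
                yield name, kind, spikes[lo:hi] - self.bounds[p]


def run_simulation(
    network: Network,
    input_raster: SpikeRaster,
    learning: bool = False,
    record_layers: list[str] | None = None,
) -> dict[str, Any]:
    """Drive the network with an input raster, presentation by presentation.

    Returns a dict with ``rasters`` (one :class:`SpikeRaster` covering the
    recorded layers), ``weights_before`` and ``weights_after`` (plastic
    snapshots).  The run is bit-reproducible: all randomness lives in
    network construction and input generation.
    """
    input_name = network.input_layer
    n_input = network.layers[input_name].n_excitatory
    inp = input_raster.layer_events(input_name)
    if inp["neuron"].size and inp["neuron"].max() >= n_input:
        raise ValueError("input raster neuron index exceeds input layer size")
    record = set(record_layers if record_layers is not None else network.order)
    rec_input = input_name in record

    state = _GlobalState(network)
    eslice = {
        n: slice(state.e_off[n], state.e_off[n] + network.layers[n].n_excitatory)
        for n in state.sim_layers
    }
    delayed_in: dict[str, list[Projection]] = {}
    weights_before = network.weight_snapshot()
    events: list[tuple[int, str, int, float]] = []
    presentations: list[Presentation] = []
    inp_by_pid = dict(tuple(inp.groupby("presentation_id")))
    empty = inp.iloc[0:0]

    def route(proj: Projection, pre_idx: np.ndarray, step: int,
              I_next: np.ndarray) -> None:
        imm = proj.emit(pre_idx, step, learn=learning)
        if imm is not None:
            I_next[eslice[proj.target]] += imm

    for _, prow in input_raster.presentations.iterrows():
        pid = int(prow["presentation_id"])
        duration = float(prow["duration_ms"])
        n_steps = int(np.ceil(duration / DT_MS))
        per_step = _input_spikes_by_step(inp_by_pid.get(pid, empty), n_steps)
        state.reset()
        for proj in network.projections:
            proj.reset_buffers()
        I_now = np.zeros(state.n)
        I_next = np.zeros(state.n)
        plastic = network.plastic_projections() if learning else []

        for step in range(n_steps):
            I_now, I_next = I_next, I_now
            I_next[:] = 0.0
            # delayed deliveries landing this step
            for proj in network.projections:
                buffered = proj.collect(step)
                if buffered is not None:
                    I_now[eslice[proj.target]] += buffered
            for proj in plastic:
                proj.process_arrivals(step)
            # external input events at this step
            in_idx = per_step[step]
            if in_idx.size:
                if rec_input:
                    t = step * DT_MS
                    events.extend((pid, input_name, int(k), t) for k in in_idx)
                for proj in network._outgoing[input_name]:
                    route(proj, in_idx, step, I_next)
            # integrate everything (blow-up check amortised: NaN/inf states
            # either spike immediately or persist until the periodic check)
            spikes = state.step(I_now)
            if step % 200 == 0 and not np.all(np.isfinite(state.v)):
                raise FloatingPointError("neuron integration blew up")
            if spikes.size:
                if not np.isfinite(state.v.max()):
                    raise FloatingPointError("neuron integration blew up")
                t = step * DT_MS
                for name, kind, idx in state.split(spikes):
                    layer = network.layers[name]
                    if kind == "E":
                        if name in record:
                            events.extend((pid, name, int(k), t) for k in idx)
                        for proj in network._incoming[name]:
                            if proj.plastic and learning:
                                proj.process_post_spikes(idx, step)
                        for proj in network._outgoing[name]:
                            route(proj, idx, step, I_next)
                        if layer.inh is not None and layer.w_EI != 0.0:
                            k = idx[idx < layer.n_inhibitory]
                            I_next[state.i_off[name] + k] += layer.w_EI
                    else:  # inhibitory: one-to-all within the layer
                        if layer.w_IE != 0.0:
                            I_next[eslice[name]] += layer.w_IE * idx.size
        presentations.append(
            Presentation(
                presentation_id=pid,
                stimulus_class=int(prow["stimulus_class"]),
                exemplar=int(prow["exemplar"]),
                repetition=int(prow["repetition"]),
                duration_ms=duration,
            )
        )

    raster = SpikeRaster.from_events(events, presentations)
    return {
        "rasters": raster,
        "weights_before": weights_before,
        "weights_after": network.weight_snapshot(),
    }


def weight_histogram(
    snapshot_before: dict[str, np.ndarray],
    snapshot_after: dict[str, np.ndarray],
    bins: int = 60,
    w_max: float | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Histogram counts of plastic weights before/after training.

    Only realised synapses are counted (the histogram total equals the
    synapse count and is conserved between the two snapshots).
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for key in snapshot_before:
        if key not in snapshot_after:
            raise KeyError(f"projection {key} missing from 'after' snapshot")
        wb = snapshot_before[key]
        wa = snapshot_after[key]
        top = w_max if w_max is not None else max(wb.max(), wa.max())
        edges = np.linspace(0.0, top, bins + 1)
        live = wb > 0
        before, _ = np.histogram(wb[live], bins=edges)
        after, _ = np.histogram(wa[live], bins=edges)
        out[key] = {"edges": edges, "before": before, "after": after}
    return out
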