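"""Izhikevich point-neuron dynamics.

All cells in the network (everything downstream of the auditory-nerve
surrogate) are Izhikevich quadratic integrate-and-fire neurons

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)

with after-spike resetting ``v <- c, u <- u + d`` whenever the updated
membrane potential reaches the 30 mV cutoff.  Three parameter presets are
used: a spike-frequency-adaptation cell for cortical excitatory neurons, a
Class-1 (continuously graded f-I curve) cell for subcortical excitatory
neurons, and a phasic-bursting cell for inhibitory interneurons.

Integration is a single forward-Euler step at ``dt = 0.1`` ms (the
two-half-step update of Izhikevich's original reference code is *not*
used).  Synaptic input is a train of Dirac-delta current pulses: a weight
``w`` arriving on a given step contributes ``w`` to that step's ``I`` and
nothing afterwards.  Blow-ups (non-finite state) raise instead of being
clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Simulation time step in ms, shared by every module that integrates.
DT_MS = 0.1

#: Spike cutoff in mV, common to all presets.
SPIKE_THRESHOLD_MV = 30.0

#: Hyperpolarisation floor in mV.  The quadratic membrane equation is only
#: valid in a basin around rest; a strong delta-pulse of inhibition can
#: otherwise push v so low that the v^2 term produces a spurious rebound
#: spike.  Clamping at -100 mV keeps inhibition inhibitory.
V_FLOOR_MV = -100.0


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich ``a``-``d`` constants plus the spike cutoff.

    a : recovery time scale (smaller = slower recovery)
    b : sensitivity of the recovery variable to subthreshold v
    c : after-spike membrane reset (mV)
    d : after-spike recovery increment
    """

    a: float
    b: float
    c: float
    d: float
    threshold: float = SPIKE_THRESHOLD_MV

    def rest_state(self) -> "NeuronState":
        """Analytic stable resting point for I = 0.

        At rest ``u = b v`` and v solves ``0.04 v^2 + (5 - b) v + 140 = 0``;
        the more hyperpolarised root is the stable one.
        """
        roots = np.roots([0.04, 5.0 - self.b, 140.0])
        if np.iscomplexobj(roots) and np.any(np.abs(roots.imag) > 1e-9):
            raise ValueError("preset has no real resting point at I=0")
        v_rest = float(np.min(roots.real))
        return NeuronState(v=v_rest, u=self.b * v_rest)


@dataclass
class NeuronState:
    """Membrane potential v (mV) and recovery variable u."""

    v: float
    u: float


_PRESETS: dict[str, NeuronParams] = {
    # Spike-frequency adaptation ("F"): cortical excitatory cells.
    "excitatory_cortical": NeuronParams(a=0.01, b=0.2, c=-65.0, d=8.0),
    # Class 1 ("G"): subcortical excitatory cells (graded f-I, integrator).
    "excitatory_subcortical": NeuronParams(a=0.02, b=-0.1, c=-55.0, d=6.0),
    # Phasic bursting ("D"): inhibitory interneurons.
    "inhibitory": NeuronParams(a=0.02, b=0.25, c=-55.0, d=0.05),
}


def preset(name: str) -> NeuronParams:
    """Return one of the three named parameter presets."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown neuron preset {name!r}; expected one of {sorted(_PRESETS)}"
        ) from None


def step_neuron(
    state: NeuronState,
    params: NeuronParams,
    I: float,
    dt: float = DT_MS,
) -> tuple[NeuronState, bool]:
    """Advance a single neuron by one forward-Euler step.

    Returns the new state and whether a spike was emitted.  On a spike the
    returned state already holds the reset values (v = c, u = u + d); the
    pre-reset overshoot is not preserved.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.isfinite(state.v) and np.isfinite(state.u) and np.isfinite(I)):
        raise FloatingPointError("non-finite neuron state or current")
    v = state.v + dt * (0.04 * state.v**2 + 5.0 * state.v + 140.0 - state.u + I)
    u = state.u + dt * params.a * (params.b * state.v - state.u)
    if not (np.isfinite(v) and np.isfinite(u)):
        raise FloatingPointError("neuron integration blew up")
    if v >= params.threshold:
        return NeuronState(v=params.c, u=u + params.d), True
    return NeuronState(v=max(v, V_FLOOR_MV), u=u), False


# ---------------------------------------------------------------------------
# Vectorised form used by the network simulator.
# ---------------------------------------------------------------------------


class NeuronArray:
    """A population of Izhikevich neurons integrated in lockstep.

    Heterogeneous presets are supported by storing per-neuron a-d vectors.
    """

    def __init__(self, params_per_neuron: list[NeuronParams]):
        self.n = len(params_per_neuron)
        self.a = np.array([p.a for p in params_per_neuron])
        self.b = np.array([p.b for p in params_per_neuron])
        self.c = np.array([p.c for p in params_per_neuron])
        self.d = np.array([p.d for p in params_per_neuron])
        self.threshold = np.array([p.threshold for p in params_per_neuron])
        self.v = np.empty(self.n)
        self.u = np.empty(self.n)
        self.reset_state()

    def reset_state(self) -> None:
        """Return every neuron to its preset's analytic resting point."""
        if not hasattr(self, "_v_rest"):
            v_rest = np.empty(self.n)
            seen: dict[tuple[float, float], float] = {}
            for i in range(self.n):
                key = (self.b[i], self.threshold[i])
                if key not in seen:
                    roots = np.roots([0.04, 5.0 - self.b[i], 140.0])
                    seen[key] = float(np.min(roots.real))
                v_rest[i] = seen[key]
            self._v_rest = v_rest
        self.v[:] = self._v_rest
        self.u[:] = self.b * self._v_rest

    def step(self, I: np.ndarray, dt: float = DT_MS) -> np.ndarray:
        """One Euler step for the whole population; returns the spike mask."""
        v, u = self.v, self.u
        v_new = v + dt * (0.04 * v**2 + 5.0 * v + 140.0 - u + I)
        u_new = u + dt * self.a * (self.b * v - u)
        if not np.all(np.isfinite(v_new)):
            raise FloatingPointError("neuron integration blew up")
        spiked = v_new >= self.threshold
        if spiked.any():
            v_new[spiked] = self.c[spiked]
            u_new[spiked] += self.d[spiked]
        np.maximum(v_new, V_FLOOR_MV, out=v_new)
        self.v, self.u = v_new, u_new
        return spiked
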