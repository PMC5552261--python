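"""Spike-timing-dependent plasticity with conduction-delay-aware pairing.

The learning rule is the "mixed" exponential STDP scheme: the weight
update magnitude is

    f(s) = alpha_p * exp(-s / tau_p)   if s > 0  (LTP)
    f(s) = alpha_d * exp( s / tau_d)   if s < 0  (LTD)

where ``s = t_post - (t_pre + delay)`` is computed on the *arrival* time
of the pre-synaptic spike at the post-synaptic cell, not on its emission
time.  LTP is multiplicative towards the ceiling ``w_max`` (strong
synapses potentiate less); LTD is additive with a hard floor at 0 nA:

    w <- w + (w_max - w) * f(s)      (LTP)
    w <- max(0, w + w_max * f(s))    (LTD)

Pairing follows the nearest-neighbour scheme with a first-spike-only
restriction: when the same pre-synaptic cell fires several times inside
an ongoing STDP window, only its first spike takes part in the pairing
bookkeeping; each pre-synaptic arrival is usable for at most one LTP
pairing, and each arrival pairs for LTD with the most recent preceding
post-synaptic spike.  Exactly simultaneous arrival and post spike
(s = 0) produces no update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Pairings further apart than this multiple of the slower time constant are
#: dropped; the corresponding scale factor is below exp(-7) ~ 9e-4 of alpha.
WINDOW_TAU_MULTIPLE = 7.0


@dataclass(frozen=True)
class STDPParams:
    """Parameters of the mixed exponential STDP rule.

    tau_p, tau_d : LTP / LTD time constants (ms); the defaults follow the
        physiological asymmetry (LTD window wider than LTP).
    alpha_p : LTP magnitude (> 0).
    alpha_d : LTD magnitude (< 0); ``-0.015`` in the full model,
        ``-0.033`` in the reduced model.
    w_max : weight ceiling (nA).
    """

    tau_p: float = 15.0
    tau_d: float = 25.0
    alpha_p: float = 0.005
    alpha_d: float = -0.015
    w_max: float = 60.0

    def __post_init__(self) -> None:
        if self.tau_p <= 0 or self.tau_d <= 0:
            raise ValueError("STDP time constants must be positive")
        if self.alpha_p <= 0:
            raise ValueError("alpha_p must be positive")
        if self.alpha_d >= 0:
            raise ValueError("alpha_d must be negative")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")

    @property
    def window_ms(self) -> float:
        """Truncation horizon for pairings, in ms."""
        return WINDOW_TAU_MULTIPLE * max(self.tau_p, self.tau_d)

    @property
    def burst_ms(self) -> float:
        """First-spike-only suppression window, in ms.

        Further spikes of the same pre-synaptic cell within one LTP time
        constant of its registered arrival count as the same burst and
        are ignored; a later spike re-registers, so pairing remains
        nearest-neighbour between distinct firing events.
        """
        return self.tau_p


def stdp_scale(s: float, params: STDPParams) -> float:
    """Exponential STDP scale factor for a signed spike-time difference.

    ``s`` is in ms, positive for pre-before-post (LTP).  ``s = 0`` is a
    tie and violates the precondition; callers skip such pairings.
    """
    if s == 0:
        raise ValueError("s = 0 is a pairing tie; no scale is defined")
    if s > 0:
        return params.alpha_p * np.exp(-s / params.tau_p)
    return params.alpha_d * np.exp(s / params.tau_d)


def apply_update(w: float, scale: float, params: STDPParams) -> float:
    """Mixed additive/multiplicative weight update; result in [0, w_max]."""
    if not (0.0 <= w <= params.w_max):
        raise ValueError(f"weight {w} outside [0, {params.w_max}]")
    if scale > 0:
        return w + (params.w_max - w) * scale
    return max(0.0, w + params.w_max * scale)


@dataclass
class Pairing:
    """One STDP pairing event on a synapse."""

    synapse: int
    s: float
    scale: float


def pair_spikes(
    pre_emission_times: list[np.ndarray],
    post_spike_times: np.ndarray,
    delays: np.ndarray,
    params: STDPParams,
) -> list[Pairing]:
    """Enumerate nearest-neighbour STDP pairings for one post-synaptic cell.

    Parameters
    ----------
    pre_emission_times
        Per synapse, sorted spike *emission* times (ms) of its pre-synaptic
        cell.  Arrival times are ``emission + delays[k]``.
    post_spike_times
        Sorted spike times of the post-synaptic cell.
    delays
        Per-synapse conduction delay (ms, >= 0).

    Returns the pairings in chronological order of the event that triggered
    them (LTD at arrival, LTP at post spike).
    """
    post = np.asarray(post_spike_times, dtype=float)
    if np.any(np.diff(post) < 0):
        raise ValueError("post_spike_times must be sorted")
    delays = np.asarray(delays, dtype=float)
    if np.any(delays < 0):
        raise ValueError("delays must be non-negative")
    window = params.window_ms

    # Build a merged event stream: (time, kind, synapse) with kind 0 for
    # arrivals and 1 for post spikes; arrivals at equal time are processed
    # before the post spike they coincide with (the s = 0 tie then yields no
    # update but the arrival is consumed by the next post spike only if
    # still unused -- with s = 0 excluded it stays pending).
    events: list[tuple[float, int, int]] = []
    for k, times in enumerate(pre_emission_times):
        t = np.asarray(times, dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError("pre_emission_times must be sorted per synapse")
        for arr in t + delays[k]:
            events.append((float(arr), 0, k))
    for tp in post:
        events.append((float(tp), 1, -1))
    events.sort(key=lambda e: (e[0], e[1]))

    n_syn = len(pre_emission_times)
    pending_arrival = np.full(n_syn, -np.inf)  # time of unused arrival
    pending_used = np.ones(n_syn, dtype=bool)
    last_post = -np.inf
    out: list[Pairing] = []

    for t, kind, k in events:
        if kind == 0:  # pre-synaptic arrival at synapse k
            # first-spike-only: later spikes of the same burst are ignored
            if t - pending_arrival[k] < params.burst_ms:
                continue
            pending_arrival[k] = t
            pending_used[k] = False
            s = last_post - t  # <= 0: LTD (or tie)
            if s < 0 and -s <= window:
                out.append(Pairing(k, s, stdp_scale(s, params)))
        else:  # post-synaptic spike
            for j in np.nonzero(~pending_used)[0]:
                s = t - pending_arrival[j]
                if s == 0:
                    continue  # tie: no update, arrival stays pending
                if s > window:
                    pending_used[j] = True  # expired
                    continue
                out.append(Pairing(int(j), s, stdp_scale(s, params)))
                pending_used[j] = True
            last_post = t
    return out
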