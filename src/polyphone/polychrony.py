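"""Polychronization index (PI): reproducible spatio-temporal firing.

A polychronous group is a set of cells that fire in a reproducible,
time-locked but non-synchronous pattern.  Exhaustively enumerating such
groups is intractable, so the PI summarises, per reference cell ``j``,
how reproducible the firing *around* ``j``'s spikes is across repeated
presentations of a stimulus class:

1. for each presentation (exemplar) in which ``j`` fires, sample one of
   ``j``'s spikes uniformly and collect a (layer size x 101) matrix of
   the other cells' spike counts in 1 ms bins over the +/- 50 ms window
   around it (the window matches the maximum conduction delay);
2. average the matrices over the exemplars of a class, exclude the
   centre element (cell ``j`` at lag 0), and take the mean of the ten
   largest elements;
3. normalise by the layer's mean firing statistic ``f`` (mean spike
   count per cell per 1 ms bin, pooled over the analysed
   presentations), and maximise over stimulus classes.

A PI near 1 is the chance level of structureless (Poisson) firing for a
large number of exemplars; values well above 1 indicate cells embedded
in reproducible firing patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import SpikeRaster

WINDOW_HALF_MS = 50
N_LAGS = 2 * WINDOW_HALF_MS + 1  # 101 bins at 1 ms
N_TOP = 10


def pattern_matrix(
    events: pd.DataFrame,
    cell_j: int,
    layer_size: int,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Windowed co-firing matrix around one sampled spike of ``cell_j``.

    ``events`` holds one presentation's events for one layer (columns
    ``neuron`` and ``time_ms``).  Returns a (layer_size, 101) count
    matrix, or None when the reference cell is silent (skip contract).
    Window bins that fall outside the presentation stay zero-padded.
    """
    times = events["time_ms"].to_numpy(dtype=float)
    neurons = events["neuron"].to_numpy(dtype=np.int64)
    own = times[neurons == cell_j]
    if own.size == 0:
        return None
    t_j = float(own[rng.integers(own.size)])
    lag = np.rint(times - t_j).astype(np.int64)
    sel = np.abs(lag) <= WINDOW_HALF_MS
    M = np.zeros((layer_size, N_LAGS))
    np.add.at(M, (neurons[sel], lag[sel] + WINDOW_HALF_MS), 1.0)
    # the sampled reference spike itself is not part of the pattern
    M[cell_j, WINDOW_HALF_MS] -= 1.0
    return M


def mean_firing_statistic(
    raster: SpikeRaster, layer: str, layer_size: int
) -> float:
    """Mean spike count per cell per 1 ms bin over all presentations."""
    n_events = len(raster.layer_events(layer))
    total_ms = raster.presentations["duration_ms"].sum()
    if total_ms <= 0 or layer_size <= 0:
        raise ValueError("empty presentation schedule")
    return n_events / (layer_size * total_ms)


def _top_elements(M: np.ndarray, cell_j: int, n_top: int) -> np.ndarray:
    """The ``n_top`` largest elements of M, centre element excluded.

    Ties break stably by (count desc, lag asc, cell asc); the ten
    elements are not constrained to lie on distinct cells.
    """
    M = M.copy()
    M[cell_j, WINDOW_HALF_MS] = -np.inf
    cells, lags = np.indices(M.shape)
    flat = M.ravel()
    order = np.lexsort((cells.ravel(), lags.ravel(), -flat))
    return flat[order[:n_top]]


@dataclass
class PIResult:
    """Per-cell polychronization index and its class-wise components."""

    cell: int
    a_s: dict[int, float]  # per stimulus class
    pi: float
    f: float
    skipped: dict[int, int]  # exemplars where the cell was silent
    top_elements: dict[int, np.ndarray] = field(default_factory=dict)


def polychronization_index(
    raster: SpikeRaster,
    layer: str,
    cell_j: int,
    layer_size: int,
    seed: int | np.random.Generator = 0,
    n_top: int = N_TOP,
) -> PIResult:
    """PI of one cell: max over classes of the normalised top-element mean."""
    rng = np.random.default_rng(seed)
    f = mean_firing_statistic(raster, layer, layer_size)
    lev = raster.layer_events(layer)
    by_pid = dict(tuple(lev.groupby("presentation_id")))
    empty = lev.iloc[0:0]

    a_s: dict[int, float] = {}
    skipped: dict[int, int] = {}
    tops: dict[int, np.ndarray] = {}
    classes = sorted(raster.presentations["stimulus_class"].unique())
    for s in classes:
        pids = raster.presentations.loc[
            raster.presentations["stimulus_class"] == s, "presentation_id"
        ]
        acc = np.zeros((layer_size, N_LAGS))
        used = 0
        skip = 0
        for pid in pids:
            M = pattern_matrix(by_pid.get(pid, empty), cell_j, layer_size, rng)
            if M is None:
                skip += 1
                continue
            acc += M
            used += 1
        skipped[int(s)] = skip
        if used == 0:
            continue
        M_s = acc / used
        top = _top_elements(M_s, cell_j, n_top)
        tops[int(s)] = top
        a_s[int(s)] = float(top.mean() / f)
    if not a_s:
        raise ValueError(
            f"cell {cell_j} silent in every exemplar of every class"
        )
    return PIResult(
        cell=cell_j,
        a_s=a_s,
        pi=max(a_s.values()),
        f=f,
        skipped=skipped,
        top_elements=tops,
    )


def layer_pi(
    raster: SpikeRaster,
    layer: str,
    layer_size: int,
    cells: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """PI table for a set of cells (default: the whole layer).

    Cells that never fire are reported with NaN rather than raising.
    """
    rng = np.random.default_rng(seed)
    if cells is None:
        cells = np.arange(layer_size)
    rows = []
    for c in cells:
        try:
            res = polychronization_index(raster, layer, int(c), layer_size, rng)
            rows.append({"cell": int(c), "pi": res.pi, "f": res.f})
        except ValueError:
            rows.append({"cell": int(c), "pi": np.nan, "f": np.nan})
    return pd.DataFrame(rows)
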