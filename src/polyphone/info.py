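"""Temporal vs rate decoding of spike rasters via MLP ensembles.

How much does a layer's activity tell us about which of two stimulus
classes was presented?  Two read-outs are compared:

* **temporal code** -- for each of ``J = 100`` randomly sampled
  reference cells, every presentation is summarised by the windowed
  co-firing matrix (100 sampled cells x 101 lags, as in the
  polychronization index) around one sampled spike of the reference
  cell, compressed to a 201-element vector of row sums (100) and column
  sums (101).  One small MLP per reference cell (a single hidden layer
  of 20 tanh units, ~10% of the input size to limit capacity, trained
  to convergence on a cross-entropy objective) classifies the vectors,
  and the ensemble prediction for a presentation is the majority vote
  over the 100 decoders;
* **rate code** -- a single MLP of the same shape classifies the
  201-element vector of mean firing rates of 201 sampled cells,
  discarding all spike timing.

Decoder predictions on held-out presentations fill a 2 x 2 joint
probability table from which the mutual information I(S;R) is computed,
with the analytic positive-bias term #bins / (2 N ln 2) reported
alongside.  With two equiprobable classes the ceiling is H(S) = 1 bit.
The whole procedure is repeated over independent cell subsamples to
yield a distribution of estimates.

The decoder is an measurement instrument, not a model of a brain
mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier

from .polychrony import N_LAGS, WINDOW_HALF_MS
from .raster import SpikeRaster

J_TEMPORAL = 100  # reference cells / decoders in temporal mode
J_RATE = 201  # sampled cells in rate mode (matches feature length)
N_HIDDEN = 20


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def temporal_features(
    events: pd.DataFrame,
    cell_j: int,
    sampled_cells: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """201-element row/column-sum vector of the subsampled window matrix.

    ``events`` is one presentation of one layer.  The matrix is built
    over ``sampled_cells`` (length 100) around one uniformly sampled
    spike of ``cell_j``; returns None when the reference cell is silent
    (the decoder abstains for this presentation).
    """
    sampled_cells = np.asarray(sampled_cells)
    times = events["time_ms"].to_numpy()
    neurons = events["neuron"].to_numpy()
    own = times[neurons == cell_j]
    if own.size == 0:
        return None
    t_j = float(own[rng.integers(own.size)])
    pos = {int(c): i for i, c in enumerate(sampled_cells)}
    keep = np.isin(neurons, sampled_cells)
    lag = np.rint(times[keep] - t_j).astype(np.int64)
    sub_neurons = neurons[keep]
    sel = np.abs(lag) <= WINDOW_HALF_MS
    M = np.zeros((sampled_cells.size, N_LAGS))
    rows = np.fromiter((pos[int(n)] for n in sub_neurons[sel]), dtype=np.int64,
                       count=int(sel.sum()))
    np.add.at(M, (rows, lag[sel] + WINDOW_HALF_MS), 1.0)
    return np.concatenate([M.sum(axis=1), M.sum(axis=0)])


def rate_features(
    events: pd.DataFrame,
    sampled_cells: np.ndarray,
    duration_ms: float,
) -> np.ndarray:
    """Mean firing rate (Hz) of each sampled cell over the presentation."""
    sampled_cells = np.asarray(sampled_cells)
    counts = (
        events.groupby("neuron").size().reindex(sampled_cells, fill_value=0)
    )
    return counts.to_numpy() / (duration_ms / 1000.0)


# ---------------------------------------------------------------------------
# Decoders
# ---------------------------------------------------------------------------


def _make_mlp(seed: int) -> MLPClassifier:
    # lbfgs is a convergent quasi-Newton method on the cross-entropy
    # objective; fast and deterministic on these small problems.
    return MLPClassifier(
        hidden_layer_sizes=(N_HIDDEN,),
        activation="tanh",
        solver="lbfgs",
        max_iter=1000,
        tol=1e-6,
        random_state=seed,
    )


def fit_decoders(
    feature_sets: list[tuple[np.ndarray, np.ndarray]],
    seed: int | np.random.Generator = 0,
) -> list[MLPClassifier]:
    """Fit one MLP per reference-cell feature set (X, y).

    Raises on degenerate single-class training labels.
    """
    rng = np.random.default_rng(seed)
    decoders = []
    for X, y in feature_sets:
        if np.unique(y).size < 2:
            raise ValueError("degenerate single-class training labels")
        clf = _make_mlp(int(rng.integers(2**31 - 1)))
        clf.fit(X, y)
        decoders.append(clf)
    return decoders


def majority_vote(votes: np.ndarray) -> int:
    """Majority over per-decoder votes; NaN marks an abstention.

    Ties (and the all-abstain case) resolve to the lowest class index.
    """
    votes = np.asarray(votes, dtype=float)
    votes = votes[~np.isnan(votes)]
    if votes.size == 0:
        return 0
    classes, counts = np.unique(votes.astype(int), return_counts=True)
    return int(classes[np.argmax(counts)])  # first maximum = lowest class


# ---------------------------------------------------------------------------
# Confusion matrix and mutual information
# ---------------------------------------------------------------------------


def confusion_joint(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Joint probability table p(predicted r, actual s).

    Entry (r, s) = #{predict r among presentations of class s} /
    (#presentations of class s * number of classes), so each actual
    class carries an equal prior regardless of presentation counts.
    """
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    classes = np.unique(y_true)
    n = classes.size
    joint = np.zeros((n, n))
    for ci, s in enumerate(classes):
        m = y_true == s
        tot = m.sum()
        for ri, r in enumerate(classes):
            joint[ri, ci] = np.sum(y_pred[m] == r) / (tot * n)
    return joint


@dataclass
class InfoEstimate:
    """Mutual information in bits, with its ceiling and bias term."""

    mi_bits: float
    h_s_bits: float
    bias_bits: float
    n_trials: int
    n_bins: int

    def __post_init__(self) -> None:
        if self.mi_bits < -1e-12 or self.mi_bits > self.h_s_bits + 1e-9:
            raise ValueError("mutual information outside [0, H(S)]")


def information_bias(n_bins: int, n_trials: int) -> float:
    """Positive plug-in estimator bias, #bins / (2 N ln 2), in bits."""
    return n_bins / (2.0 * n_trials * np.log(2.0))


def mutual_information(
    joint: np.ndarray, n_trials: int | None = None
) -> InfoEstimate:
    """I(S;R) in bits from a joint probability table (0 log 0 = 0)."""
    joint = np.asarray(joint, dtype=float)
    if (joint < 0).any():
        raise ValueError("joint table has negative entries")
    total = joint.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError("joint table does not sum to 1")
    p_r = joint.sum(axis=1)  # response marginal
    p_s = joint.sum(axis=0)  # stimulus marginal
    nz = joint > 0
    ratio = joint[nz] / np.outer(p_r, p_s)[nz]
    mi = float(np.sum(joint[nz] * np.log2(ratio)))
    h_s = float(-np.sum(p_s[p_s > 0] * np.log2(p_s[p_s > 0])))
    n_bins = joint.size
    n = int(n_trials) if n_trials is not None else 0
    bias = information_bias(n_bins, n) if n else float("nan")
    return InfoEstimate(
        mi_bits=max(mi, 0.0),
        h_s_bits=h_s,
        bias_bits=bias,
        n_trials=n,
        n_bins=n_bins,
    )


# ---------------------------------------------------------------------------
# End-to-end evaluation protocol
# ---------------------------------------------------------------------------


def _stratified_split(
    labels: np.ndarray, rng: np.random.Generator, train_frac: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Presentation-level stratified split; returns (train idx, test idx)."""
    train, test = [], []
    for s in np.unique(labels):
        idx = np.flatnonzero(labels == s)
        idx = rng.permutation(idx)
        k = max(1, int(round(train_frac * idx.size)))
        k = min(k, idx.size - 1)
        train.append(idx[:k])
        test.append(idx[k:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def evaluate_layer(
    raster: SpikeRaster,
    layer: str,
    layer_size: int,
    mode: str,
    n_subsamples: int = 20,
    j_cells: int | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Distribution of MI estimates for one layer and encoding mode.

    Each repetition draws a fresh random cell subsample and a fresh
    stratified 50/50 train/test split of the presentations; decoders are
    trained on the train half and the confusion table is filled from
    their (majority-vote) predictions on the held-out half.
    """
    if mode not in ("temporal", "rate"):
        raise ValueError("mode must be 'temporal' or 'rate'")
    rng = np.random.default_rng(seed)
    J = j_cells if j_cells is not None else (
        J_TEMPORAL if mode == "temporal" else J_RATE
    )
    pres = raster.presentations
    pids = pres["presentation_id"].to_numpy()
    labels = pres["stimulus_class"].to_numpy()
    durations = pres["duration_ms"].to_numpy()
    lev = raster.layer_events(layer)
    by_pid = dict(tuple(lev.groupby("presentation_id")))
    empty = lev.iloc[0:0]

    rows = []
    for rep in range(n_subsamples):
        cells = rng.choice(layer_size, size=min(J, layer_size), replace=False)
        tr, te = _stratified_split(labels, rng)
        if mode == "rate":
            X = np.stack(
                [
                    rate_features(by_pid.get(p, empty), cells, d)
                    for p, d in zip(pids, durations)
                ]
            )
            clf = _make_mlp(int(rng.integers(2**31 - 1)))
            clf.fit(X[tr], labels[tr])
            y_pred = clf.predict(X[te])
        else:
            # pre-extract the sampled cells' events once per presentation;
            # every reference cell then bins from the same arrays
            sub: dict[int, tuple[np.ndarray, np.ndarray]] = {}
            pos = np.full(layer_size, -1, dtype=np.int64)
            pos[cells] = np.arange(cells.size)
            for p in pids:
                ev = by_pid.get(p, empty)
                n = ev["neuron"].to_numpy(dtype=np.int64)
                t = ev["time_ms"].to_numpy(dtype=float)
                keep = pos[n] >= 0
                sub[p] = (pos[n[keep]], t[keep])

            def fast_features(p: int, cell_pos: int) -> np.ndarray | None:
                rows, times = sub[p]
                own = times[rows == cell_pos]
                if own.size == 0:
                    return None
                t_j = float(own[rng.integers(own.size)])
                lag = np.rint(times - t_j).astype(np.int64)
                keep = np.abs(lag) <= WINDOW_HALF_MS
                M = np.zeros((cells.size, N_LAGS))
                np.add.at(M, (rows[keep], lag[keep] + WINDOW_HALF_MS), 1.0)
                return np.concatenate([M.sum(axis=1), M.sum(axis=0)])

            votes = np.full((te.size, cells.size), np.nan)
            for ci, cell in enumerate(cells):
                feats = [fast_features(p, ci) for p in pids]
                tr_ok = [i for i in tr if feats[i] is not None]
                if not tr_ok:
                    continue
                y_tr = labels[tr_ok]
                if np.unique(y_tr).size < 2:
                    continue  # degenerate training set: decoder abstains
                clf = _make_mlp(int(rng.integers(2**31 - 1)))
                clf.fit(np.stack([feats[i] for i in tr_ok]), y_tr)
                te_ok = [k for k, i in enumerate(te) if feats[i] is not None]
                if te_ok:
                    Xte = np.stack([feats[te[k]] for k in te_ok])
                    votes[te_ok, ci] = clf.predict(Xte)
            y_pred = np.array([majority_vote(v) for v in votes])
        joint = confusion_joint(labels[te], y_pred)
        est = mutual_information(joint, n_trials=te.size)
        rows.append(
            {
                "layer": layer,
                "mode": mode,
                "subsample": rep,
                "mi_bits": est.mi_bits,
                "h_s_bits": est.h_s_bits,
                "bias_bits": est.bias_bits,
                "n_test": te.size,
            }
        )
    return pd.DataFrame(rows)


def evaluate_model(
    rasters: SpikeRaster,
    layer_sizes: dict[str, int],
    modes: tuple[str, ...] = ("temporal", "rate"),
    layers: list[str] | None = None,
    n_subsamples: int = 20,
    j_cells: int | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """MI distributions per layer and mode (held-out presentations)."""
    rng = np.random.default_rng(seed)
    layers = layers if layers is not None else sorted(layer_sizes)
    frames = []
    for layer in layers:
        for mode in modes:
            frames.append(
                evaluate_layer(
                    rasters,
                    layer,
                    layer_sizes[layer],
                    mode,
                    n_subsamples=n_subsamples,
                    j_cells=j_cells,
                    seed=rng,
                )
            )
    return pd.concat(frames, ignore_index=True)
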