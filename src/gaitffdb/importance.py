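"""Reverse-synapse-weight feature impact (the model sanity check).

Each input feature receives a signed score by propagating weights backwards
through the trained network: the output neuron starts at 1, and every neuron
in an earlier layer receives the width-averaged weighted sum of its outgoing
synapses' scores. Biases and activations are ignored — the score reflects
pure synapse weights — and signs are kept, so features can carry negative
impact. For a network with all-linear activations the score vector is
exactly the input gradient scaled by the product of 1/width over the
non-input layers.

Averaging the per-model scores over an ensemble of equally configured
trained models (one per repeated experiment) smooths initialization noise;
the ranked table with its top/bottom excerpt is the human-facing check that
the model attends to plausible features (cadence, speed, stride length)
rather than noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

__all__ = ["reverse_weights", "rsw_table", "top_bottom_report"]


def _layers_of(model) -> list[tuple[np.ndarray, np.ndarray]]:
    layers = model.layers_ if hasattr(model, "layers_") else model
    if not layers:
        raise DataError("model has no weight layers")
    for i, (W, _) in enumerate(layers[:-1]):
        W_next = layers[i + 1][0]
        if W.shape[1] != W_next.shape[0]:
            raise DataError(
                f"weight shapes do not chain: layer {i} ends in {W.shape[1]} "
                f"neurons, layer {i + 1} starts with {W_next.shape[0]}"
            )
    return layers


def reverse_weights(model) -> np.ndarray:
    """Per-input-feature signed reverse weight of one trained model.

    Accepts a fitted :class:`~gaitffdb.network.DistanceMLPRegressor` or a raw
    ordered list of ``(W, b)`` pairs. Backward recursion: the output neuron
    has score 1; a neuron's score is the mean over the next layer's width of
    ``W[i, j] * score_j``. Returns the input-layer vector, unnormalized.
    """
    layers = _layers_of(model)
    score = np.ones(1, dtype=np.float64)
    for W, _ in reversed(layers):
        score = (W.astype(np.float64) @ score) / W.shape[1]
    return score


def rsw_table(models, feature_names) -> pd.DataFrame:
    """Ensemble-averaged reverse weights, ranked descending.

    Returns a DataFrame with columns ``feature``, ``reverse_weight`` and
    ``rank`` (1 = largest signed weight), one row per input feature.
    """
    models = list(models)
    if not models:
        raise ConfigurationError("need at least one model to build a reverse-weight table")
    feature_names = list(feature_names)
    scores = []
    for model in models:
        rw = reverse_weights(model)
        if rw.size != len(feature_names):
            raise ConfigurationError(
                f"model has {rw.size} inputs but {len(feature_names)} feature names given"
            )
        scores.append(rw)
    mean_rw = np.mean(scores, axis=0)
    table = pd.DataFrame({"feature": feature_names, "reverse_weight": mean_rw})
    table = table.sort_values("reverse_weight", ascending=False, kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)


def top_bottom_report(table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """The k largest and k smallest reverse weights, in rank order.

    The returned frame carries a ``group`` column ("top" / "bottom") and the
    original ``feature``/``reverse_weight``/``rank`` columns.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if len(table) < 2 * k:
        raise ConfigurationError(
            f"need at least {2 * k} features for a top/bottom-{k} report, have {len(table)}"
        )
    ranked = table.sort_values("rank", kind="stable")
    top = ranked.head(k).assign(group="top")
    bottom = ranked.tail(k).assign(group="bottom")
    return pd.concat([top, bottom], ignore_index=True)
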