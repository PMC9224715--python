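"""Deep feed-forward regressor with parameterized shape, in numpy.

The architecture is fixed by two shape parameters: every hidden layer has
width ``round(spread * input_dim)`` (ReLU activation) and there are ``depth``
hidden layers, followed by a single linear output neuron that predicts the
walking distance in meters. Weights are Glorot-uniform initialized from the
seed, training minimizes mean squared error with seed-controlled mini-batch
shuffling, and all parameters are float32.

The trained weight stack is exposed as ``layers_``: an ordered list of
``(W, b)`` pairs from input to output, with ``W[i, j]`` the synapse weight
from source neuron ``i`` to destination neuron ``j``. The reverse-weight
sanity check depends on exactly this convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from ._optim import ALGORITHMS, canonical_algorithm, make_optimizer
from .exceptions import ConfigurationError

__all__ = ["DistanceMLPRegressor", "hidden_width", "initialize_layers", "forward", "ALGORITHMS"]


def hidden_width(spread: float, input_dim: int) -> int:
    """Hidden-layer width: round-half-away-from-zero of spread * input_dim."""
    width = int(np.floor(spread * input_dim + 0.5))
    if width < 1:
        raise ConfigurationError(
            f"spread {spread} with {input_dim} inputs gives hidden width {width} < 1"
        )
    return width


def initialize_layers(input_dim: int, width: int, depth: int, seed: int | None
                      ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Glorot-uniform weight matrices and zero biases, reproducible from seed."""
    rng = np.random.default_rng(seed)
    dims = [input_dim] + [width] * depth + [1]
    layers = []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        W = rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)
        layers.append((W, np.zeros(fan_out, dtype=np.float32)))
    return layers


def forward(layers: list[tuple[np.ndarray, np.ndarray]], X: np.ndarray) -> np.ndarray:
    """Forward pass (ReLU hidden, linear output); returns shape (n,) meters."""
    a = X
    last = len(layers) - 1
    for i, (W, b) in enumerate(layers):
        a = a @ W + b
        if i < last:
            np.maximum(a, 0.0, out=a)
    return a[:, 0]


class DistanceMLPRegressor(RegressorMixin, BaseEstimator):
    """Feed-forward walking-distance regressor.

    Parameters
    ----------
    spread : float, default 3.0
        Hidden width factor relative to the input dimension.
    depth : int, default 3
        Number of hidden layers.
    algorithm : str, default "Adam"
        One of SGD, RMSProp, Adam, Adadelta, Adagrad, Adamax, Nadam
        (case-insensitive).
    learning_rate : float, default 1e-3
    n_epoch : int, default 100
        Training epochs; 0 leaves the Glorot initialization untouched.
    batch_size : int, default 32
    random_state : int or None
        Seeds both the weight initialization and the per-epoch shuffling.

    Attributes
    ----------
    layers_ : ordered ``(W, b)`` pairs, input to output.
    loss_history_ : mean training MSE per completed epoch.
    failed_ : True when training produced non-finite loss or weights; the
        benchmark scores such runs through its failed-run policy instead of
        raising.
    """

    def __init__(self, spread: float = 3.0, depth: int = 3, algorithm: str = "Adam",
                 learning_rate: float = 1e-3, n_epoch: int = 100, batch_size: int = 32,
                 random_state: int | None = None):
        self.spread = spread
        self.depth = depth
        self.algorithm = algorithm
        self.learning_rate = learning_rate
        self.n_epoch = n_epoch
        self.batch_size = batch_size
        self.random_state = random_state

    def fit(self, X, y) -> "DistanceMLPRegressor":
        X, y = self._validate(X, y)
        if self.depth < 1 or int(self.depth) != self.depth:
            raise ConfigurationError(f"depth must be a positive integer, got {self.depth}")
        if self.n_epoch < 0:
            raise ConfigurationError(f"n_epoch must be >= 0, got {self.n_epoch}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")
        algorithm = canonical_algorithm(self.algorithm)

        n, d = X.shape
        self.n_features_in_ = d
        width = hidden_width(self.spread, d)
        seeds = np.random.SeedSequence(
            self.random_state if self.random_state is not None else None
        ).spawn(2)
        init = initialize_layers(d, width, int(self.depth), seeds[0])
        shuffler = np.random.default_rng(seeds[1])
        opt = make_optimizer(algorithm, self.learning_rate)

        # all parameters in one contiguous vector; layers are views into it
        flat = np.concatenate([t.ravel() for pair in init for t in pair])
        gflat = np.zeros_like(flat)
        layers, gviews, pos = [], [], 0
        for W, b in init:
            Wv = flat[pos:pos + W.size].reshape(W.shape)
            gW = gflat[pos:pos + W.size].reshape(W.shape)
            pos += W.size
            bv = flat[pos:pos + b.size]
            gb = gflat[pos:pos + b.size]
            pos += b.size
            layers.append((Wv, bv))
            gviews.append((gW, gb))

        self.loss_history_ = []
        self.failed_ = False
        sq_err = np.empty(n)  # per-sample squared errors, summed in fixed order
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            for _ in range(int(self.n_epoch)):
                order = shuffler.permutation(n)
                for start in range(0, n, self.batch_size):
                    idx = order[start:start + self.batch_size]
                    sq_err[idx] = self._train_batch(layers, gviews, X[idx], y[idx])
                    opt.step(flat, gflat)
                epoch_loss = sq_err.sum() / n
                self.loss_history_.append(float(epoch_loss))
                if not np.isfinite(epoch_loss):
                    self.failed_ = True
                    break
        if not self.failed_ and not np.isfinite(flat).all():
            self.failed_ = True
        self.layers_ = layers
        return self

    @staticmethod
    def _train_batch(layers, gviews, Xb, yb) -> np.ndarray:
        """Forward/backward for one batch, gradients written into the flat
        buffer's views; returns the batch's per-sample squared errors."""
        activations = [Xb]
        a = Xb
        last = len(layers) - 1
        for i, (W, b) in enumerate(layers):
            a = a @ W + b
            if i < last:
                np.maximum(a, 0.0, out=a)
            activations.append(a)
        residual = activations[-1][:, 0] - yb
        m = len(yb)
        delta = (np.float32(2.0 / m) * residual)[:, None]
        for i in range(last, -1, -1):
            W, _ = layers[i]
            gW, gb = gviews[i]
            delta.sum(axis=0, out=gb)
            np.matmul(activations[i].T, delta, out=gW)
            if i > 0:
                delta = (delta @ W.T) * (activations[i] > 0)
        return np.square(residual, dtype=np.float64)

    def predict(self, X) -> np.ndarray:
        X = self._as_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ConfigurationError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return forward(self.layers_, X).astype(np.float64)

    def _validate(self, X, y) -> tuple[np.ndarray, np.ndarray]:
        X = self._as_matrix(X)
        y = np.asarray(y, dtype=np.float32).ravel()
        if len(y) != len(X):
            raise ConfigurationError("X and y have different lengths")
        return X, y

    @staticmethod
    def _as_matrix(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2:
            raise ConfigurationError(f"expected a 2-D feature matrix, got shape {X.shape}")
        return X
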