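"""First-order optimizer update rules for the numpy feed-forward regressor.

Seven classic stochastic-gradient methods, each with the hyperparameter
defaults popularized by the mainstream deep-learning frameworks; only the
learning rate is exposed, since the benchmark tunes nothing else.

All network parameters live in one contiguous float32 vector and each
optimizer keeps its state (moment accumulators) as flat vectors of the same
length, updating in place through preallocated scratch buffers — one big
vectorized update per step instead of many small per-tensor ones.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigurationError

EPS = np.float32(1e-7)


class _Optimizer:
    """Base: flat-vector state allocated lazily on the first step."""

    n_slots = 0

    def __init__(self, learning_rate: float):
        if learning_rate < 0:
            raise ConfigurationError(f"learning rate must be >= 0, got {learning_rate}")
        self.lr = np.float32(learning_rate)
        self.t = 0
        self._ready = False

    def _prepare(self, n: int) -> None:
        self.slots = [np.zeros(n, dtype=np.float32) for _ in range(self.n_slots)]
        self.buf = np.empty(n, dtype=np.float32)
        self.buf2 = np.empty(n, dtype=np.float32)
        self._ready = True

    def step(self, params: np.ndarray, grads: np.ndarray) -> None:
        """One in-place update of the flat parameter vector."""
        if not self._ready:
            self._prepare(params.size)
        self.t += 1
        self._update(params, grads)
        if self.t % 100 == 0:
            # geometric moment decay of dead units drifts into float32
            # denormals, which stall the CPU; flush them to exact zero
            for s in self.slots:
                np.copyto(s, np.float32(0), where=np.abs(s) < np.float32(1e-30))

    def _update(self, p: np.ndarray, g: np.ndarray) -> None:
        raise NotImplementedError


class SGD(_Optimizer):
    def _update(self, p, g):
        np.multiply(g, self.lr, out=self.buf)
        p -= self.buf


class RMSProp(_Optimizer):
    n_slots = 1
    rho = np.float32(0.9)

    def _update(self, p, g):
        (a,) = self.slots
        a *= self.rho
        np.multiply(g, g, out=self.buf)
        self.buf *= np.float32(1) - self.rho
        a += self.buf
        np.sqrt(a, out=self.buf)
        self.buf += EPS
        np.divide(g, self.buf, out=self.buf)
        self.buf *= self.lr
        p -= self.buf


class Adagrad(_Optimizer):
    n_slots = 1
    initial_accumulator = np.float32(0.1)

    def _prepare(self, n):
        super()._prepare(n)
        self.slots[0].fill(self.initial_accumulator)

    def _update(self, p, g):
        (a,) = self.slots
        np.multiply(g, g, out=self.buf)
        a += self.buf
        np.add(a, EPS, out=self.buf)
        np.sqrt(self.buf, out=self.buf)
        np.divide(g, self.buf, out=self.buf)
        self.buf *= self.lr
        p -= self.buf


class Adadelta(_Optimizer):
    n_slots = 2
    rho = np.float32(0.95)

    def _update(self, p, g):
        acc_g, acc_dx = self.slots
        one = np.float32(1)
        acc_g *= self.rho
        np.multiply(g, g, out=self.buf)
        self.buf *= one - self.rho
        acc_g += self.buf
        np.add(acc_dx, EPS, out=self.buf)
        np.sqrt(self.buf, out=self.buf)
        np.add(acc_g, EPS, out=self.buf2)
        np.sqrt(self.buf2, out=self.buf2)
        self.buf /= self.buf2
        self.buf *= g                      # buf = dx
        acc_dx *= self.rho
        np.multiply(self.buf, self.buf, out=self.buf2)
        self.buf2 *= one - self.rho
        acc_dx += self.buf2
        self.buf *= self.lr
        p -= self.buf


class Adam(_Optimizer):
    n_slots = 2
    beta1 = np.float32(0.9)
    beta2 = np.float32(0.999)

    def _update(self, p, g):
        m, v = self.slots
        one = np.float32(1)
        m *= self.beta1
        np.multiply(g, one - self.beta1, out=self.buf)
        m += self.buf
        v *= self.beta2
        np.multiply(g, g, out=self.buf)
        self.buf *= one - self.beta2
        v += self.buf
        np.sqrt(v, out=self.buf)
        self.buf /= np.sqrt(one - self.beta2**self.t)
        self.buf += EPS
        np.divide(m, self.buf, out=self.buf)
        self.buf *= self.lr / (one - self.beta1**self.t)
        p -= self.buf


class Adamax(_Optimizer):
    n_slots = 2
    beta1 = np.float32(0.9)
    beta2 = np.float32(0.999)

    def _update(self, p, g):
        m, u = self.slots
        one = np.float32(1)
        m *= self.beta1
        np.multiply(g, one - self.beta1, out=self.buf)
        m += self.buf
        np.abs(g, out=self.buf)
        u *= self.beta2
        np.maximum(u, self.buf, out=u)
        np.add(u, EPS, out=self.buf)
        np.divide(m, self.buf, out=self.buf)
        self.buf *= self.lr / (one - self.beta1**self.t)
        p -= self.buf


class Nadam(_Optimizer):
    """Adam with Nesterov momentum (Dozat's formulation, fixed momentum)."""

    n_slots = 2
    beta1 = np.float32(0.9)
    beta2 = np.float32(0.999)

    def _update(self, p, g):
        m, v = self.slots
        one = np.float32(1)
        m *= self.beta1
        np.multiply(g, one - self.beta1, out=self.buf)
        m += self.buf
        v *= self.beta2
        np.multiply(g, g, out=self.buf)
        self.buf *= one - self.beta2
        v += self.buf
        # numerator: beta1 * m_hat(t+1) + (1 - beta1) * g_hat(t)
        np.multiply(m, self.beta1 / (one - self.beta1 ** (self.t + 1)), out=self.buf)
        np.multiply(g, (one - self.beta1) / (one - self.beta1**self.t), out=self.buf2)
        self.buf += self.buf2
        np.sqrt(v, out=self.buf2)
        self.buf2 /= np.sqrt(one - self.beta2**self.t)
        self.buf2 += EPS
        self.buf /= self.buf2
        self.buf *= self.lr
        p -= self.buf


OPTIMIZERS: dict[str, type[_Optimizer]] = {
    "SGD": SGD,
    "RMSProp": RMSProp,
    "Adam": Adam,
    "Adadelta": Adadelta,
    "Adagrad": Adagrad,
    "Adamax": Adamax,
    "Nadam": Nadam,
}

ALGORITHMS: tuple[str, ...] = tuple(OPTIMIZERS)
_CANONICAL = {name.lower(): name for name in OPTIMIZERS}


def canonical_algorithm(name: str) -> str:
    """Resolve a case-insensitive algorithm name to its canonical spelling."""
    try:
        return _CANONICAL[str(name).lower()]
    except KeyError:
        raise ConfigurationError(
            f"unknown training algorithm {name!r}; choose one of {ALGORITHMS}"
        ) from None


def make_optimizer(name: str, learning_rate: float) -> _Optimizer:
    return OPTIMIZERS[canonical_algorithm(name)](learning_rate)
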