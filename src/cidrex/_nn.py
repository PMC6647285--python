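"""Small numerical building blocks shared by the two neural models.

Everything runs in float64 NumPy on one thread; determinism is governed solely
by the RNG seeds handed to the estimators.
"""

from __future__ import annotations

import numpy as np

LOG_FLOOR = 1e-12  # floor inside log() of the objective


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    """Shift-invariant softmax over the last axis."""
    z = x - np.max(x, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


def l2_norm_sq(params: dict[str, np.ndarray]) -> float:
    return float(sum(np.sum(v * v) for v in params.values()))


def zeros_like_params(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in params.items()}


def uniform_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Glorot-style uniform initialization for weight matrices and tables."""
    fan = sum(shape) if len(shape) > 1 else shape[0]
    bound = np.sqrt(6.0 / max(fan, 1))
    return rng.uniform(-bound, bound, size=shape)


def dropout_mask(rng: np.random.Generator, size: int, rate: float) -> np.ndarray:
    """Inverted-dropout mask: zeros with probability ``rate``, else 1/(1-rate)."""
    if rate <= 0.0:
        return np.ones(size)
    keep = rng.random(size) >= rate
    return keep.astype(float) / (1.0 - rate)


class RMSProp:
    """Elementwise RMSprop over a dict of parameter arrays (in-place updates)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        learning_rate: float,
        rho: float = 0.9,
        eps: float = 1e-8,
    ) -> None:
        self.lr = learning_rate
        self.rho = rho
        self.eps = eps
        self.cache = zeros_like_params(params)

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            c = self.cache[k]
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            params[k] -= self.lr * g / (np.sqrt(c) + self.eps)
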