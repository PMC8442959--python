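"""Minimal fully connected network with RMSProp, written on numpy.

Rectifier activations, inverted dropout on the hidden layers (active only
during training; prediction is deterministic), He-style initialization.
The class exposes exactly what the patch regularizer needs: a cached
forward pass, backpropagation from an output gradient, and access to the
last hidden layer for embedding export.
"""

from __future__ import annotations

import copy
from typing import List, Optional, Sequence

import numpy as np

__all__ = ["MLP", "RMSProp"]


class MLP:
    def __init__(self, layer_sizes: Sequence[int], dropout_p: float = 0.0,
                 seed: int = 0, dtype=np.float32):
        if len(layer_sizes) < 2:
            raise ValueError("need at least input and output layer sizes")
        if not 0.0 <= dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        self.layer_sizes = [int(s) for s in layer_sizes]
        self.dropout_p = float(dropout_p)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.W: List[np.ndarray] = []
        self.b: List[np.ndarray] = []
        for fan_in, fan_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.W.append((rng.standard_normal((fan_in, fan_out)) * scale
                           ).astype(dtype))
            self.b.append(np.zeros(fan_out, dtype=dtype))

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def parameters(self) -> List[np.ndarray]:
        return self.W + self.b

    def copy_parameters(self) -> List[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_parameters(self, params: List[np.ndarray]) -> None:
        n = self.n_layers
        self.W = [p.copy() for p in params[:n]]
        self.b = [p.copy() for p in params[n:]]

    # ---- forward / backward ---------------------------------------------
    def forward(self, X: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None):
        """Return (output, cache).  Hidden layers: ReLU (+ dropout when
        training); output layer linear."""
        X = np.asarray(X, dtype=self.dtype)
        acts = [X]
        drops: List[Optional[np.ndarray]] = []
        h = X
        for li in range(self.n_layers - 1):
            z = h @ self.W[li] + self.b[li]
            h = np.maximum(z, 0.0)
            if training and self.dropout_p > 0.0:
                keep = (rng.random(h.shape) >= self.dropout_p).astype(self.dtype)
                h = h * keep / (1.0 - self.dropout_p)
                drops.append(keep)
            else:
                drops.append(None)
            acts.append(h)
        out = h @ self.W[-1] + self.b[-1]
        return out, (acts, drops)

    def backward(self, cache, grad_out: np.ndarray):
        """Backpropagate an output gradient; returns (dW, db) lists."""
        acts, drops = cache
        dW = [None] * self.n_layers
        db = [None] * self.n_layers
        g = np.asarray(grad_out, dtype=self.dtype)
        dW[-1] = acts[-1].T @ g
        db[-1] = g.sum(axis=0)
        g = g @ self.W[-1].T
        for li in range(self.n_layers - 2, -1, -1):
            h = acts[li + 1]
            if drops[li] is not None:
                g = g * drops[li] / (1.0 - self.dropout_p)
            g = g * (h > 0)
            dW[li] = acts[li].T @ g
            db[li] = g.sum(axis=0)
            if li > 0:
                g = g @ self.W[li].T
        return dW, db

    def predict(self, X: np.ndarray) -> np.ndarray:
        out, _ = self.forward(X, training=False)
        return out

    def hidden_activations(self, X: np.ndarray) -> np.ndarray:
        """Activations of the last hidden layer in evaluation mode."""
        _, (acts, _) = self.forward(X, training=False)
        return acts[-1]

    def clone(self) -> "MLP":
        other = copy.copy(self)
        other.W = [w.copy() for w in self.W]
        other.b = [b.copy() for b in self.b]
        return other


class RMSProp:
    """RMSProp with decay ``alpha`` (Hinton's running-average form)."""

    def __init__(self, params: List[np.ndarray], learning_rate: float = 1e-5,
                 alpha: float = 0.9, eps: float = 1e-8):
        self.learning_rate = float(learning_rate)
        self.alpha = float(alpha)
        self.eps = float(eps)
        self.cache = [np.zeros_like(p) for p in params]

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        for p, g, c in zip(params, grads, self.cache):
            c *= self.alpha
            c += (1.0 - self.alpha) * np.square(g)
            p -= self.learning_rate * g / (np.sqrt(c) + self.eps)
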