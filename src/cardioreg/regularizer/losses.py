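"""Training objectives for the patch regularization network.

Two objectives are provided:

* the supervised log-cosh loss — a smooth Huber-like penalty with L2
  behaviour for small residuals and L1 behaviour for large ones — between
  predicted and ground-truth patches;
* the biomechanical loss used for semi-supervised domain adaptation:
  squared-error data adherence to the noisy input plus an incompressibility
  term (squared L2 norm of the per-frame divergence, computed as the trace
  of the displacement gradient inside the patch) and a soft-periodicity term
  (squared L2 norm of the cyclic temporal derivative).

Both come with analytic gradients with respect to the prediction, used by
the numpy training loop.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

__all__ = ["logcosh", "logcosh_loss", "logcosh_grad",
           "biomech_loss", "biomech_grad", "patch_divergence"]

_LOG2 = float(np.log(2.0))


def logcosh(x: np.ndarray) -> np.ndarray:
    """Elementwise log cosh, overflow-safe: |x| + log(1 + e^{-2|x|}) - log 2."""
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - _LOG2


def logcosh_loss(pred: np.ndarray, true: np.ndarray) -> float:
    """(1/N) sum over patches of the elementwise log-cosh of the residual."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {true.shape}")
    n = pred.shape[0] if pred.ndim > 1 else 1
    return float(logcosh(true - pred).sum() / n)


def logcosh_grad(pred: np.ndarray, true: np.ndarray) -> np.ndarray:
    """d/d pred of logcosh_loss: tanh(pred - true) / N."""
    n = pred.shape[0] if pred.ndim > 1 else 1
    return np.tanh(pred - true) / n


# ---------------------------------------------------------------------------
# biomechanical loss
# ---------------------------------------------------------------------------

def _as_patches(x: np.ndarray, patch_shape: Sequence[int]) -> np.ndarray:
    x = np.asarray(x)
    return x.reshape((-1,) + tuple(patch_shape))


def patch_divergence(y: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Central-difference divergence inside patches.

    ``y``: (N, px, py, pz, T, 3).  Returns (N, px-2, py-2, pz-2, T) over the
    interior voxels (the patch boundary contributes no divergence term).
    """
    px, py, pz = y.shape[1:4]
    if min(px, py, pz) < 3:
        raise ValueError("patch spatial extent must be >= 3 for a divergence stencil")
    hx, hy, hz = (float(s) for s in spacing)
    div = (y[:, 2:, 1:-1, 1:-1, :, 0] - y[:, :-2, 1:-1, 1:-1, :, 0]) / (2 * hx)
    div = div + (y[:, 1:-1, 2:, 1:-1, :, 1] - y[:, 1:-1, :-2, 1:-1, :, 1]) / (2 * hy)
    div = div + (y[:, 1:-1, 1:-1, 2:, :, 2] - y[:, 1:-1, 1:-1, :-2, :, 2]) / (2 * hz)
    return div


def _divergence_adjoint(div: np.ndarray, shape: tuple,
                        spacing: Sequence[float]) -> np.ndarray:
    """Adjoint of patch_divergence applied to `div` (same layout)."""
    g = np.zeros(shape)
    hx, hy, hz = (float(s) for s in spacing)
    g[:, 2:, 1:-1, 1:-1, :, 0] += div / (2 * hx)
    g[:, :-2, 1:-1, 1:-1, :, 0] -= div / (2 * hx)
    g[:, 1:-1, 2:, 1:-1, :, 1] += div / (2 * hy)
    g[:, 1:-1, :-2, 1:-1, :, 1] -= div / (2 * hy)
    g[:, 1:-1, 1:-1, 2:, :, 2] += div / (2 * hz)
    g[:, 1:-1, 1:-1, :-2, :, 2] -= div / (2 * hz)
    return g


def biomech_loss(pred: np.ndarray, noise: np.ndarray,
                 lambda_div: float, lambda_loop: float,
                 patch_shape: Sequence[int], spacing: Sequence[float],
                 reduction: str = "sum") -> Tuple[float, dict]:
    """Biomechanically constrained objective over a batch of patches.

    total = sum_i { ||noise_i - pred_i||^2
                    + lambda_div * sum_t ||div pred_i(t)||^2
                    + lambda_loop * sum_t ||d pred_i / dt||^2 }

    The temporal derivative is a cyclic forward difference (soft periodicity).
    Returns ``(total, terms)`` with the unweighted data / div / loop terms.
    ``reduction="mean"`` divides by the number of patches.
    """
    if pred.shape != noise.shape:
        raise ValueError("pred and noise shapes differ")
    yp = _as_patches(pred, patch_shape)
    yn = _as_patches(noise, patch_shape)
    data = float(((yn - yp) ** 2).sum())
    div = patch_divergence(yp, spacing)
    div_term = float((div ** 2).sum())
    dt = np.roll(yp, -1, axis=4) - yp
    loop_term = float((dt ** 2).sum())
    total = data + lambda_div * div_term + lambda_loop * loop_term
    scale = 1.0 / len(yp) if reduction == "mean" else 1.0
    terms = {"data": data * scale, "div": div_term * scale,
             "loop": loop_term * scale}
    return total * scale, terms


def biomech_grad(pred: np.ndarray, noise: np.ndarray,
                 lambda_div: float, lambda_loop: float,
                 patch_shape: Sequence[int], spacing: Sequence[float],
                 reduction: str = "sum") -> np.ndarray:
    """Gradient of :func:`biomech_loss` with respect to ``pred`` (flattened)."""
    yp = _as_patches(pred, patch_shape)
    yn = _as_patches(noise, patch_shape)
    g = 2.0 * (yp - yn)
    if lambda_div != 0.0:
        div = patch_divergence(yp, spacing)
        g += 2.0 * lambda_div * _divergence_adjoint(div, yp.shape, spacing)
    if lambda_loop != 0.0:
        g += 2.0 * lambda_loop * (
            2.0 * yp - np.roll(yp, 1, axis=4) - np.roll(yp, -1, axis=4))
    if reduction == "mean":
        g = g / len(yp)
    return g.reshape(np.asarray(pred).shape)
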