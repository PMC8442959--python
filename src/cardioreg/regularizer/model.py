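"""Patch-based displacement regularization network: Model / Results objects.

:class:`DisplacementRegularizer` is built from patch data (noisy input
patches, optional ground-truth patches, optional unlabeled target-domain
patches) and a :class:`TrainConfig`; :meth:`DisplacementRegularizer.fit`
trains the MLP and returns a :class:`RegularizerResults` carrying the
fitted parameters, the loss history, diagnostics and a ``summary()`` table.
Prediction, whole-field regularization, hidden-layer embedding export and
plotting hang off the results object.

Three training regimes:

* **supervised** — log-cosh loss between predicted and ground-truth patches,
  with identity augmentation ((truth, truth) pairs) so the network does not
  bias low-error patches;
* **semi-supervised** — adds unlabeled target-domain patches trained with the
  biomechanical objective (data adherence + incompressibility + soft
  periodicity), the mechanism for domain adaptation; synthetic and target
  mini-batches alternate 1:1;
* **multi-view** — two complementary noisy inputs concatenated at the input
  layer, one regularized output.

Defaults follow the reference training protocol for echo-scale data
(RMSProp, initial learning rate 1e-5, 100 epochs, best-validation model
selection; 3 hidden layers x 1000 units, dropout 0.2 for supervised
training; 7 x 1000, dropout 0.5 for semi-supervised in vivo-style runs).
Patch values are standardized per displacement component by training-set
statistics stored with the model; losses are computed on the physical (mm)
scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from ..fields import DisplacementField4D
from ..patches import PatchSet, extract_patches, reconstruct_field, FLATTEN_ORDER
from .losses import logcosh_loss, logcosh_grad, biomech_loss, biomech_grad
from .mlp import MLP, RMSProp

__all__ = ["TrainConfig", "DisplacementRegularizer", "RegularizerResults",
           "LAMBDA_PRESETS", "train_supervised", "train_semisupervised",
           "regularize_field", "hidden_embedding"]

#: (lambda_div, lambda_loop) used per input tracking method
LAMBDA_PRESETS = {
    "rfbm_like": (0.5, 0.5),
    "fnt_like": (0.0, 1.0),
    "ffd_like": (0.5, 0.5),
}


@dataclass
class TrainConfig:
    hidden_layers: int = 3
    hidden_width: int = 1000
    dropout: float = 0.2
    learning_rate: float = 1e-5
    epochs: int = 100
    batch_size: int = 256
    lambda_super: float = 1.0
    lambda_div: float = 0.0
    lambda_loop: float = 0.0
    identity_augmentation: bool = True
    validation_fraction: float = 0.15
    rmsprop_alpha: float = 0.9
    standardize: bool = True
    #: final learning rate as a fraction of the initial one, interpolated
    #: exponentially over the epochs (1.0 = constant)
    lr_decay: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if min(self.lambda_super, self.lambda_div, self.lambda_loop) < 0:
            raise ValueError("lambda weights must be nonnegative")

    @classmethod
    def semisupervised_default(cls, preset: str = "rfbm_like",
                               **overrides) -> "TrainConfig":
        lam_div, lam_loop = LAMBDA_PRESETS[preset]
        kw = dict(hidden_layers=7, dropout=0.5, lambda_super=1.0,
                  lambda_div=lam_div, lambda_loop=lam_loop,
                  identity_augmentation=False)
        kw.update(overrides)
        return cls(**kw)


def _patch_data(p: Union[PatchSet, np.ndarray]) -> np.ndarray:
    return p.data if isinstance(p, PatchSet) else np.asarray(p)


class DisplacementRegularizer:
    """MLP regularization model over flattened 4D displacement patches.

    Parameters
    ----------
    noise_patches : PatchSet or (N, D) array
        Noisy source-domain input patches (paired with ``true_patches``).
    true_patches : PatchSet or (N, D) array, optional
        Ground-truth patches; required for the supervised term.
    target_patches : PatchSet or (N, D) array, optional
        Unlabeled target-domain patches; switches on semi-supervised
        training with the biomechanical loss.
    second_view / target_second_view : optional
        Second complementary noisy input, concatenated at the input layer
        (multi-view fusion).
    """

    def __init__(self, noise_patches, true_patches=None, target_patches=None,
                 config: Optional[TrainConfig] = None,
                 second_view=None, target_second_view=None,
                 patch_shape=None, spacing_mm=None, stride=None):
        self.config = config or TrainConfig()
        self.noise = _patch_data(noise_patches)
        self.true = None if true_patches is None else _patch_data(true_patches)
        self.target = None if target_patches is None else _patch_data(target_patches)
        self.second = None if second_view is None else _patch_data(second_view)
        self.target_second = (None if target_second_view is None
                              else _patch_data(target_second_view))
        self.multi_view = self.second is not None
        if self.multi_view and self.second.shape != self.noise.shape:
            raise ValueError("second view must match the first view's shape")
        if self.target is not None and self.multi_view and self.target_second is None:
            raise ValueError("multi-view semi-supervised training needs a "
                             "second target view")

        src = noise_patches if isinstance(noise_patches, PatchSet) else None
        self.patch_shape = tuple(patch_shape or (src.patch_shape if src else ()))
        if not self.patch_shape:
            raise ValueError("patch_shape required when passing raw arrays")
        self.spacing_mm = tuple(spacing_mm or (src.spacing_mm if src else (1, 1, 1)))
        self.stride = tuple(stride or (src.stride if src else (2, 2, 2)))
        self.D = int(np.prod(self.patch_shape))
        if self.noise.shape[1] != self.D:
            raise ValueError("noise patch dimension does not match patch_shape")
        self.mode = "semisupervised" if self.target is not None else "supervised"
        if self.mode == "supervised" and self.true is None:
            raise ValueError("supervised training needs true_patches")

    @classmethod
    def from_fields(cls, noisy_field: DisplacementField4D,
                    true_field: Optional[DisplacementField4D] = None,
                    target_field: Optional[DisplacementField4D] = None,
                    second_field: Optional[DisplacementField4D] = None,
                    target_second_field: Optional[DisplacementField4D] = None,
                    patch_xyz=(5, 5, 5), stride=(2, 2, 2),
                    config: Optional[TrainConfig] = None) -> "DisplacementRegularizer":
        ex = lambda f: (None if f is None else
                        extract_patches(f, patch_xyz=patch_xyz, stride=stride))
        return cls(ex(noisy_field), ex(true_field), ex(target_field),
                   config=config, second_view=ex(second_field),
                   target_second_view=ex(target_second_field))

    # ------------------------------------------------------------------
    def fit(self) -> "RegularizerResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)

        X_sup = (np.concatenate([self.noise, self.second], axis=1)
                 if self.multi_view else self.noise)
        Y_sup = self.true
        if cfg.identity_augmentation and self.mode == "supervised":
            X_id = (np.concatenate([self.true, self.true], axis=1)
                    if self.multi_view else self.true)
            X_sup = np.concatenate([X_sup, X_id], axis=0)
            Y_sup = np.concatenate([Y_sup, self.true], axis=0)

        mean, std = self._fit_standardization(Y_sup if Y_sup is not None
                                              else self.noise)
        Xs = self._standardize(X_sup, mean, std).astype(np.float32)
        Ys = (None if Y_sup is None
              else np.asarray(Y_sup, dtype=np.float64))

        X_tgt_phys = None
        if self.target is not None:
            X_tgt_in = (np.concatenate([self.target, self.target_second], axis=1)
                        if self.multi_view else self.target)
            X_tgt = self._standardize(X_tgt_in, mean, std).astype(np.float32)
            X_tgt_phys = np.asarray(self.target, dtype=np.float64)

        D_in = Xs.shape[1]
        layers = [D_in] + [cfg.hidden_width] * cfg.hidden_layers + [self.D]
        net = MLP(layers, dropout_p=cfg.dropout, seed=int(rng.integers(2 ** 31)))
        opt = RMSProp(net.parameters(), cfg.learning_rate, cfg.rmsprop_alpha)

        tr_s, va_s = _split(len(Xs), cfg.validation_fraction, rng)
        if self.target is not None:
            tr_t, va_t = _split(len(X_tgt), cfg.validation_fraction, rng)

        history = []
        best = (np.inf, None, -1)
        for epoch in range(cfg.epochs):
            if cfg.lr_decay != 1.0 and cfg.epochs > 1:
                opt.learning_rate = cfg.learning_rate * cfg.lr_decay ** (
                    epoch / (cfg.epochs - 1))
            order_s = rng.permutation(tr_s)
            batches_s = [order_s[i:i + cfg.batch_size]
                         for i in range(0, len(order_s), cfg.batch_size)]
            if self.target is not None:
                order_t = rng.permutation(tr_t)
                batches_t = [order_t[i:i + cfg.batch_size]
                             for i in range(0, len(order_t), cfg.batch_size)]
            else:
                batches_t = []

            train_loss, n_steps = 0.0, 0
            for step in range(max(len(batches_s), len(batches_t))):
                if batches_s:
                    idx = batches_s[step % len(batches_s)]
                    train_loss += self._sup_step(net, opt, rng, Xs[idx], Ys[idx],
                                                 mean, std)
                    n_steps += 1
                if batches_t:
                    idx = batches_t[step % len(batches_t)]
                    train_loss += self._tgt_step(net, opt, rng, X_tgt[idx],
                                                 X_tgt_phys[idx], mean, std)
                    n_steps += 1
            train_loss /= max(n_steps, 1)

            val, val_terms = self._validation_loss(
                net, Xs[va_s], None if Ys is None else Ys[va_s],
                None if self.target is None else X_tgt[va_t],
                None if self.target is None else X_tgt_phys[va_t],
                mean, std)
            if not np.isfinite(train_loss) or not np.isfinite(val):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: train={train_loss}, "
                    f"val={val}; reduce the learning rate or check scaling")
            history.append({"epoch": epoch, "train_loss": train_loss,
                            "val_loss": val, **val_terms})
            if val < best[0]:
                best = (val, net.copy_parameters(), epoch)

        if best[1] is not None:
            net.set_parameters(best[1])
        fingerprint = {"patch_shape": list(self.patch_shape),
                       "flatten_order": FLATTEN_ORDER,
                       "spacing_mm": list(self.spacing_mm),
                       "stride": list(self.stride),
                       "multi_view": self.multi_view}
        return RegularizerResults(self, net, pd.DataFrame(history),
                                  best_epoch=best[2], best_val_loss=best[0],
                                  standardization=(mean, std),
                                  fingerprint=fingerprint)

    # ------------------------------------------------------------------
    def _fit_standardization(self, ref: np.ndarray):
        if not self.config.standardize:
            return np.zeros(3), np.ones(3)
        pools = [self.noise, ref]
        if self.target is not None:
            pools.append(self.target)
        comp = np.concatenate([p.reshape(-1, 3) for p in pools], axis=0)
        mean = comp.mean(axis=0)
        std = comp.std(axis=0)
        std[std < 1e-9] = 1.0
        return mean, std

    @staticmethod
    def _standardize(x: np.ndarray, mean, std) -> np.ndarray:
        n = len(x)
        return ((x.reshape(n, -1, 3) - mean) / std).reshape(n, -1)

    @staticmethod
    def _destandardize(y: np.ndarray, mean, std) -> np.ndarray:
        n = len(y)
        return (np.asarray(y, dtype=np.float64).reshape(n, -1, 3) * std
                + mean).reshape(n, -1)

    def _sup_step(self, net, opt, rng, Xb, Yb, mean, std) -> float:
        cfg = self.config
        pred_std, cache = net.forward(Xb, training=True, rng=rng)
        pred = self._destandardize(pred_std, mean, std)
        loss = cfg.lambda_super * logcosh_loss(pred, Yb)
        g_phys = cfg.lambda_super * logcosh_grad(pred, Yb)
        g_std = (g_phys.reshape(len(Xb), -1, 3) * std).reshape(len(Xb), -1)
        dW, db = net.backward(cache, g_std)
        opt.step(net.parameters(), dW + db)
        return loss

    def _tgt_step(self, net, opt, rng, Xb, Xb_phys, mean, std) -> float:
        cfg = self.config
        pred_std, cache = net.forward(Xb, training=True, rng=rng)
        pred = self._destandardize(pred_std, mean, std)
        loss, _ = biomech_loss(pred, Xb_phys, cfg.lambda_div, cfg.lambda_loop,
                               self.patch_shape, self.spacing_mm[:3],
                               reduction="mean")
        g_phys = biomech_grad(pred, Xb_phys, cfg.lambda_div, cfg.lambda_loop,
                              self.patch_shape, self.spacing_mm[:3],
                              reduction="mean")
        g_std = (g_phys.reshape(len(Xb), -1, 3) * std).reshape(len(Xb), -1)
        dW, db = net.backward(cache, g_std)
        opt.step(net.parameters(), dW + db)
        return loss

    def _validation_loss(self, net, Xv, Yv, Xtv, Xtv_phys, mean, std):
        cfg = self.config
        total, terms = 0.0, {}
        if Yv is not None and len(Xv):
            pred = self._destandardize(net.predict(Xv), mean, std)
            lc = logcosh_loss(pred, Yv)
            total += cfg.lambda_super * lc
            terms["val_logcosh"] = lc
        if Xtv is not None and len(Xtv):
            pred = self._destandardize(net.predict(Xtv), mean, std)
            bm, parts = biomech_loss(pred, Xtv_phys, cfg.lambda_div,
                                     cfg.lambda_loop, self.patch_shape,
                                     self.spacing_mm[:3], reduction="mean")
            total += bm
            terms.update({"val_data": parts["data"], "val_div": parts["div"],
                          "val_loop": parts["loop"]})
        return total, terms


def _split(n: int, frac: float, rng) -> tuple:
    perm = rng.permutation(n)
    n_val = max(1, int(round(frac * n))) if n > 1 else 0
    return perm[n_val:], perm[:n_val]


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

class RegularizerResults:
    """Fitted regularizer: parameters, history, prediction and diagnostics."""

    def __init__(self, model: DisplacementRegularizer, net: MLP,
                 history: pd.DataFrame, best_epoch: int, best_val_loss: float,
                 standardization, fingerprint: dict):
        self.model = model
        self.net = net
        self.history = history
        self.best_epoch = int(best_epoch)
        self.best_val_loss = float(best_val_loss)
        self.standardization = standardization
        self.fingerprint = fingerprint

    # ---- prediction ----------------------------------------------------
    def predict(self, patches: Union[PatchSet, np.ndarray],
                second: Union[PatchSet, np.ndarray, None] = None) -> np.ndarray:
        """Regularize flattened patches (physical mm in, physical mm out).

        Deterministic: dropout is inactive and no randomness is used."""
        X = _patch_data(patches)
        if self.fingerprint["multi_view"]:
            if second is None:
                raise ValueError("multi-view model needs a second input view")
            X = np.concatenate([X, _patch_data(second)], axis=1)
        elif second is not None:
            raise ValueError("single-view model takes one input")
        mean, std = self.standardization
        Xs = DisplacementRegularizer._standardize(X, mean, std).astype(np.float32)
        pred_std = self.net.predict(Xs)
        return DisplacementRegularizer._destandardize(pred_std, mean, std)

    def regularize_field(self, noisy_field: DisplacementField4D,
                         second_field: Optional[DisplacementField4D] = None,
                         stride=None) -> DisplacementField4D:
        """Extract -> (concatenate views) -> forward pass -> reconstruct."""
        ps = tuple(self.fingerprint["patch_shape"])
        if noisy_field.n_frames != ps[3]:
            raise ValueError(
                f"field has {noisy_field.n_frames} frames; model expects {ps[3]}")
        stride = tuple(stride or self.fingerprint.get("stride", (2, 2, 2)))
        pset = extract_patches(noisy_field, patch_xyz=ps[:3], stride=stride)
        second_pset = None
        if self.fingerprint["multi_view"]:
            if second_field is None:
                raise ValueError("multi-view model needs a second noisy field")
            second_pset = extract_patches(second_field, patch_xyz=ps[:3],
                                          stride=stride)
        pred = self.predict(pset, second_pset)
        out = PatchSet(pred, pset.patch_shape, pset.stride, pset.origins,
                       pset.grid_shape, pset.spacing_mm, mask=pset.mask)
        return reconstruct_field(out)

    def hidden_embedding(self, patches, second=None):
        """Last-hidden-layer activations (N, hidden_width) in evaluation mode.

        ``patches`` may be a dict mapping domain label -> patch array, in
        which case ``(embeddings, labels)`` is returned for external 2-D
        embedding (e.g. t-SNE)."""
        if isinstance(patches, dict):
            embs, labels = [], []
            for name, p in patches.items():
                e, _ = self.hidden_embedding(p, second)
                embs.append(e)
                labels.extend([name] * len(e))
            return np.concatenate(embs, axis=0), np.asarray(labels)
        X = _patch_data(patches)
        if self.fingerprint["multi_view"]:
            if second is None:
                raise ValueError("multi-view model needs a second input view")
            X = np.concatenate([X, _patch_data(second)], axis=1)
        mean, std = self.standardization
        Xs = DisplacementRegularizer._standardize(X, mean, std).astype(np.float32)
        return self.net.hidden_activations(Xs), np.zeros(len(X), dtype=object)

    # ---- reporting ------------------------------------------------------
    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Displacement Regularizer Results",
            "=" * 40,
            f"mode:              {self.model.mode}"
            + (" (multi-view)" if self.fingerprint["multi_view"] else ""),
            f"patch shape:       {tuple(self.fingerprint['patch_shape'])}",
            f"layers:            {self.net.layer_sizes}",
            f"dropout:           {self.net.dropout_p}",
            f"parameters:        {sum(p.size for p in self.net.parameters()):,}",
            f"epochs trained:    {len(self.history)}",
            f"best epoch:        {self.best_epoch}",
            f"best val loss:     {self.best_val_loss:.6g}",
            f"lambda_super:      {cfg.lambda_super}",
            f"lambda_div:        {cfg.lambda_div}",
            f"lambda_loop:       {cfg.lambda_loop}",
            f"learning rate:     {cfg.learning_rate}",
        ]
        return "\n".join(lines)

    def plot_training(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_loss"], label="train")
        ax.plot(self.history["epoch"], self.history["val_loss"], label="validation")
        ax.axvline(self.best_epoch, ls="--", c="gray", lw=0.8)
        ax.set_xlabel("epoch")
        ax.set_ylabel("objective")
        ax.legend()
        return ax

    # ---- persistence -----------------------------------------------------
    def save(self, path: str) -> None:
        """Checkpoint: npz weights + JSON metadata + CSV loss history."""
        mean, std = self.standardization
        arrays = {f"W{i}": w for i, w in enumerate(self.net.W)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.net.b)})
        arrays.update({"mean": mean, "std": std})
        np.savez(path, **arrays)
        with open(path + ".json", "w") as fh:
            json.dump({"layer_sizes": self.net.layer_sizes,
                       "dropout": self.net.dropout_p,
                       "config": asdict(self.model.config),
                       "fingerprint": self.fingerprint,
                       "best_epoch": self.best_epoch,
                       "best_val_loss": self.best_val_loss}, fh, indent=1)
        self.history.to_csv(path + ".history.csv", index=False)

    @classmethod
    def load(cls, path: str) -> "RegularizerResults":
        with open(path + ".json") as fh:
            meta = json.load(fh)
        arrays = np.load(path if path.endswith(".npz") else path + ".npz")
        net = MLP(meta["layer_sizes"], dropout_p=meta["dropout"])
        n = net.n_layers
        net.W = [arrays[f"W{i}"] for i in range(n)]
        net.b = [arrays[f"b{i}"] for i in range(n)]
        cfg = TrainConfig(**meta["config"])
        fp = meta["fingerprint"]
        shell = DisplacementRegularizer.__new__(DisplacementRegularizer)
        shell.config = cfg
        shell.mode = "loaded"
        shell.patch_shape = tuple(fp["patch_shape"])
        shell.spacing_mm = tuple(fp["spacing_mm"])
        shell.multi_view = fp["multi_view"]
        hist = pd.read_csv(path + ".history.csv")
        return cls(shell, net, hist, meta["best_epoch"], meta["best_val_loss"],
                   (arrays["mean"], arrays["std"]), fp)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def train_supervised(noise_patches, true_patches,
                     config: Optional[TrainConfig] = None,
                     **model_kw) -> RegularizerResults:
    """Supervised log-cosh training on paired (noisy, truth) patches."""
    return DisplacementRegularizer(noise_patches, true_patches,
                                   config=config, **model_kw).fit()


def train_semisupervised(synthetic_noise, synthetic_true, target_noise,
                         config: Optional[TrainConfig] = None,
                         **model_kw) -> RegularizerResults:
    """Semi-supervised training: supervised term on synthetic pairs plus the
    biomechanical loss on unlabeled target-domain patches."""
    return DisplacementRegularizer(synthetic_noise, synthetic_true,
                                   target_patches=target_noise,
                                   config=config, **model_kw).fit()


def regularize_field(results: RegularizerResults, noisy_field,
                     second_noisy_field=None) -> DisplacementField4D:
    return results.regularize_field(noisy_field, second_noisy_field)


def hidden_embedding(results: RegularizerResults, patches, second=None):
    return results.hidden_embedding(patches, second)
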