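"""Displacement-field data model and field-level operators.

A 4D cardiac displacement field is a grid-sampled, 3-component vector field
over the cardiac cycle, restricted to a myocardium mask.  Fields are either
*Lagrangian* (every vector references the material point's position at the
end-diastole frame, frame 0) or *Eulerian* (frame-to-frame displacement at
fixed grid locations).  This module provides:

* :class:`DisplacementField4D` and :class:`SparseTrajectorySet` containers,
  with NIfTI / CSV round-trip I/O,
* mask-aware spatial :func:`divergence` (trace of the displacement gradient),
* cyclic :func:`loop_residual` / temporal-derivative energy (the periodicity
  diagnostic used by the biomechanical loss),
* :func:`eulerian_to_lagrangian` accumulation along material trajectories,
* sparse-to-dense interpolation (:func:`fit_rbf_dense`) with compactly
  supported radial basis functions, an L1 penalty on the kernel weights and
  an incompressibility (divergence) penalty.

Units: physical coordinates and displacements are millimetres throughout;
divergence is 1/mm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "DisplacementField4D",
    "SparseTrajectorySet",
    "RBFModel",
    "LoopResult",
    "divergence",
    "loop_residual",
    "eulerian_to_lagrangian",
    "fit_rbf_dense",
    "evaluate_rbf",
    "masked_gradient",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DisplacementField4D:
    """Grid-sampled displacement field ``values[x, y, z, frame, component]`` in mm.

    ``reference`` is ``"lagrangian"`` (displacement from the ED material
    position; frame 0 identically zero) or ``"eulerian"`` (frame-to-frame).
    ``validity`` optionally flags voxels whose trajectory left the grid
    during accumulation.
    """

    values: np.ndarray
    spacing_mm: tuple
    mask: np.ndarray
    reference: str = "lagrangian"
    origin_mm: tuple = (0.0, 0.0, 0.0)
    validity: Optional[np.ndarray] = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 5 or self.values.shape[-1] != 3:
            raise ValueError("values must have shape (nx, ny, nz, frames, 3)")
        if self.values.shape[:3] != self.mask.shape:
            raise ValueError("mask shape does not match field grid")
        if self.reference not in ("lagrangian", "eulerian"):
            raise ValueError(f"unknown reference {self.reference!r}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("field values must be finite on the mask")
        if self.reference == "lagrangian" and self.n_frames > 0:
            ed = self.values[self.mask][:, 0, :]
            if not np.allclose(ed, 0.0, atol=1e-9):
                raise ValueError("Lagrangian field must be zero at the ED frame")

    @property
    def grid_shape(self) -> tuple:
        return self.mask.shape

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    def copy(self) -> "DisplacementField4D":
        return DisplacementField4D(
            self.values.copy(), self.spacing_mm, self.mask.copy(),
            self.reference, self.origin_mm,
            None if self.validity is None else self.validity.copy(),
            dict(self.meta),
        )

    def voxel_coords_mm(self) -> np.ndarray:
        """Physical coordinates (nx, ny, nz, 3) of voxel centers."""
        idx = np.indices(self.grid_shape).astype(float)
        coords = np.stack(
            [idx[i] * self.spacing_mm[i] + self.origin_mm[i] for i in range(3)],
            axis=-1,
        )
        return coords

    # ---- I/O -------------------------------------------------------------
    def to_nifti(self, path: str) -> None:
        """Write as a 5-D NIfTI (x, y, z, frame, component); mask to a sidecar."""
        import nibabel as nib

        affine = np.diag(list(self.spacing_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), path)
        mask_path = _sidecar(path, "_mask")
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine), mask_path)
        with open(_sidecar(path, "_meta", ext=".json"), "w") as fh:
            json.dump({"reference": self.reference,
                       "spacing_mm": list(self.spacing_mm),
                       "origin_mm": list(self.origin_mm)}, fh)

    @classmethod
    def from_nifti(cls, path: str) -> "DisplacementField4D":
        import nibabel as nib

        img = nib.load(path)
        values = np.asarray(img.dataobj, dtype=float)
        mask = np.asarray(nib.load(_sidecar(path, "_mask")).dataobj) > 0
        with open(_sidecar(path, "_meta", ext=".json")) as fh:
            meta = json.load(fh)
        return cls(values, tuple(meta["spacing_mm"]), mask,
                   reference=meta["reference"], origin_mm=tuple(meta["origin_mm"]))


def _sidecar(path: str, suffix: str, ext: Optional[str] = None) -> str:
    for e in (".nii.gz", ".nii"):
        if path.endswith(e):
            return path[: -len(e)] + suffix + (ext if ext is not None else e)
    raise ValueError(f"expected a .nii/.nii.gz path, got {path!r}")


@dataclass
class SparseTrajectorySet:
    """Material-point trajectories: ED positions and per-frame Lagrangian displacement."""

    point_ids: np.ndarray              # (M,)
    ed_positions_mm: np.ndarray        # (M, 3)
    displacements_mm: np.ndarray       # (M, frames, 3)

    def __post_init__(self):
        self.point_ids = np.asarray(self.point_ids)
        self.ed_positions_mm = np.asarray(self.ed_positions_mm, dtype=float)
        self.displacements_mm = np.asarray(self.displacements_mm, dtype=float)
        if not np.allclose(self.displacements_mm[:, 0, :], 0.0):
            raise ValueError("sparse trajectories must have zero displacement at frame 0")

    @property
    def n_points(self) -> int:
        return len(self.point_ids)

    @property
    def n_frames(self) -> int:
        return self.displacements_mm.shape[1]

    def positions_mm(self, frame: int) -> np.ndarray:
        return self.ed_positions_mm + self.displacements_mm[:, frame, :]

    def to_csv(self, path: str) -> None:
        rows = []
        for i, pid in enumerate(self.point_ids):
            pos = self.ed_positions_mm[i] + self.displacements_mm[i]
            for f in range(self.n_frames):
                rows.append((pid, f, *pos[f]))
        pd.DataFrame(rows, columns=["point_id", "frame", "x_mm", "y_mm", "z_mm"]).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "SparseTrajectorySet":
        df = pd.read_csv(path).sort_values(["point_id", "frame"])
        ids = df["point_id"].unique()
        n_frames = df["frame"].nunique()
        pos = df[["x_mm", "y_mm", "z_mm"]].to_numpy().reshape(len(ids), n_frames, 3)
        ed = pos[:, 0, :]
        return cls(ids, ed, pos - ed[:, None, :])


# ---------------------------------------------------------------------------
# mask-aware differential operators
# ---------------------------------------------------------------------------

def masked_gradient(volume: np.ndarray, mask: np.ndarray,
                    spacing_mm: Sequence[float]) -> np.ndarray:
    """Spatial gradient (nx, ny, nz, 3) of a scalar volume on a mask.

    Central differences where both axis neighbours are masked, one-sided at
    the mask boundary, zero where a voxel has no masked neighbour along an
    axis.  Exact for fields affine in the coordinates (including at the
    boundary, since one-sided first differences are exact there too).
    """
    volume = np.asarray(volume, dtype=float)
    out = np.zeros(volume.shape + (3,))
    for ax in range(3):
        h = float(spacing_mm[ax])
        vp = _shift(volume, -1, ax)    # value at index+1
        vm = _shift(volume, +1, ax)
        mp = _shift(mask, -1, ax, fill=False)
        mm = _shift(mask, +1, ax, fill=False)
        central = mask & mp & mm
        fwd = mask & mp & ~mm
        bwd = mask & mm & ~mp
        g = out[..., ax]
        g[central] = (vp[central] - vm[central]) / (2.0 * h)
        g[fwd] = (vp[fwd] - volume[fwd]) / h
        g[bwd] = (volume[bwd] - vm[bwd]) / h
    return out


def _shift(a: np.ndarray, step: int, axis: int, fill=0):
    """Shift array along axis; vacated entries take `fill`."""
    out = np.full_like(a, fill)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if step == -1:
        src[axis] = slice(1, None)
        dst[axis] = slice(None, -1)
    elif step == 1:
        src[axis] = slice(None, -1)
        dst[axis] = slice(1, None)
    else:
        raise ValueError("step must be +-1")
    out[tuple(dst)] = a[tuple(src)]
    return out


def displacement_gradient(field: DisplacementField4D, frame: int) -> np.ndarray:
    """Displacement gradient tensor (nx, ny, nz, 3, 3): G[..., i, j] = du_i/dx_j."""
    u = field.values[..., frame, :]
    G = np.zeros(field.grid_shape + (3, 3))
    for comp in range(3):
        G[..., comp, :] = masked_gradient(u[..., comp], field.mask, field.spacing_mm)
    return G


def divergence(field: DisplacementField4D, frame: int) -> np.ndarray:
    """Divergence of the frame-`frame` displacement (1/mm): trace of the
    displacement gradient tensor, via mask-aware central differences.
    Zero outside the mask."""
    G = displacement_gradient(field, frame)
    div = np.trace(G, axis1=-2, axis2=-1)
    div[~field.mask] = 0.0
    return div


@dataclass
class LoopResult:
    """Periodicity diagnostics of a Lagrangian field.

    ``residual``: per-voxel vector sum of frame-to-frame differences
    (identically zero in cyclic mode; ``u(T-1) - u(0)`` otherwise).
    ``energy``: per-voxel temporal-derivative energy sum_t ||u(t+1)-u(t)||^2,
    the quantity penalised by the periodicity loss term.
    """

    residual: np.ndarray   # (nx, ny, nz, 3)
    energy: np.ndarray     # (nx, ny, nz)
    cyclic: bool


def loop_residual(field: DisplacementField4D, cyclic: bool = True) -> LoopResult:
    if field.reference != "lagrangian":
        raise ValueError("loop residual is defined for Lagrangian fields")
    u = field.values
    diffs = np.diff(u, axis=3)                       # (..., T-1, 3)
    # the frame-to-frame differences telescope: sum = u(T-1) - u(0); computed
    # directly so the cyclic residual is exactly zero, not merely tiny
    residual = u[..., -1, :] - u[..., 0, :]
    energy = (diffs ** 2).sum(axis=(3, 4))
    if cyclic:
        wrap = u[..., 0, :] - u[..., -1, :]
        residual = residual + wrap
        energy = energy + (wrap ** 2).sum(axis=-1)
    residual[~field.mask] = 0.0
    energy[~field.mask] = 0.0
    return LoopResult(residual=residual, energy=energy, cyclic=cyclic)


# ---------------------------------------------------------------------------
# Eulerian -> Lagrangian accumulation
# ---------------------------------------------------------------------------

def eulerian_to_lagrangian(eulerian: DisplacementField4D) -> DisplacementField4D:
    """Accumulate frame-to-frame (Eulerian) fields into a Lagrangian field.

    Each masked ED voxel is treated as a material point; at every frame the
    Eulerian displacement is sampled trilinearly at the point's current
    position and accumulated.  Frame ``t`` of the Eulerian input holds the
    displacement carrying frame ``t`` to ``t+1``; the last frame is unused.
    Positions leaving the grid are clamped and flagged in ``validity``.
    """
    if eulerian.reference != "eulerian":
        raise ValueError("input must be an Eulerian field")
    T = eulerian.n_frames
    spacing = np.asarray(eulerian.spacing_mm)
    origin = np.asarray(eulerian.origin_mm)
    shape = np.asarray(eulerian.grid_shape, dtype=float)

    mask_idx = np.argwhere(eulerian.mask)
    pos = mask_idx * spacing + origin                  # current position (mm)
    ed_pos = pos.copy()
    lag = np.zeros(eulerian.grid_shape + (T, 3))
    valid = np.ones(eulerian.grid_shape, dtype=bool)
    valid_pts = np.ones(len(mask_idx), dtype=bool)

    for t in range(T - 1):
        vox = (pos - origin) / spacing                 # fractional voxel coords
        out_of_grid = np.any((vox < 0) | (vox > shape - 1), axis=1)
        valid_pts &= ~out_of_grid
        coords = np.clip(vox, 0, shape - 1).T
        step = np.empty_like(pos)
        for c in range(3):
            step[:, c] = ndimage.map_coordinates(
                eulerian.values[..., t, c], coords, order=1, mode="nearest")
        pos = pos + step
        disp = pos - ed_pos
        lag[mask_idx[:, 0], mask_idx[:, 1], mask_idx[:, 2], t + 1, :] = disp

    valid[mask_idx[:, 0], mask_idx[:, 1], mask_idx[:, 2]] = valid_pts
    return DisplacementField4D(lag, eulerian.spacing_mm, eulerian.mask,
                               reference="lagrangian", origin_mm=eulerian.origin_mm,
                               validity=valid)


# ---------------------------------------------------------------------------
# RBF sparse-to-dense interpolation
# ---------------------------------------------------------------------------

@dataclass
class RBFModel:
    """Compactly supported RBF expansion of one frame's displacement field.

    Each component is expanded as u_c(x) = sum_k w[k, c] phi(|x - c_k| / rho)
    with a Wendland C2 kernel.  Fitted by minimising

        ||H w - u_sp||^2 + lambda1 ||w||_1 + lambda2 ||div u||^2

    where the divergence is evaluated at the sample points via analytic
    kernel gradients.
    """

    centers_mm: np.ndarray
    weights: np.ndarray        # (K, 3)
    support_radius_mm: float
    kernel: str = "wendland_c2"
    lambda1: float = 0.0
    lambda2: float = 0.0

    def __post_init__(self):
        if self.support_radius_mm <= 0:
            raise ValueError("support radius must be positive")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"centers_mm": self.centers_mm.tolist(),
                       "weights": self.weights.tolist(),
                       "support_radius_mm": self.support_radius_mm,
                       "kernel": self.kernel,
                       "lambda1": self.lambda1, "lambda2": self.lambda2}, fh)

    @classmethod
    def from_json(cls, path: str) -> "RBFModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["centers_mm"]), np.asarray(d["weights"]),
                   d["support_radius_mm"], d["kernel"], d["lambda1"], d["lambda2"])


def _wendland_c2(r: np.ndarray, rho: float) -> np.ndarray:
    q = np.clip(r / rho, 0.0, 1.0)
    return (1.0 - q) ** 4 * (4.0 * q + 1.0)


def _kernel_matrix(points: np.ndarray, centers: np.ndarray, rho: float) -> np.ndarray:
    d = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=-1)
    return _wendland_c2(d, rho)


def _kernel_grad_matrices(points: np.ndarray, centers: np.ndarray, rho: float):
    """G_c[m, k] = d phi_k / d x_c evaluated at point m (analytic, no r=0 singularity)."""
    diff = points[:, None, :] - centers[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    q = r / rho
    inside = q < 1.0
    # d phi / d q = -20 q (1-q)^3  =>  grad = -20 (1-q)^3 / rho^2 * (x - c)
    coef = np.where(inside, -20.0 * (1.0 - np.clip(q, None, 1.0)) ** 3 / rho ** 2, 0.0)
    return [coef * diff[..., c] for c in range(3)]


def evaluate_rbf(model: RBFModel, points_mm: np.ndarray,
                 chunk: int = 4096) -> np.ndarray:
    """Evaluate the fitted expansion at arbitrary points (N, 3) -> (N, 3)."""
    out = np.empty((len(points_mm), 3))
    for lo in range(0, len(points_mm), chunk):
        H = _kernel_matrix(points_mm[lo:lo + chunk], model.centers_mm,
                           model.support_radius_mm)
        out[lo:lo + chunk] = H @ model.weights
    return out


def fit_rbf_dense(sparse: SparseTrajectorySet, geometry, frame: int,
                  lambda1: float = 1e-3, lambda2: float = 1e-2,
                  support_radius_mm: Optional[float] = None,
                  max_iter: int = 5000, tol: float = 1e-8,
                  return_history: bool = False):
    """Fit one frame's sparse displacements with a regularized RBF expansion
    and evaluate it on all masked voxels of ``geometry``.

    Returns ``(RBFModel, dense (nx, ny, nz, 3))`` (plus the per-iteration
    loss history when requested).  With ``lambda1 == 0`` the smooth quadratic
    objective is solved directly; with ``lambda1 > 0`` a proximal-gradient
    (ISTA) iteration with backtracking handles the L1 term.
    """
    pts = sparse.ed_positions_mm
    u = sparse.displacements_mm[:, frame, :]
    M = len(pts)
    if M < 4:
        raise ValueError("need at least 4 sparse points")
    if support_radius_mm is None:
        support_radius_mm = 4.0 * _max_nn_gap(pts)
    else:
        gap = _max_nn_gap(pts)
        if support_radius_mm <= gap:
            raise ValueError(
                f"support radius {support_radius_mm} must exceed the largest "
                f"nearest-neighbour gap {gap:.3g}")

    H = _kernel_matrix(pts, pts, support_radius_mm)
    if lambda1 == 0.0 and lambda2 == 0.0:
        cond = np.linalg.cond(H)
        if cond > 1e12:
            raise np.linalg.LinAlgError(
                f"ill-conditioned kernel system (cond {cond:.2g}); "
                "duplicate centers or add regularization")
    empty = (H > 0).sum(axis=0) == 1  # only the center itself in support
    if np.any(empty):
        warnings.warn(f"{int(empty.sum())} kernel(s) support no other sample point")

    G = _kernel_grad_matrices(pts, pts, support_radius_mm)
    history: list = []

    if lambda1 == 0.0:
        # coupled 3K x 3K normal equations: blockdiag(H^T H) + lambda2 G_c^T G_c'
        K = M
        A = np.zeros((3 * K, 3 * K))
        b = np.zeros(3 * K)
        HtH = H.T @ H
        for c in range(3):
            A[c * K:(c + 1) * K, c * K:(c + 1) * K] += HtH
            b[c * K:(c + 1) * K] = H.T @ u[:, c]
            for c2 in range(3):
                A[c * K:(c + 1) * K, c2 * K:(c2 + 1) * K] += lambda2 * (G[c].T @ G[c2])
        w = np.linalg.lstsq(A, b, rcond=None)[0].reshape(3, K).T
        history.append(_rbf_loss(H, G, w, u, lambda1, lambda2))
    else:
        w = np.zeros((M, 3))
        L = 2.0 * (np.linalg.norm(H, 2) ** 2 +
                   lambda2 * sum(np.linalg.norm(Gc, 2) ** 2 for Gc in G))
        step = 1.0 / max(L, 1e-12)
        loss = _rbf_loss(H, G, w, u, lambda1, lambda2)
        history.append(loss)
        for _ in range(max_iter):
            grad = 2.0 * (H.T @ (H @ w - u))
            div = sum(G[c] @ w[:, c] for c in range(3))
            for c in range(3):
                grad[:, c] += 2.0 * lambda2 * (G[c].T @ div)
            # backtracking on the smooth part
            s = step
            smooth0 = loss - lambda1 * np.abs(w).sum()
            for _bt in range(50):
                w_new = _soft_threshold(w - s * grad, s * lambda1)
                smooth_new = (np.sum((H @ w_new - u) ** 2) + lambda2 *
                              np.sum(sum(G[c] @ w_new[:, c] for c in range(3)) ** 2))
                dw = w_new - w
                if smooth_new <= smooth0 + np.sum(grad * dw) + np.sum(dw ** 2) / (2 * s) + 1e-15:
                    break
                s *= 0.5
            new_loss = smooth_new + lambda1 * np.abs(w_new).sum()
            w = w_new
            history.append(new_loss)
            if abs(loss - new_loss) <= tol * max(abs(loss), 1e-12):
                loss = new_loss
                break
            loss = new_loss

    model = RBFModel(pts.copy(), w, support_radius_mm, "wendland_c2",
                     lambda1, lambda2)
    coords = np.argwhere(geometry.mask) * np.asarray(geometry.spacing_mm)
    dense_vals = evaluate_rbf(model, coords)
    dense = np.zeros(geometry.mask.shape + (3,))
    dense[geometry.mask] = dense_vals
    if return_history:
        return model, dense, np.asarray(history)
    return model, dense


def _rbf_loss(H, G, w, u, lambda1, lambda2) -> float:
    div = sum(G[c] @ w[:, c] for c in range(3))
    return float(np.sum((H @ w - u) ** 2) + lambda1 * np.abs(w).sum() +
                 lambda2 * np.sum(div ** 2))


def _soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _max_nn_gap(pts: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(pts).query(pts, k=2)
    return float(d[:, 1].max())
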