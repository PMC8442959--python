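"""Overlapping 4D patch extraction and dense-field reconstruction.

The regularization network consumes flattened spatiotemporal displacement
patches spanning the whole cardiac cycle (e.g. 5x5x5 voxels x 32 frames x 3
components -> a 12000-vector) and emits patches of the same shape; this
module extracts them from a :class:`~cardioreg.fields.DisplacementField4D`
and reassembles predictions by per-voxel averaging of overlaps.

The flatten order is fixed to (x, y, z, frame, component), component
fastest-varying, and is serialized with every patch set and model so that
train and test time agree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .fields import DisplacementField4D

__all__ = ["PatchSet", "extract_patches", "reconstruct_field", "FLATTEN_ORDER"]

FLATTEN_ORDER = "xyztc"


@dataclass
class PatchSet:
    """Flattened overlapping 4D patches with placement metadata.

    ``data`` is (N, D) with D = px*py*pz*frames*3; ``origins`` the (N, 3)
    spatial voxel index of each patch's low corner.
    """

    data: np.ndarray
    patch_shape: tuple            # (px, py, pz, frames, 3)
    stride: tuple
    origins: np.ndarray
    grid_shape: tuple
    spacing_mm: tuple
    mask: Optional[np.ndarray] = None
    flatten_order: str = FLATTEN_ORDER
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        D = int(np.prod(self.patch_shape))
        if self.data.ndim != 2 or self.data.shape[1] != D:
            raise ValueError(f"data must be (N, {D}) for patch shape {self.patch_shape}")
        if len(self.origins) != len(self.data):
            raise ValueError("origins and data length mismatch")
        hi = np.asarray(self.origins) + np.asarray(self.patch_shape[:3])
        if np.any(np.asarray(self.origins) < 0) or np.any(
                hi > np.asarray(self.grid_shape)):
            raise ValueError("patch exceeds source grid")

    @property
    def n_patches(self) -> int:
        return len(self.data)

    @property
    def dim(self) -> int:
        return self.data.shape[1]

    def unflatten(self) -> np.ndarray:
        """View patches as (N, px, py, pz, frames, 3)."""
        return self.data.reshape((self.n_patches,) + tuple(self.patch_shape))

    def fingerprint(self) -> dict:
        return {"patch_shape": list(self.patch_shape),
                "flatten_order": self.flatten_order,
                "spacing_mm": list(self.spacing_mm)}

    def save(self, path: str) -> None:
        """Binary container (npz) with a JSON sidecar of the placement metadata."""
        np.savez_compressed(path, data=self.data, origins=self.origins,
                            mask=(self.mask if self.mask is not None
                                  else np.zeros(0, dtype=bool)))
        with open(path + ".json", "w") as fh:
            json.dump({"patch_shape": list(self.patch_shape),
                       "stride": list(self.stride),
                       "grid_shape": list(self.grid_shape),
                       "spacing_mm": list(self.spacing_mm),
                       "flatten_order": self.flatten_order,
                       "has_mask": self.mask is not None}, fh)

    @classmethod
    def load(cls, path: str) -> "PatchSet":
        with open(path + ".json") as fh:
            meta = json.load(fh)
        arrays = np.load(path if path.endswith(".npz") else path + ".npz")
        mask = arrays["mask"] if meta["has_mask"] else None
        if mask is not None and mask.size == 0:
            mask = None
        return cls(arrays["data"], tuple(meta["patch_shape"]),
                   tuple(meta["stride"]), arrays["origins"],
                   tuple(meta["grid_shape"]), tuple(meta["spacing_mm"]),
                   mask=mask, flatten_order=meta["flatten_order"])


def extract_patches(field: DisplacementField4D, patch_xyz=(5, 5, 5),
                    stride=(2, 2, 2), mask_rule: str = "center") -> PatchSet:
    """Extract whole-cycle 4D patches at grid-aligned origins.

    A patch is kept when its spatial window satisfies ``mask_rule``:
    ``"center"`` (default) keeps windows whose center voxel is masked,
    ``"any"`` / ``"all"`` require any / all window voxels masked.  The
    temporal extent is always the full frame count of the field.
    """
    px, py, pz = patch_xyz
    nx, ny, nz = field.grid_shape
    if px > nx or py > ny or pz > nz:
        raise ValueError("patch larger than field grid")
    T = field.n_frames
    patch_shape = (px, py, pz, T, 3)

    grid = np.meshgrid(*(np.arange(0, n - p + 1, s)
                         for n, p, s in zip((nx, ny, nz), patch_xyz, stride)),
                       indexing="ij")
    origins = np.stack([g.ravel() for g in grid], axis=1)

    if mask_rule == "center":
        centers = origins + np.asarray(patch_xyz) // 2
        keep = field.mask[centers[:, 0], centers[:, 1], centers[:, 2]]
    elif mask_rule in ("any", "all"):
        # window-reduced mask via a box filter
        counts = ndimage.uniform_filter(field.mask.astype(float), size=patch_xyz,
                                        mode="constant", origin=0)
        # value at window *center*; map origins to centers
        centers = origins + np.asarray(patch_xyz) // 2
        frac = counts[centers[:, 0], centers[:, 1], centers[:, 2]]
        vol = np.prod(patch_xyz)
        keep = frac > (1.0 - 0.5 / vol) if mask_rule == "all" else frac > 0.5 / vol
    else:
        raise ValueError(f"unknown mask_rule {mask_rule!r}")
    origins = origins[keep]

    windows = sliding_window_view(field.values, patch_xyz, axis=(0, 1, 2))
    # windows: (nx-px+1, ny-py+1, nz-pz+1, T, 3, px, py, pz)
    sel = windows[origins[:, 0], origins[:, 1], origins[:, 2]]
    sel = np.moveaxis(sel, (1, 2), (4, 5))           # -> (N, px, py, pz, T, 3)
    data = np.ascontiguousarray(sel).reshape(len(origins), -1)
    return PatchSet(data, patch_shape, tuple(stride), origins,
                    field.grid_shape, field.spacing_mm, mask=field.mask.copy())


def reconstruct_field(patchset: PatchSet) -> DisplacementField4D:
    """Reassemble a dense field from (predicted) patches.

    Voxels covered by several patches take the unweighted average; masked
    voxels covered by no patch are filled from the nearest covered voxel and
    flagged invalid in ``validity``.
    """
    if patchset.n_patches == 0:
        raise ValueError("empty patch set")
    px, py, pz, T, _ = patchset.patch_shape
    acc = np.zeros(tuple(patchset.grid_shape) + (T, 3))
    cnt = np.zeros(patchset.grid_shape)
    patches = patchset.unflatten()
    for n in range(patchset.n_patches):
        i, j, k = patchset.origins[n]
        acc[i:i + px, j:j + py, k:k + pz] += patches[n]
        cnt[i:i + px, j:j + py, k:k + pz] += 1.0
    covered = cnt > 0
    acc[covered] /= cnt[covered][:, None, None]

    validity = covered.copy()
    mask = patchset.mask if patchset.mask is not None else covered
    uncovered = mask & ~covered
    if np.any(uncovered):
        _, (ix, iy, iz) = ndimage.distance_transform_edt(
            ~covered, return_indices=True)
        acc[uncovered] = acc[ix[uncovered], iy[uncovered], iz[uncovered]]
    # the ED frame of a Lagrangian field is identically zero by definition;
    # any (numerically tiny) predicted frame-0 content is discarded
    acc[..., 0, :] = 0.0
    return DisplacementField4D(acc, patchset.spacing_mm, mask,
                               reference="lagrangian", validity=validity,
                               meta={"reconstructed_from_patches": True})
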