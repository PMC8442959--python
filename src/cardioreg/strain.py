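"""Strain analysis from dense displacement fields and sonomicrometer crystals.

Dense-field strain: the displacement gradient is computed with the same
mask-aware central/one-sided stencils as the divergence operator; the
default convention is the finite Green-Lagrange tensor
E = 1/2 (grad u + grad u^T + grad u^T grad u), exactly invariant under
superposed rigid rotation (the infinitesimal tensor is kept as an option).
Tensors are projected onto the local radial / circumferential /
longitudinal wall directions; the principal strain is the algebraically
largest eigenvalue.

Crystal strain: implanted piezoelectric crystals report pairwise acoustic
distances.  Crystal positions are recovered by trilateration from three
reference crystals mounted on the transducer; each 8-crystal cube yields
~50 non-degenerate tetrahedra whose affine deformation gradients give
per-tetrahedron Green-Lagrange tensors, aggregated by element-wise median.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fields import DisplacementField4D, masked_gradient
from .phantom import LVGeometry

__all__ = [
    "StrainField",
    "CrystalRecord",
    "strain_from_displacement",
    "peak_strain",
    "differential_strain",
    "localize_crystals",
    "crystal_cube_strain",
    "default_reference_geometry",
    "TrilaterationError",
]


# ---------------------------------------------------------------------------
# dense-field strain
# ---------------------------------------------------------------------------

@dataclass
class StrainField:
    """Per-voxel symmetric strain tensors and clinical projections.

    ``tensors``: (nx, ny, nz, frames, 3, 3), zero outside the mask.
    ``projections``: dict direction -> (nx, ny, nz, frames) scalar volumes.
    ``principal``: (nx, ny, nz, frames) largest eigenvalue.
    """

    tensors: np.ndarray
    projections: dict
    principal: np.ndarray
    mask: np.ndarray
    convention: str
    spacing_mm: tuple
    meta: dict = dc_field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.tensors.shape[3]


def _strain_tensor_one_frame(field: DisplacementField4D, frame: int,
                             convention: str) -> np.ndarray:
    G = np.zeros(field.grid_shape + (3, 3))
    u = field.values[..., frame, :]
    for comp in range(3):
        G[..., comp, :] = masked_gradient(u[..., comp], field.mask,
                                          field.spacing_mm)
    Gt = np.swapaxes(G, -1, -2)
    E = 0.5 * (G + Gt)
    if convention == "green_lagrange":
        E = E + 0.5 * np.einsum("...ki,...kj->...ij", G, G)
    elif convention != "infinitesimal":
        raise ValueError(f"unknown convention {convention!r}")
    E[~field.mask] = 0.0
    return E


def strain_from_displacement(field: DisplacementField4D,
                             geometry: Optional[LVGeometry] = None,
                             frames: Optional[Sequence[int]] = None,
                             convention: str = "green_lagrange") -> StrainField:
    """Strain tensors, wall-direction projections and principal strain.

    ``field`` must be Lagrangian (every frame's strain references the ED
    configuration).  Without a geometry, only tensors and principal strain
    are computed.
    """
    if field.reference != "lagrangian":
        raise ValueError("strain is computed from Lagrangian fields")
    frame_list = list(range(field.n_frames)) if frames is None else list(frames)
    T = len(frame_list)
    tensors = np.zeros(field.grid_shape + (T, 3, 3))
    for i, f in enumerate(frame_list):
        tensors[..., i, :, :] = _strain_tensor_one_frame(field, f, convention)

    principal = np.zeros(field.grid_shape + (T,))
    midx = field.mask
    if midx.any():
        vals = np.linalg.eigvalsh(tensors[midx])    # ascending
        principal[midx] = vals[..., -1]

    projections = {}
    if geometry is not None:
        for di, name in enumerate(("radial", "circumferential", "longitudinal")):
            e = geometry.directions[..., di, :]
            proj = np.einsum("...i,...tij,...j->...t", e, tensors, e)
            proj[~field.mask] = 0.0
            projections[name] = proj
    return StrainField(tensors, projections, principal, field.mask.copy(),
                       convention, field.spacing_mm,
                       meta={"frames": frame_list})


def peak_strain(curves: np.ndarray, axis: int = -1) -> np.ndarray:
    """Signed value of the largest-magnitude strain over frames.

    ``curves`` is any array with a frame axis; the sign of the extreme value
    is preserved (e.g. [0, -0.08, -0.15, -0.1] -> -0.15)."""
    curves = np.asarray(curves)
    if curves.shape[axis] < 2:
        raise ValueError("need at least 2 frames")
    idx = np.argmax(np.abs(curves), axis=axis)
    return np.take_along_axis(curves, np.expand_dims(idx, axis),
                              axis=axis).squeeze(axis)


def differential_strain(rest_peak_map: np.ndarray,
                        stress_peak_map: np.ndarray) -> np.ndarray:
    """Stress-minus-rest peak strain per voxel (positive = recruitable
    deformation under stress); maps must share the grid."""
    rest = np.asarray(rest_peak_map)
    stress = np.asarray(stress_peak_map)
    if rest.shape != stress.shape:
        raise ValueError("rest and stress maps are on different grids")
    return stress - rest


# ---------------------------------------------------------------------------
# sonomicrometer crystals
# ---------------------------------------------------------------------------

class TrilaterationError(RuntimeError):
    """No consistent crystal position; carries the best residual (mm)."""

    def __init__(self, msg: str, residual_mm: float):
        super().__init__(msg)
        self.residual_mm = residual_mm


def default_reference_geometry() -> np.ndarray:
    """Reference-crystal positions on the transducer (mm).

    Two facing crystals 28 mm apart, a third 13 mm from the probe-surface
    center, all in a plane 5 mm above the fan apex (origin); imaging side is
    +z (depth into the tissue)."""
    return np.array([[-14.0, 0.0, -5.0],
                     [14.0, 0.0, -5.0],
                     [0.0, 13.0, -5.0]])


@dataclass
class CrystalRecord:
    """Sonomicrometry log: 16 myocardial crystals (8 endo + 8 epi) in 3
    face-sharing cubes, plus reference-to-crystal distances per frame.

    ``distances_mm``: (frames, 3, 16) distance from each reference crystal
    to each myocardial crystal.  ``cube_membership``: three 8-tuples of
    crystal indices.
    """

    crystal_ids: np.ndarray
    reference_positions_mm: np.ndarray       # (3, 3)
    distances_mm: np.ndarray                 # (T, 3, 16)
    cube_membership: tuple

    def __post_init__(self):
        self.distances_mm = np.asarray(self.distances_mm, dtype=float)
        if np.any(self.distances_mm <= 0):
            raise ValueError("crystal distances must be positive")
        if len(self.cube_membership) != 3 or any(
                len(c) != 8 for c in self.cube_membership):
            raise ValueError("expected 3 cubes of 8 crystals each")

    @property
    def n_frames(self) -> int:
        return self.distances_mm.shape[0]

    def to_csv(self, path: str) -> None:
        rows = []
        for t in range(self.n_frames):
            for r in range(3):
                for c, cid in enumerate(self.crystal_ids):
                    rows.append((t, f"ref{r}", cid, self.distances_mm[t, r, c]))
        pd.DataFrame(rows, columns=["frame", "id_a", "id_b", "distance_mm"]
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, reference_positions_mm=None,
                 cube_membership=None) -> "CrystalRecord":
        df = pd.read_csv(path)
        refs = sorted(df["id_a"].unique())
        ids = sorted(df["id_b"].unique())
        T = df["frame"].nunique()
        d = np.full((T, len(refs), len(ids)), np.nan)
        ref_ix = {r: i for i, r in enumerate(refs)}
        id_ix = {c: i for i, c in enumerate(ids)}
        for _, row in df.iterrows():
            d[int(row["frame"]), ref_ix[row["id_a"]], id_ix[row["id_b"]]] = \
                row["distance_mm"]
        if reference_positions_mm is None:
            reference_positions_mm = default_reference_geometry()
        if cube_membership is None:
            cube_membership = (tuple(range(8)),
                               tuple(range(4, 12)),
                               tuple(range(8, 16)))
        return cls(np.asarray(ids), np.asarray(reference_positions_mm), d,
                   cube_membership)


def localize_crystals(record: CrystalRecord, frame: int,
                      imaging_side: int = +1) -> np.ndarray:
    """Trilaterate the 16 crystal positions at one frame.

    For each crystal the three sphere equations |p - r_i| = d_i are solved;
    of the two algebraic solutions, the one on the imaging side of the
    reference plane (sign of ``imaging_side`` along the plane normal) is
    returned.
    """
    refs = record.reference_positions_mm
    return np.stack([
        trilaterate(refs, record.distances_mm[frame, :, c], imaging_side)
        for c in range(record.distances_mm.shape[2])])


def trilaterate(refs: np.ndarray, dists: np.ndarray,
                imaging_side: int = +1) -> np.ndarray:
    """Solve the 3-sphere intersection for a single point (positions in mm)."""
    p1, p2, p3 = (np.asarray(r, dtype=float) for r in refs)
    d1, d2, d3 = (float(d) for d in dists)

    ex = p2 - p1
    nex = np.linalg.norm(ex)
    if nex < 1e-12:
        raise ValueError("degenerate reference configuration (coincident points)")
    ex = ex / nex
    i = ex @ (p3 - p1)
    ey = (p3 - p1) - i * ex
    ney = np.linalg.norm(ey)
    if ney < 1e-9:
        raise ValueError("degenerate reference configuration (collinear points)")
    ey = ey / ney
    ez = np.cross(ex, ey)
    j = ney

    x = (d1 ** 2 - d2 ** 2 + nex ** 2) / (2 * nex)
    y = (d1 ** 2 - d3 ** 2 + i ** 2 + j ** 2 - 2 * i * x) / (2 * j)
    z2 = d1 ** 2 - x ** 2 - y ** 2
    scale = max(d1, 1.0)
    if z2 < -1e-6 * scale ** 2:
        residual = float(np.sqrt(-z2))
        raise TrilaterationError(
            f"inconsistent distances: no real intersection "
            f"(imaginary offset {residual:.3g} mm)", residual)
    z = np.sqrt(max(z2, 0.0))
    base = p1 + x * ex + y * ey
    cand = [base + z * ez, base - z * ez]
    # pick the solution on the requested side of the reference plane
    side = [float(np.sign((c - p1) @ ez)) for c in cand]
    want = float(np.sign(imaging_side))
    for c, s in zip(cand, side):
        if s == want or s == 0.0:
            return c
    return cand[0]


def crystal_cube_strain(ed_positions: np.ndarray, def_positions: np.ndarray,
                        degeneracy_frac: float = 0.01):
    """Green-Lagrange strain of one 8-crystal cube between ED and a frame.

    All 70 tetrahedral 4-vertex subsets are enumerated; subsets whose ED
    volume is below ``degeneracy_frac`` of (cube volume / 6) are discarded
    (~50 retained for realistic geometries).  Per tetrahedron the affine
    deformation gradient F maps the 3 ED edge vectors onto the deformed
    edges and E = 1/2 (F^T F - I); the cube tensor is the element-wise
    median, its principal strain the algebraically largest eigenvalue.

    Returns ``(E_median, principal, per_tetra_tensors)``.
    """
    ed = np.asarray(ed_positions, dtype=float)
    de = np.asarray(def_positions, dtype=float)
    if ed.shape != (8, 3) or de.shape != (8, 3):
        raise ValueError("need 8 vertices at both times")
    from scipy.spatial import ConvexHull

    cube_volume = ConvexHull(ed).volume
    vol_thresh = degeneracy_frac * cube_volume / 6.0

    tensors = []
    for quad in itertools.combinations(range(8), 4):
        v = ed[list(quad)]
        edges_ed = (v[1:] - v[0]).T                  # columns are edges
        vol = abs(np.linalg.det(edges_ed)) / 6.0
        if vol < vol_thresh:
            continue
        w = de[list(quad)]
        edges_de = (w[1:] - w[0]).T
        F = edges_de @ np.linalg.inv(edges_ed)
        tensors.append(0.5 * (F.T @ F - np.eye(3)))
    if len(tensors) < 4:
        raise ValueError(
            f"only {len(tensors)} non-degenerate tetrahedra; cube too flat")
    tensors = np.asarray(tensors)
    E_med = np.median(tensors, axis=0)
    E_med = 0.5 * (E_med + E_med.T)                  # keep exactly symmetric
    principal = float(np.linalg.eigvalsh(E_med)[-1])
    return E_med, principal, tensors
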