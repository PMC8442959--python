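"""Synthetic left-ventricle motion phantom.

Generates desk-scale labelled inputs for every downstream stage: a
thick-walled truncated-ellipsoid LV shell on a voxel grid, a periodic
near-incompressible ground-truth Lagrangian motion (wall thickening +
apex-base torsion + longitudinal shortening), sparse material-point
trajectories, tracking-noise corruptions emulating the qualitative error
structure of common echo trackers, and wedge-shaped infarct masks with a
regional motion deficit.

The phantom produces displacement fields, not images: no speckle or B-mode
synthesis is attempted.

Conventions: voxel indices are 0-based; physical coordinates are
``index * spacing_mm`` (origin at voxel (0,0,0)); displacements are stored
in mm in world axes; the long axis is +z with the apex toward -z and the
basal truncation plane at the center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from typing import Optional

import numpy as np
from scipy import ndimage

from .fields import DisplacementField4D, SparseTrajectorySet

__all__ = [
    "LVGeometry",
    "MotionParams",
    "NoisePreset",
    "make_lv_geometry",
    "make_ground_truth_motion",
    "sample_sparse_trajectories",
    "corrupt_field",
    "make_infarct_mask",
    "temporal_profile",
]


class InvalidGeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class LVGeometry:
    """Thick-walled truncated-ellipsoid LV shell with local wall directions.

    ``directions`` holds, for every masked voxel, an orthonormal triple
    (radial = outward wall normal, circumferential, longitudinal) in world
    axes, shape (nx, ny, nz, 3, 3) indexed [..., direction, component] with
    direction order (radial, circumferential, longitudinal).
    """

    grid_shape: tuple
    spacing_mm: tuple
    long_axis: tuple
    center_mm: np.ndarray
    endo_semiaxes_mm: tuple
    epi_semiaxes_mm: tuple
    mask: np.ndarray
    directions: np.ndarray

    def voxel_coords_mm(self) -> np.ndarray:
        idx = np.indices(self.grid_shape).astype(float)
        return np.stack([idx[i] * self.spacing_mm[i] for i in range(3)], axis=-1)

    def radial(self) -> np.ndarray:
        return self.directions[..., 0, :]

    def circumferential(self) -> np.ndarray:
        return self.directions[..., 1, :]

    def longitudinal(self) -> np.ndarray:
        return self.directions[..., 2, :]

    def to_json(self, path: str) -> None:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in asdict(self).items() if k not in ("mask", "directions")}
        with open(path, "w") as fh:
            json.dump(d, fh)


def make_lv_geometry(grid_shape=(64, 64, 64), spacing_mm=(1.0, 1.0, 1.0),
                     endo_semiaxes_mm=(15.0, 15.0, 25.0),
                     epi_semiaxes_mm=(22.0, 22.0, 32.0),
                     center_mm=None) -> LVGeometry:
    """Build the LV shell mask and per-voxel wall directions.

    The myocardium is the set of voxels between two coaxial ellipsoids,
    truncated at the basal plane z = center (plane included); the apex points
    toward -z.
    """
    endo = np.asarray(endo_semiaxes_mm, dtype=float)
    epi = np.asarray(epi_semiaxes_mm, dtype=float)
    spacing = np.asarray(spacing_mm, dtype=float)
    if np.any(endo <= 0) or np.any(epi <= 0) or np.any(endo >= epi):
        raise InvalidGeometryError(
            "endo semiaxes must be positive and strictly inside epi semiaxes")
    if center_mm is None:
        # base plane at z = center; the shell extends epi_z below it, so the
        # default center sits the apex 2 voxels above the grid floor
        mid = (np.asarray(grid_shape) - 1) * spacing / 2.0
        center_mm = (mid[0], mid[1], epi[2] + 2.0 * spacing[2])
    center = np.asarray(center_mm, dtype=float)

    extent = (np.asarray(grid_shape) - 1) * spacing
    margin = 2.0 * spacing
    # the shell is truncated at z = center, so only x/y need full headroom above
    hi = center + np.array([epi[0], epi[1], 0.0])
    if (np.any(center - epi < margin - 1e-9) or
            np.any(hi > extent - margin + 1e-9)):
        raise InvalidGeometryError("epi shell (plus 2-voxel margin) exits the grid")

    coords = np.stack([np.indices(grid_shape)[i] * spacing[i] for i in range(3)],
                      axis=-1)
    rel = coords - center
    q_endo = ((rel / endo) ** 2).sum(axis=-1)
    q_epi = ((rel / epi) ** 2).sum(axis=-1)
    mask = (q_epi <= 1.0) & (q_endo >= 1.0) & (rel[..., 2] <= 0.0)

    # keep a single connected component (the shell; rounding can strand voxels)
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    if not mask.any():
        raise InvalidGeometryError("empty myocardium mask")

    directions = _wall_directions(rel, epi, mask)
    return LVGeometry(tuple(grid_shape), tuple(spacing), (0.0, 0.0, 1.0),
                      center, tuple(endo), tuple(epi), mask, directions)


def _wall_directions(rel: np.ndarray, semiaxes: np.ndarray,
                     mask: np.ndarray) -> np.ndarray:
    """Orthonormal (radial, circumferential, longitudinal) triple per voxel.

    Radial is the outward normal of the local ellipsoidal level set;
    longitudinal is the long axis projected onto the wall tangent plane
    (with an arbitrary tangent fallback near the apex pole where the two are
    parallel); circumferential completes the right-handed triple.
    """
    normal = 2.0 * rel / semiaxes ** 2
    nrm = np.linalg.norm(normal, axis=-1, keepdims=True)
    nrm[nrm == 0] = 1.0
    radial = normal / nrm

    laxis = np.array([0.0, 0.0, 1.0])
    long_t = laxis - (radial @ laxis)[..., None] * radial
    lnorm = np.linalg.norm(long_t, axis=-1, keepdims=True)
    degenerate = lnorm[..., 0] < 1e-8
    if np.any(degenerate):
        fallback = np.cross(radial[degenerate], np.array([0.0, 1.0, 0.0]))
        fb = np.linalg.norm(fallback, axis=-1, keepdims=True)
        fb[fb == 0] = 1.0
        long_t[degenerate] = fallback / fb
        lnorm = np.linalg.norm(long_t, axis=-1, keepdims=True)
    longitudinal = long_t / lnorm
    circumferential = np.cross(longitudinal, radial)

    directions = np.zeros(mask.shape + (3, 3))
    directions[..., 0, :] = radial
    directions[..., 1, :] = circumferential
    directions[..., 2, :] = longitudinal
    directions[~mask] = 0.0
    return directions


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------

@dataclass
class MotionParams:
    """Ground-truth motion amplitudes for one synthetic cycle.

    Defaults give a physiologically plausible mid-range LV contraction:
    ~15% radial wall motion, 8 deg apex-base torsion and 8% long-axis
    shortening peaking at end-systole (~40% of the cycle).
    """

    n_frames: int = 16
    es_frame: int = 6
    thickening_amp: float = 0.15
    twist_amp_deg: float = 8.0
    shortening_amp: float = 0.08
    temporal_profile: str = "raised_cosine"
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 8:
            raise ValueError("need at least 8 frames")
        if not (0 < self.es_frame < self.n_frames - 1):
            raise ValueError("es_frame must lie strictly inside the cycle")


def temporal_profile(params: MotionParams) -> np.ndarray:
    """Raised-cosine activation: 0 (with zero slope) at both cycle ends,
    peak 1 at the ES frame."""
    if params.temporal_profile != "raised_cosine":
        raise ValueError(f"unknown profile {params.temporal_profile!r}")
    t = np.arange(params.n_frames, dtype=float)
    es, T = params.es_frame, params.n_frames - 1
    p = np.where(
        t <= es,
        0.5 * (1.0 - np.cos(np.pi * t / es)),
        0.5 * (1.0 - np.cos(np.pi * (T - t) / (T - es))),
    )
    return p


def make_ground_truth_motion(geometry: LVGeometry, params: MotionParams,
                             infarct_mask: Optional[np.ndarray] = None,
                             deficit: float = 0.0) -> DisplacementField4D:
    """Analytic periodic Lagrangian motion u(x, t) = p(t) * [thickening +
    twist + shortening] on the masked voxels.

    * thickening: in-plane motion toward the axis, largest at mid-wall and
      vanishing at the epicardial waist, giving a positive radial strain of
      order ``thickening_amp`` across the wall;
    * twist: exact (volume-preserving) rotation about the long axis, angle
      linear from 0 at the base plane to ``twist_amp_deg`` at the apex;
    * shortening: uniform longitudinal strain ``-shortening_amp`` toward the
      base.

    ``infarct_mask`` with ``deficit`` in (0, 1] scales the thickening and
    twist amplitudes down inside the infarct (1 = akinetic).  The field's
    ``meta`` reports the median |divergence| of the full motion at ES.
    """
    p = temporal_profile(params)
    coords = geometry.voxel_coords_mm()
    rel = coords - geometry.center_mm
    dx, dy, dz = rel[..., 0], rel[..., 1], rel[..., 2]

    amp_scale = np.ones(geometry.grid_shape)
    if infarct_mask is not None and deficit > 0:
        amp_scale[infarct_mask] = 1.0 - deficit

    rho = np.hypot(dx, dy)
    r_epi = geometry.epi_semiaxes_mm[0]
    # inward in-plane motion, zero at the epicardial waist and at the axis:
    # u_rho = -amp * rho (R - rho) / R, smooth through the apex pole
    thick_coef = -params.thickening_amp * amp_scale * (r_epi - rho) / r_epi
    ux_th = thick_coef * dx
    uy_th = thick_coef * dy

    apex_depth = geometry.epi_semiaxes_mm[2]
    frac = np.clip(-dz / apex_depth, 0.0, 1.0)   # 0 at base plane, 1 at apex
    alpha_max = np.deg2rad(params.twist_amp_deg) * frac * amp_scale

    uz_sh = params.shortening_amp * (-dz)        # toward the base (+z)

    T = params.n_frames
    values = np.zeros(geometry.grid_shape + (T, 3))
    for t in range(T):
        a = alpha_max * p[t]
        ca, sa = np.cos(a), np.sin(a)
        ux_tw = dx * ca - dy * sa - dx
        uy_tw = dx * sa + dy * ca - dy
        values[..., t, 0] = p[t] * ux_th + ux_tw
        values[..., t, 1] = p[t] * uy_th + uy_tw
        values[..., t, 2] = p[t] * uz_sh
    values[~geometry.mask] = 0.0

    field = DisplacementField4D(values, geometry.spacing_mm, geometry.mask,
                                reference="lagrangian")
    from .fields import divergence as _div
    div_es = _div(field, params.es_frame)
    field.meta["median_abs_divergence_es_per_mm"] = float(
        np.median(np.abs(div_es[geometry.mask])))
    field.meta["motion_params"] = asdict(params)
    return field


def sample_sparse_trajectories(field: DisplacementField4D, n_points: int = 2250,
                               seed: int = 0) -> SparseTrajectorySet:
    """Sample material points uniformly without replacement from the mask;
    the default count matches a typical sparse ground-truth trajectory set."""
    idx = np.argwhere(field.mask)
    if n_points > len(idx):
        raise ValueError(f"n_points {n_points} exceeds mask size {len(idx)}")
    rng = np.random.default_rng(seed)
    sel = idx[rng.choice(len(idx), size=n_points, replace=False)]
    ed = sel * np.asarray(field.spacing_mm) + np.asarray(field.origin_mm)
    disp = field.values[sel[:, 0], sel[:, 1], sel[:, 2]]
    return SparseTrajectorySet(np.arange(n_points), ed, disp.copy())


# ---------------------------------------------------------------------------
# tracking-noise corruption
# ---------------------------------------------------------------------------

@dataclass
class NoisePreset:
    """Qualitative emulation of one tracker's error structure.

    ``rfbm_like``: speckle-tracking style — moderate correlated noise, strongly
    degraded in a 2-voxel band at the wall surface, occasional outliers.
    ``fnt_like``: surface-tracking style — accurate near the wall surface,
    smoother interpolated (degraded) errors in the interior.
    ``ffd_like``: registration style — over-smoothed (long-correlation) errors
    with a cumulative per-frame temporal drift.
    ``white``: uncorrelated Gaussian noise, no structure.
    """

    name: str = "white"
    sigma_mm: float = 1.0
    correlation_length_mm: float = 0.0
    boundary_degradation: float = 0.0
    interior_degradation: float = 0.0
    drift_per_frame_mm: float = 0.0
    outlier_rate: float = 0.0
    seed: int = 0

    _DEFAULTS = {
        "rfbm_like": dict(sigma_mm=1.0, correlation_length_mm=1.5,
                          boundary_degradation=1.0, outlier_rate=0.02),
        "fnt_like": dict(sigma_mm=0.8, correlation_length_mm=3.0,
                         interior_degradation=1.0),
        "ffd_like": dict(sigma_mm=0.5, correlation_length_mm=4.0,
                         drift_per_frame_mm=0.05),
        "white": dict(),
    }

    def __post_init__(self):
        if self.name not in self._DEFAULTS:
            raise ValueError(f"unknown preset {self.name!r}")
        for v, nm in [(self.sigma_mm, "sigma_mm"),
                      (self.correlation_length_mm, "correlation_length_mm"),
                      (self.boundary_degradation, "boundary_degradation"),
                      (self.interior_degradation, "interior_degradation"),
                      (self.drift_per_frame_mm, "drift_per_frame_mm")]:
            if v < 0:
                raise ValueError(f"{nm} must be nonnegative")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be a probability")

    @classmethod
    def named(cls, name: str, sigma_mm: Optional[float] = None,
              seed: int = 0, **overrides) -> "NoisePreset":
        kw = dict(cls._DEFAULTS[name])
        kw.update(overrides)
        if sigma_mm is not None:
            kw["sigma_mm"] = sigma_mm
        return cls(name=name, seed=seed, **kw)


def corrupt_field(field: DisplacementField4D, preset: NoisePreset) -> DisplacementField4D:
    """Add tracker-style noise to a Lagrangian field (ED frame left exactly zero).

    Spatially correlated Gaussian noise (Gaussian-filtered white noise
    rescaled back to ``sigma_mm``), amplified by ``1 + boundary_degradation``
    within 2 voxels of the mask surface (and by ``1 + interior_degradation``
    elsewhere in the mask), with ``outlier_rate`` of masked voxel-frames
    replaced by 3-sigma noise and, if requested, a cumulative per-frame drift.
    """
    if field.reference != "lagrangian":
        raise ValueError("corruption is defined on Lagrangian fields")
    out = field.copy()
    if (preset.sigma_mm == 0 and preset.outlier_rate == 0
            and preset.drift_per_frame_mm == 0):
        out.meta["noise_preset"] = asdict(preset)
        return out

    rng = np.random.default_rng(preset.seed)
    mask = field.mask
    band = mask & ~ndimage.binary_erosion(mask, iterations=2)
    amp = np.ones(mask.shape)
    amp[band] *= 1.0 + preset.boundary_degradation
    amp[mask & ~band] *= 1.0 + preset.interior_degradation

    spacing = np.asarray(field.spacing_mm)
    sig_vox = preset.correlation_length_mm / spacing
    drift_dir = rng.normal(size=3)
    drift_dir /= np.linalg.norm(drift_dir)

    T = field.n_frames
    for t in range(1, T):
        for c in range(3):
            noise = rng.standard_normal(mask.shape)
            if preset.correlation_length_mm > 0:
                noise = ndimage.gaussian_filter(noise, sigma=sig_vox)
                noise /= max(noise.std(), 1e-12)
            noise *= preset.sigma_mm * amp
            if preset.outlier_rate > 0:
                hit = rng.random(mask.shape) < preset.outlier_rate
                noise[hit] = rng.standard_normal(int(hit.sum())) * 3.0 * preset.sigma_mm
            out.values[..., t, c] += np.where(mask, noise, 0.0)
        if preset.drift_per_frame_mm > 0:
            out.values[mask, t, :] += preset.drift_per_frame_mm * t * drift_dir

    out.meta["noise_preset"] = asdict(preset)
    return out


# ---------------------------------------------------------------------------
# infarct wedge
# ---------------------------------------------------------------------------

def make_infarct_mask(geometry: LVGeometry, center_direction_deg: float = 0.0,
                      angular_extent_deg: float = 90.0,
                      long_extent_frac: float = 0.5) -> np.ndarray:
    """Wedge of masked voxels about the long axis: azimuth within
    ``angular_extent_deg`` of ``center_direction_deg`` and within the apical
    ``long_extent_frac`` of the shell's long extent (measured from the apex)."""
    if angular_extent_deg < 0 or long_extent_frac < 0:
        raise ValueError("extents must be positive")
    if angular_extent_deg == 0 or long_extent_frac == 0:
        return np.zeros(geometry.grid_shape, dtype=bool)

    rel = geometry.voxel_coords_mm() - geometry.center_mm
    theta = np.degrees(np.arctan2(rel[..., 1], rel[..., 0]))
    dtheta = np.abs((theta - center_direction_deg + 180.0) % 360.0 - 180.0)
    in_wedge = (dtheta <= angular_extent_deg / 2.0
                if angular_extent_deg < 360.0
                else np.ones(geometry.grid_shape, dtype=bool))

    apex_depth = geometry.epi_semiaxes_mm[2]
    frac_from_apex = 1.0 + rel[..., 2] / apex_depth   # 0 at apex, 1 at base plane
    in_long = (frac_from_apex <= long_extent_frac
               if long_extent_frac < 1.0
               else np.ones(geometry.grid_shape, dtype=bool))
    return geometry.mask & in_wedge & in_long
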