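"""Evaluation metrics and the infarct-detection procedure.

Median tracking error between estimated and ground-truth displacement
fields, median strain error, Pearson correlation of peak strains against a
reference (e.g. crystal-derived), strain-threshold infarct masks and the
DICE overlap coefficient.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field, asdict
from typing import Optional

import numpy as np
from scipy import ndimage, stats

from .fields import DisplacementField4D
from .strain import StrainField

__all__ = [
    "MetricsReport",
    "median_tracking_error",
    "strain_error",
    "pearson_peak_strain",
    "threshold_infarct",
    "dice",
]


@dataclass
class TrackingError:
    per_frame_mm: np.ndarray    # (T,) median over masked voxels per frame
    pooled_mm: float            # median over all masked voxel-frames (frames >= 1)
    iqr_mm: tuple               # (25th, 75th) percentiles of the pooled errors
    n_samples: int


def median_tracking_error(estimated: DisplacementField4D,
                          truth: DisplacementField4D) -> TrackingError:
    """Per-frame and pooled median Euclidean tracking error (mm).

    The pooled median spans all masked voxel-frames excluding the ED frame,
    which is identically zero for Lagrangian fields by construction and
    carries no tracking information.
    """
    _check_grids(estimated, truth)
    diff = estimated.values[estimated.mask] - truth.values[truth.mask]
    err = np.linalg.norm(diff, axis=-1)                 # (n_vox, T)
    per_frame = np.median(err, axis=0)
    pooled = err[:, 1:].ravel()
    return TrackingError(per_frame, float(np.median(pooled)),
                         (float(np.percentile(pooled, 25)),
                          float(np.percentile(pooled, 75))),
                         n_samples=pooled.size)


def strain_error(estimated: StrainField, truth: StrainField,
                 direction: str = "radial") -> float:
    """Median |estimated - true| strain over masked voxel-frames, in strain
    percentage points (0.02 strain offset -> 2.0)."""
    if estimated.tensors.shape != truth.tensors.shape:
        raise ValueError("strain fields are on different grids")
    if direction == "principal":
        est, tru = estimated.principal, truth.principal
    else:
        est = estimated.projections[direction]
        tru = truth.projections[direction]
    mask = estimated.mask
    d = np.abs(est[mask] - tru[mask])
    return float(np.median(d) * 100.0)


def pearson_peak_strain(est_peaks, ref_peaks) -> float:
    """Sample Pearson correlation between image-derived and reference peak
    strains (the crystal-validation statistic)."""
    est = np.asarray(est_peaks, dtype=float)
    ref = np.asarray(ref_peaks, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("peak-strain vectors must be equal-length 1-D")
    if len(est) < 3:
        raise ValueError("need at least 3 samples")
    if est.std() == 0 or ref.std() == 0:
        raise ValueError("undefined correlation: zero variance input")
    return float(stats.pearsonr(est, ref).statistic)


def threshold_infarct(strain_map: np.ndarray, threshold: float,
                      mask: np.ndarray, below: bool = True,
                      largest_component: bool = False) -> np.ndarray:
    """Hypokinesis mask: myocardium voxels with strain below (default) or
    above the threshold; optionally keep only the largest connected
    component."""
    strain_map = np.asarray(strain_map)
    sel = strain_map < threshold if below else strain_map > threshold
    out = sel & mask
    if largest_component and out.any():
        lab, n = ndimage.label(out)
        sizes = ndimage.sum_labels(out, lab, index=np.arange(1, n + 1))
        out = lab == (1 + int(np.argmax(sizes)))
    return out


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """DICE overlap 2|A^B| / (|A|+|B|); both-empty is defined as 1.0 (flagged
    with a warning)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks are on different grids")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        warnings.warn("DICE of two empty masks: defined as 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


@dataclass
class MetricsReport:
    """Aggregated evaluation of one pipeline run."""

    median_tracking_error_mm: Optional[dict] = None
    strain_error_pct: dict = dc_field(default_factory=dict)
    pearson_r: Optional[float] = None
    dice: Optional[float] = None
    n_samples: Optional[int] = None
    config_fingerprint: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.dice is not None and not 0.0 <= self.dice <= 1.0:
            raise ValueError("dice must lie in [0, 1]")
        if self.pearson_r is not None and not -1.0 <= self.pearson_r <= 1.0:
            raise ValueError("pearson_r must lie in [-1, 1]")

    def to_json(self, path: str) -> None:
        def _clean(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: _clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_clean(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x
        with open(path, "w") as fh:
            json.dump(_clean(asdict(self)), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "MetricsReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def _check_grids(a: DisplacementField4D, b: DisplacementField4D) -> None:
    if (a.grid_shape != b.grid_shape or a.n_frames != b.n_frames
            or not np.array_equal(a.mask, b.mask)):
        raise ValueError("fields have mismatched grid, frames or mask")
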