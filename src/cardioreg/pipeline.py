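"""End-to-end pipeline: simulate -> corrupt -> (densify) -> patch -> train ->
regularize -> strain -> evaluate.

A :class:`PipelineConfig` holds every stage's parameters and serializes
losslessly to YAML; :func:`run_pipeline` executes the stages, writes all
intermediates (NIfTI fields, model checkpoint, JSON metrics, JSONL stage
log) beside the outputs, and returns the :class:`MetricsReport`.

One global seed fans out deterministically to per-stage seeds (hash of the
stage name mixed with the global seed) so that stages can be re-run
standalone with identical randomness.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import phantom as ph
from . import evaluation as ev
from .fields import DisplacementField4D, fit_rbf_dense
from .regularizer import TrainConfig, DisplacementRegularizer
from .strain import strain_from_displacement

__all__ = ["PipelineConfig", "PhantomConfig", "NoiseConfig", "PatchConfig",
           "run_pipeline", "stage_seed"]


def stage_seed(stage: str, global_seed: int) -> int:
    h = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


@dataclass
class PhantomConfig:
    grid_shape: tuple = (32, 32, 32)
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    endo_semiaxes_mm: tuple = (6.0, 6.0, 8.5)
    epi_semiaxes_mm: tuple = (12.0, 12.0, 13.5)
    n_frames: int = 16
    es_frame: int = 6
    thickening_amp: float = 0.15
    twist_amp_deg: float = 8.0
    shortening_amp: float = 0.08
    n_sparse: int = 2250


@dataclass
class NoiseConfig:
    preset: str = "rfbm_like"
    sigma_mm: Optional[float] = None


@dataclass
class PatchConfig:
    patch_xyz: tuple = (5, 5, 5)
    stride: tuple = (2, 2, 2)


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    phantom: PhantomConfig = dc_field(default_factory=PhantomConfig)
    noise: NoiseConfig = dc_field(default_factory=NoiseConfig)
    patch: PatchConfig = dc_field(default_factory=PatchConfig)
    train: TrainConfig = dc_field(default_factory=TrainConfig)
    semisupervised: bool = False
    densify_truth: bool = False
    strain_convention: str = "green_lagrange"

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("phantom", PhantomConfig), ("noise", NoiseConfig),
                         ("patch", PatchConfig), ("train", TrainConfig)):
            if key in d and isinstance(d[key], dict):
                kw = {k: (tuple(v) if isinstance(v, list) else v)
                      for k, v in d[key].items()}
                d[key] = sub(**kw)
        return cls(**d)


def _plain(x):
    if isinstance(x, dict):
        return {k: _plain(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_plain(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x


class _StageLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def __call__(self, stage: str, **stats):
        rec = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
               **_plain(stats)}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def run_pipeline(config: PipelineConfig) -> ev.MetricsReport:
    """Execute the full train/test pipeline on the synthetic phantom.

    Training pairs come from one noise realization; evaluation uses an
    independent realization of the same preset on the same ground truth.
    Deterministic given the global seed.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out / "stages.jsonl")
    config.to_yaml(str(out / "config.yaml"))
    pc = config.phantom

    t0 = time.time()
    geom = ph.make_lv_geometry(pc.grid_shape, pc.spacing_mm,
                               pc.endo_semiaxes_mm, pc.epi_semiaxes_mm)
    motion = ph.MotionParams(n_frames=pc.n_frames, es_frame=pc.es_frame,
                             thickening_amp=pc.thickening_amp,
                             twist_amp_deg=pc.twist_amp_deg,
                             shortening_amp=pc.shortening_amp,
                             seed=stage_seed("simulate", config.seed))
    truth = ph.make_ground_truth_motion(geom, motion)
    log("simulate", mask_voxels=int(geom.mask.sum()),
        median_abs_div=truth.meta["median_abs_divergence_es_per_mm"],
        wall_time=time.time() - t0)

    if config.densify_truth:
        t0 = time.time()
        sparse = ph.sample_sparse_trajectories(
            truth, min(pc.n_sparse, int(geom.mask.sum())),
            seed=stage_seed("sparse", config.seed))
        dense = np.zeros_like(truth.values)
        for f in range(1, pc.n_frames):
            _, dense[..., f, :] = fit_rbf_dense(sparse, geom, f)
        truth_train = DisplacementField4D(dense, truth.spacing_mm, truth.mask)
        log("densify", n_sparse=sparse.n_points, wall_time=time.time() - t0)
    else:
        truth_train = truth

    t0 = time.time()
    preset_train = ph.NoisePreset.named(config.noise.preset,
                                        sigma_mm=config.noise.sigma_mm,
                                        seed=stage_seed("corrupt-train", config.seed))
    preset_eval = ph.NoisePreset.named(config.noise.preset,
                                       sigma_mm=config.noise.sigma_mm,
                                       seed=stage_seed("corrupt-eval", config.seed))
    noisy_train = ph.corrupt_field(truth, preset_train)
    noisy_eval = ph.corrupt_field(truth, preset_eval)
    log("corrupt", preset=config.noise.preset, wall_time=time.time() - t0)

    t0 = time.time()
    model = DisplacementRegularizer.from_fields(
        noisy_train, truth_train,
        target_field=noisy_eval if config.semisupervised else None,
        patch_xyz=config.patch.patch_xyz, stride=config.patch.stride,
        config=config.train)
    results = model.fit()
    results.save(str(out / "model.npz"))
    log("train", best_epoch=results.best_epoch,
        best_val_loss=results.best_val_loss, wall_time=time.time() - t0)

    t0 = time.time()
    regularized = results.regularize_field(noisy_eval)
    truth.to_nifti(str(out / "truth.nii.gz"))
    noisy_eval.to_nifti(str(out / "noisy.nii.gz"))
    regularized.to_nifti(str(out / "regularized.nii.gz"))
    log("regularize", wall_time=time.time() - t0)

    t0 = time.time()
    s_true = strain_from_displacement(truth, geom,
                                      convention=config.strain_convention)
    s_reg = strain_from_displacement(regularized, geom,
                                     convention=config.strain_convention)
    log("strain", wall_time=time.time() - t0)

    t0 = time.time()
    te_noisy = ev.median_tracking_error(noisy_eval, truth)
    te_reg = ev.median_tracking_error(regularized, truth)
    strain_errors = {d: ev.strain_error(s_reg, s_true, d)
                     for d in ("radial", "circumferential", "longitudinal")}
    report = ev.MetricsReport(
        median_tracking_error_mm={
            "noisy_pooled": te_noisy.pooled_mm,
            "regularized_pooled": te_reg.pooled_mm,
            "noisy_per_frame": te_noisy.per_frame_mm.tolist(),
            "regularized_per_frame": te_reg.per_frame_mm.tolist(),
        },
        strain_error_pct=strain_errors,
        n_samples=te_reg.n_samples,
        config_fingerprint={"seed": config.seed,
                            "preset": config.noise.preset,
                            "semisupervised": config.semisupervised},
    )
    report.to_json(str(out / "metrics.json"))
    log("evaluate", noisy_mte=te_noisy.pooled_mm, reg_mte=te_reg.pooled_mm,
        wall_time=time.time() - t0)
    return report
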