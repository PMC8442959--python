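# cardioreg

Learning-based spatiotemporal regularization and strain analysis for 4D
(3D + time) cardiac displacement fields.

## The problem

Motion tracking in 4D echocardiography — speckle/block matching, surface
tracking, nonrigid registration — produces dense Lagrangian displacement
fields **U**(x, t) of the left-ventricular myocardium that are too noisy for
reliable regional strain analysis. `cardioreg` regularizes such fields with
a patch-based multilayer perceptron and derives the downstream clinical
quantities: radial / circumferential / longitudinal and principal strain,
peak and rest–stress differential strain, and threshold-based infarct
localization. It is aimed at researchers developing echocardiographic
motion-analysis pipelines who need a testable, self-contained
implementation of the full chain.

## The model

Whole-cycle 4D patches (default 5×5×5 voxels × T frames × 3 components,
flattened) are mapped through a fully connected network f(·; θ):

* **Supervised regularization** (labelled data with ground-truth motion):

      θ* = argmin (1/N) Σᵢ log cosh[ U_true⁽ⁱ⁾ − f(U_noise⁽ⁱ⁾; θ) ]

  a smooth Huber-like loss (L2 for small residuals, L1 for large), with
  identity pairs (U_true, U_true) appended so clean patches are not biased.

* **Semi-supervised domain adaptation** (unlabeled target domain, e.g.
  in vivo): the supervised term, weighted λ_super, plus a biomechanical
  objective on target patches

      Σᵢ ‖U_noise − U_pred‖² + λ_div Σ_t ‖∇·U_pred(t)‖² + λ_loop Σ_t ‖∂U_pred/∂t‖²

  enforcing near-incompressibility of myocardial tissue (low divergence)
  and soft cyclic periodicity of cardiac motion.

* **Multi-view fusion**: patches from two complementary trackers are
  concatenated at the input layer; the network learns to weigh them into a
  single regularized output.

Around the network: RBF (Wendland C2) sparse-to-dense interpolation with L1
and divergence penalties, Eulerian→Lagrangian trajectory accumulation,
Green–Lagrange strain E = ½(∇u + ∇uᵀ + ∇uᵀ∇u) with wall-direction
projections, sonomicrometer-crystal trilateration and tetrahedral strain,
and evaluation metrics (median tracking error, strain error, Pearson
correlation of peak strains, DICE). A synthetic left-ventricle phantom
(thick-walled truncated ellipsoid, periodic near-incompressible motion,
tracker-style noise presets, infarct wedges) provides labelled inputs for
every stage.

## Worked example

```python
from cardioreg import phantom as ph, evaluation as ev
from cardioreg.regularizer import DisplacementRegularizer, TrainConfig

geom = ph.make_lv_geometry((32, 32, 32), (1, 1, 1), (6, 6, 8.5), (12, 12, 13.5))
truth = ph.make_ground_truth_motion(geom, ph.MotionParams(n_frames=16, es_frame=6))
noisy_train = ph.corrupt_field(truth, ph.NoisePreset.named("rfbm_like", seed=11))
noisy_eval  = ph.corrupt_field(truth, ph.NoisePreset.named("rfbm_like", seed=22))

cfg = TrainConfig(hidden_layers=3, hidden_width=256, dropout=0.0,
                  learning_rate=1e-3, epochs=12, seed=5)
results = DisplacementRegularizer.from_fields(
    noisy_train, truth, patch_xyz=(5, 5, 5), stride=(1, 1, 1), config=cfg).fit()
print(results.summary())

regularized = results.regularize_field(noisy_eval)
print("noisy      :", ev.median_tracking_error(noisy_eval, truth).pooled_mm)
print("regularized:", ev.median_tracking_error(regularized, truth).pooled_mm)
```

Output (seeds as above):

```
Displacement Regularizer Results
========================================
mode:              supervised
patch shape:       (5, 5, 5, 16, 3)
layers:            [6000, 256, 256, 256, 6000]
dropout:           0.0
parameters:        3,209,840
epochs trained:    12
best epoch:        11
best val loss:     25.6681
lambda_super:      1.0
lambda_div:        0.0
lambda_loop:       0.0
learning rate:     0.001
noisy      : 2.263366255222949
regularized: 0.2159246721115202
```

The pooled median tracking error of the σ = 1 mm speckle-tracking-like
corruption drops from ≈2.3 mm to ≈0.22 mm — the supervised regularizer
recovers the underlying smooth periodic motion from an independent noise
realization.

The same pipeline is scriptable from the shell:

```sh
cardioreg simulate --out truth.nii.gz --grid 32 --frames 16
cardioreg corrupt truth.nii.gz --out noisy.nii.gz --preset rfbm_like
cardioreg train noisy.nii.gz truth.nii.gz --out model.npz --epochs 12 \
    --learning-rate 1e-3 --hidden-width 256 --stride 1
cardioreg regularize model.npz noisy.nii.gz --out reg.nii.gz
cardioreg evaluate reg.nii.gz truth.nii.gz
```

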