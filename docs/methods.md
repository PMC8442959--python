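# Methods

This note documents the models, numerical choices and limitations of
`cardioreg`: what each component computes, which parameters matter, what
the synthetic phantom does and does not emulate, and the problem sizes used
by the test suite and the acceptance script.

## Displacement fields and conventions

A field is a grid-sampled vector function `values[x, y, z, frame,
component]` in millimetres, restricted to a myocardium mask. *Lagrangian*
fields reference every vector to the material position at end-diastole
(frame 0, identically zero there by definition — enforced by the
container); *Eulerian* fields hold frame-to-frame displacements at fixed
grid locations. Voxel indices are 0-based; physical coordinates are
`index · spacing + origin`. Eulerian fields are accumulated into Lagrangian
ones by explicit (first-order) stepping with trilinear interpolation of
each frame's field at the material point's current position; points leaving
the grid are clamped and flagged. Linear temporal interpolation was chosen
over splines: at the frame rates of interest the first-order error is
dominated by tracking noise, and the convergence test (error halving with
frame-rate doubling) documents the order.

Spatial derivatives everywhere use the same mask-aware stencils: central
differences where both axis neighbours are masked, one-sided at the mask
boundary — exact for affine fields in both regimes. The divergence is the
trace of the displacement gradient (units 1/mm). The periodicity
diagnostic reports both the cyclic residual (identically zero for a closed
cycle; `u(T−1) − u(0)` in non-cyclic mode) and the temporal-derivative
energy `Σ_t ‖u(t+1) − u(t)‖²` with cyclic wrap-around — the wrap term is
included by default because without it the soft-periodicity reading of the
loop penalty is not enforced; a flag disables it.

## Sparse-to-dense RBF interpolation

Sparse material-point displacements are densified per frame by expanding
each component in compactly supported Wendland C2 kernels centred at the
sample points, minimizing

    ‖Hw − u_sp‖² + λ₁‖w‖₁ + λ₂‖∇·u‖²

with the divergence evaluated at the sample points via analytic kernel
gradients (a grid quadrature inside the solver would cost far more and the
choice of quadrature set is free). Defaults: λ₁ = 1e-3, λ₂ = 1e-2 for
mm-scale data; support radius 4× the largest nearest-neighbour gap unless
given. With λ₁ = 0 the objective is a smooth quadratic and is solved
directly as a coupled 3K×3K linear system — this makes exact interpolation
of in-model-class data (to 1e-8) a robust contract, which a first-order
iteration cannot guarantee on ill-conditioned kernels. With λ₁ > 0 a
proximal-gradient (ISTA) iteration with backtracking handles the
non-smooth term (tolerance 1e-8 relative change, max 5000 iterations); the
recorded loss history is non-increasing by construction of the
backtracking step.

## Patches

Whole-cycle 4D patches (default 5×5×5 spatial window, full frame count, 3
components; 5×5×5×32×3 → 12 000 values at echo scale) are extracted at
grid-aligned origins with a configurable stride. The flatten order
(x, y, z, frame, component — component fastest) is frozen and serialized
with every patch set and model checkpoint because train and test time must
agree. The default inclusion rule keeps windows whose *center* voxel is
masked; `any`/`all` variants exist. Reconstruction averages overlapping
patch values per voxel (unweighted — the simplest symmetric rule), fills
uncovered masked voxels from the nearest covered voxel, flags them, and
zeroes the ED frame (a Lagrangian identity). Sequences with different
frame counts get different models; no temporal resampling is attempted.

## The regularization network

A fully connected network (rectifier activations, inverted dropout on
hidden layers, He-style init) maps flattened noisy patches to regularized
patches. Reference configuration: 3 hidden layers × 1000 units with
dropout 0.2 for supervised training on labelled data, 7 × 1000 with
dropout 0.5 for semi-supervised runs on larger pooled data; RMSProp
(running-average decay 0.9) at initial learning rate 1e-5; 100 epochs;
batch 256; validation fraction 0.15; the checkpoint with the lowest
validation objective is returned. Patch values are standardized per
displacement component by training-set statistics stored in the model
(mm-scale inputs train impractically slowly otherwise); losses and
gradients are computed on the physical scale by chaining through the
de-standardization, so reported losses are in mm units.

The supervised objective is the mean per-patch log-cosh of the residual,
computed overflow-safely as `|r| + log(1 + e^(−2|r|)) − log 2`. Identity
pairs (truth → truth) are appended in supervised mode so the network does
not bias low-error patches; in semi-supervised mode they are off by
default (the synthetic pairs there serve a different role and the target
data term already anchors the output scale).

The biomechanical objective on unlabeled target patches is

    Σᵢ ‖U_noise − U_pred‖² + λ_div Σ_t ‖div U_pred(t)‖² + λ_loop Σ_t ‖∂U_pred/∂t‖²

with squared error (not log-cosh) for the data term, divergence by central
differences on the 3×3×3 interior of each 5³ window (patch-boundary voxels
contribute no stencil), and cyclic forward temporal differences (soft
periodicity). Both loss and analytic gradient are exercised against
explicit-loop oracles and finite differences in the tests. Per input
method the weights follow the presets (λ_div, λ_loop): speckle-tracking-
like (0.5, 0.5), surface-tracking-like (0, 1), registration-like
(0.5, 0.5); λ_super = 1. Synthetic and target mini-batches alternate 1:1
(each takes its own optimizer step); the combined validation objective
drives model selection. Training aborts with a diagnostic on non-finite
loss.

Multi-view fusion concatenates two views' patches at the input layer
(input 2D, output D). With two identical views the fused network is
algebraically identical to a single-view network whose first-layer weight
blocks are summed — a weight-surgery identity the tests verify.
Prediction is deterministic (dropout inactive, no randomness); the
last-hidden-layer activations can be exported with domain labels for
external 2-D embedding (e.g. t-SNE) to inspect domain mixing.

## Strain

Dense-field strain uses the deformation gradient F = I + ∇u from the same
mask-aware stencils. Default convention is Green–Lagrange
E = ½(∇u + ∇uᵀ + ∇uᵀ∇u), exactly invariant under superposed rigid
rotation — appropriate for the finite deformations of ischemic
myocardium; the infinitesimal tensor is an option for comparison.
Projections are eᵀEe along the local radial / circumferential /
longitudinal directions; principal strain is the algebraically largest
eigenvalue (not the largest in magnitude: principal strain tracks the
radial-like positive deformation). Peak strain is the signed value of the
largest-magnitude excursion over frames. Differential strain is defined
stress − rest (positive = recruitable deformation; the opposite sign
convention exists in the literature, so the orientation is documented and
trivial to flip).

Crystal strain: three reference crystals on the transducer (two facing
crystals 28 mm apart, a third 13 mm from the probe-surface center, in a
plane 5 mm above the fan apex) define three sphere equations per
myocardial crystal; trilateration returns the intersection on the imaging
side of the reference plane, raising a residual-carrying error for
inconsistent distances and a degenerate-configuration error for collinear
references. Each 8-crystal cube yields 70 tetrahedral 4-subsets; subsets
with ED volume below 1% of (cube volume / 6) are discarded as degenerate
(58 survive for an exact cube — the 12 coplanar quadruples on faces and
diagonal planes; ~50 for realistic perturbed geometries, and the filter
threshold is a documented choice, not a contract). Per tetrahedron the
affine F maps ED edges to deformed edges and E = ½(FᵀF − I); the cube
tensor is the element-wise median (the natural robust aggregate; a
matrix-valued median would need an arbitrary ordering), its largest
eigenvalue the principal strain.

## Evaluation

Median tracking error: per-voxel-frame Euclidean displacement difference;
per-frame medians plus a pooled median (with interquartile range) over all
masked voxel-frames *excluding the ED frame*, which is identically zero
for Lagrangian fields and carries no tracking information. Strain error is
the median |estimated − true| in strain percentage points (a 0.02 strain
offset = 2.0 points). Peak-strain agreement uses the sample Pearson
correlation (undefined-variance inputs rejected). Infarct prediction
thresholds a peak or differential strain map *below* a threshold
(hypokinesis for positive-valued principal/radial-like strain; a flag
inverts), optionally keeping the largest connected component; DICE is
2|A∩B|/(|A|+|B|) with the both-empty case defined as 1.0 and flagged.

## The phantom

The phantom supplies what the method needs and nothing more: displacement
fields, not images (no speckle, no B-mode/RF synthesis).

* **Geometry**: voxelized shell between coaxial ellipsoids, truncated at
  the basal plane z = center (an untruncated closed ellipsoid is
  unrepresentative of LV topology); per-voxel orthonormal wall directions
  from the local ellipsoidal normal (radial), the long axis projected onto
  the tangent plane (longitudinal, with an arbitrary-tangent fallback at
  the apex pole) and their cross product.
* **Motion**: analytic u(x, t) = p(t) · [thickening + twist + shortening],
  p a raised-cosine window that is exactly zero (with zero slope) at both
  cycle ends and peaks at the ES frame — periodicity holds by
  construction, which the loop term assumes. The twist is an exact
  rotation about the long axis (angle linear from base to apex), hence
  volume-preserving — a near-divergence-free test field; thickening is
  in-plane motion toward the axis vanishing at the epicardial waist and at
  the axis (smooth through the apex); shortening is a uniform longitudinal
  strain toward the base. The field's metadata reports the measured median
  |divergence| at ES. Defaults (16 frames, ES at frame 6, 15% thickening,
  8° twist, 8% shortening) give a plausible mid-range contraction with
  peak displacements of 1–3 mm.
* **Noise presets** (qualitative emulations — the error statistics of real
  trackers are not published, so no calibration is claimed):
  speckle-tracking-like (σ = 1 mm, 1.5 mm correlation, 2× amplification
  within 2 voxels of the wall surface, 2% outliers at 3σ),
  surface-tracking-like (σ = 0.8 mm, 3 mm correlation, 2× amplification in
  the interior — the complement of a surface-accurate tracker; this
  *interior* degradation field is an addition the boundary-only
  parameterization cannot express), registration-like (σ = 0.5 mm, 4 mm
  correlation, cumulative per-frame drift), and white. Correlated noise is
  Gaussian-filtered white noise rescaled to σ; the ED frame is never
  touched; σ = 0 with no outliers and no drift is the identity.
* **Infarct**: an angular wedge about the long axis within an apical
  fraction of the shell; motion deficit scales thickening and twist down
  inside it.

What passing tests on the phantom do **not** show: performance under real
ultrasound artifacts (speckle decorrelation, shadowing, probe motion),
anatomically realistic fiber-driven motion, or tracker error statistics
beyond the qualitative structures above. The phantom's motion lies in a
low-dimensional analytic family, which makes supervised denoising easier
than on data with richer motion variability.

## Scaled-down study protocols

The benchmark experiments (also driven by `scripts/acceptance.py`) run on
one CPU in minutes: a 32³ grid at 1 mm spacing, 16 frames, a ~6 mm-thick
wall (≈3.4k masked voxels — thick enough that the 2-voxel surface band and
the interior are both substantial, otherwise the boundary/interior noise
presets would not actually be complementary), stride-1 patch extraction
(≈3.4k patches; ≈7k supervised samples with identity augmentation), and a
3-hidden-layer MLP of width 256 (denoising) or 128 (domain adaptation,
fusion) — the architecture scales to the 3×1000 reference configuration.
For these short runs the optimizer uses learning rate 1e-3 on standardized
patches with 12–25 epochs (batch 128 in the fusion study), and dropout is
disabled: rates calibrated for 1000-wide layers over-regularize layers
4–8× narrower (the fusion model in particular stalls at a mean-prediction
plateau with dropout 0.2 at width 128). The full-scale defaults (lr 1e-5,
100 epochs, dropout 0.2/0.5) remain the `TrainConfig` defaults.

The domain-adaptation study trains source (labelled) and target
(unlabeled, different geometry and motion amplitudes) phantoms with the
(0.5, 0.5) constraint preset versus (0, 0), sharing all seeds so the only
difference is the constraint gradients, and evaluates on a held-out target
noise realization. The fusion study trains both single-view models and the
fused model with identical budgets and compares pooled median tracking
errors on held-out realizations; its training set pools two independent
noise realizations per view — the desk-scale stand-in for training across
sequences — because with a single realization the overlapping stride-1
patches leak realization-specific noise into the validation split and the
double-width fusion model overfits it (low validation loss, degraded
held-out error). The infarct study needs no training:
rest (mild contraction, 30% wedge deficit) and stress (doubled amplitudes,
85% deficit — the wedge cannot recruit) ground-truth fields give peak
principal-strain maps, their difference is thresholded over a swept range,
and the best DICE against the true wedge is reported.

## Known limitations

* The MLP is trained on one phantom's motion family; nothing is claimed
  about generalization across hearts (the full-scale protocol trains
  across sequences).
* The RBF solver's direct path scales as O(K³) in the number of sparse
  points per frame; the ISTA path is preferred beyond a few thousand.
* Crystal localization assumes an exactly known reference geometry; errors
  there propagate rigidly into all crystal positions.
* `differential_strain` and the threshold direction encode one sign
  convention each; both are documented flags, not discoveries.
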