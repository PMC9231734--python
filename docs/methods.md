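# Methods

`fluoropose` estimates the 6D poses (three translations, three rotational
degrees of freedom) of the femoral and tibial components of a knee
replacement from a single-plane fluoroscopic image, given the two
component surface meshes. This note documents the model, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Imaging model

The fluoroscope is modelled as an ideal pinhole: a point source, an image
intensifier at focal distance `f` (default 970 mm), square pixels of
pitch `p` mm (0.3 mm at 1000 px, rescaled with the working resolution),
and the principal point at the image centre. The camera frame is
right-handed with `x` right, `y` down (the image `v` axis), and `z` along
the optical axis toward the intensifier; pixel `(0, 0)` is top-left with
pixel centres at half-integers. All lengths are millimetres throughout.
A point at `(x, y, z)` projects to `u = f·x/(z·p) + c_x` (likewise `v`).
Poses annotated under a different native geometry are re-expressed under
the standard camera by rescaling depth to preserve magnification
`f/(z·p)` and shifting the in-plane translation so the projected object
centre lands on the same pixel — i.e. standardisation is defined as
projection-preserving at the silhouette centroid, exact at the object
centre and first-order elsewhere.

Implants are nearly radio-opaque, so their appearance is reduced to the
binary silhouette ("shadow"): a pixel is foreground iff its centre lies
inside the perspective projection of at least one mesh triangle. The
rasteriser does exact point-in-triangle tests with the top-left edge
rule; there is no anti-aliasing, matching the binarised segmentation
targets the loss is defined on. The two-component shadow is the
pixel-wise union of the component shadows (attenuation is cumulative, so
occlusion ordering is irrelevant after binarisation). A numba-compiled
kernel and a vectorised NumPy fallback implement the identical
rasterisation; tests compare both against an independent 3D ray-caster.

## Pose representation

Each component pose is a rotation matrix plus a translation. For
regression, rotations use the continuous 6D encoding — the first two
matrix columns, decoded back to SO(3) by Gram–Schmidt — which avoids the
discontinuities of Euler angles and quaternions and stays decodable under
additive noise. The joint regression target is the 18-vector
`[t_fem (3), r6d_fem (6), t_tib (3), r6d_tib (6)]`.

Euler angles (intrinsic x–y–z by default, configurable) appear only in
human-readable outputs. Per-axis rotation *errors* are computed from the
Euler decomposition of the relative rotation `R_pred·R_true^T` rather
than by differencing absolute Euler angles: the default lateral view
places the femur at the convention's gimbal-lock middle angle, where
absolute-angle differences are ill-conditioned and would inflate small
orientation errors arbitrarily; the relative decomposition is
well-conditioned everywhere and agrees with the naive difference away
from the singularity.

The geodesic distance on SO(3) — the angle of the relative rotation — is
evaluated as `atan2(‖skew(R_rel)‖, (tr(R_rel)−1)/2)`. This equals
`|arccos((tr−1)/2)|` analytically but keeps full precision near 0 and π,
where the arccos form loses about eight digits.

## Losses

* Translation: weighted L1 with in-plane components (x, y) weighted 10×
  the out-of-plane depth. Depth only changes apparent size through
  perspective and is intrinsically poorly constrained by one projection;
  the weighting deliberately spends model capacity on the observable
  components. The stated relative weight is implemented as absolute
  weights (10, 1).
* Rotation: the geodesic angle between the decoded predicted and true
  rotations. For gradients, the cosine is clamped to `±(1 − 1e−6)` so the
  arccos derivative stays finite at near-perfect predictions, and the
  Gram–Schmidt decoding in the loss path clamps vector norms at `1e−8`
  so a degenerate predicted 6D block (e.g. from an all-background
  segmentation early in training) produces a large finite loss instead of
  NaN. The strict decoder used at inference rejects degenerate encodings.
* Pose loss: the sum of the translation and rotation terms of both
  components. During training it is computed on z-scored translations
  (constants estimated over the training split and stored in the dataset
  manifest); reported errors are always in mm.
* Segmentation: the Lovász hinge — the Lovász extension of the Jaccard
  loss over per-pixel hinge errors, a convex surrogate that directly
  optimises overlap. For an empty-foreground ground truth the Jaccard set
  function's normalisation is degenerate (0/0); the loss then falls back
  to the mean hinge error, which keeps the gradient defined and simply
  penalises false positives uniformly.
* Total two-stage loss: `w·L_seg + L_pose` with `w = 10`, making the two
  terms comparable in magnitude.

All losses are per-sample; batch reduction is the mean. Together with
instance normalisation this makes gradient accumulation over micro-batches
exactly equivalent to one large batch, which the tests verify to 1e−5.

## Architecture and training

Stage one ("shadownet") segments the implant silhouette from a
2-channel input — the x-ray and a rendered-shadow feedback image (black
on the first pass) — and emits one logit map at input resolution. Stage
two ("synthnet") is a per-combination regressor from a binary silhouette
to the 18-vector. All normalisation is instance normalisation: batch
statistics are meaningless at batch sizes 1–4, and per-sample
normalisation preserves the accumulation equivalence above. Three
capacity scales share each topology: `paper` reproduces the published
backbones (a ResNeXt-50 32×4d regressor; a ResNet-50 encoder with atrous
spatial pyramid pooling for segmentation), while `tiny` and `small` are
desk-scale reductions. The tiny/small regressor heads flatten the final
feature map instead of global average pooling so silhouette position
remains directly observable to the dense layer at 64 px; the paper scale
keeps the canonical pooled head.

Training runs on a small NumPy layer framework written for this package
(`fluoropose.nn`) with explicit backpropagation; every layer's analytic
gradient is verified against finite differences in the test suite, and
all training is deterministic for a fixed seed on a fixed platform.

The regressor is pretrained per combination on rendered, binarised
shadows of Gaussian-perturbed gait-like poses (Adam, lr 2e−3, betas
(0.9, 0.99), batch 4, gradients accumulated over 32 samples, CutOut
occlusion with probability 0.3 and 4 squares of a quarter of the image
side). Personalisation freezes the first quarter of the network's
ordered top-level blocks — block count, not parameter count, so the
frozen prefix is stable across widths — and continues training; frozen
parameters are verified bit-identical afterwards. Freezing the input
blocks keeps early features consistent across personalised regressors so
they can be swapped behind one segmentation network.

The segmentation stage trains with plain SGD and no momentum against
the total loss, loading the personalised regressor of each sample's
combination with frozen weights. The protocol rate is 1e−2 for the
full-scale architecture; the desk-scale default is 3e−3, because the
tiny regressor's flattened head gives every silhouette pixel a short
high-weight path to the pose loss and the straight-through gradient then
destabilises SGD at 1e−2. Samples are grouped by
combination to minimise regressor swaps; momentum is disabled because it
would carry gradient history across a swap, where it is meaningless.
Pose-loss gradients reach the segmentation weights through the predicted
logits via a *saturated* straight-through estimator for the binarisation:
the gradient passes only where `|logit| ≤ 1`, i.e. where a small logit
change can actually flip the pixel. The unsaturated variant lets the
pose term (which is orders of magnitude larger per pixel than the
segmentation gradient) destabilise SGD. With more than one inference
iteration, the feedback render of the previous pose is treated as a
constant input (a depth-one truncation of the recursive architecture);
how gradients should interact with the rendering step is genuinely open,
and feeding raw probabilities instead of a binarised shadow is a noted
alternative that is not the default.

Inference optionally iterates: pass one feeds a black feedback image;
pass `k ≥ 2` feeds the rendered shadow of pose `k−1`. An unrenderable
intermediate pose falls back to the black image and is logged.

## Synthetic data

No public dataset of annotated implant fluoroscopy exists, so the
generator fabricates the study material:

* **Geometry.** The femoral component is two partial tori (condylar
  lobes) bridged by a box; the tibial component is an elliptical tray
  with an offset stem and an obliquely oriented keel fin. The tibial
  asymmetry is deliberate and mirrors real tibial trays: a rotationally
  symmetric stand-in would make tray rotation about its axis strictly
  unobservable from a silhouette. Dimensions are jittered a few percent
  per seed (distinct "implant models"); meshes are watertight by
  construction and sized 50–90 mm.
* **Kinematics.** Datasets are assembled from many short trials, each
  with its own depth (uniform in 400–700 mm), small fixed tilts, phase
  and amplitude; within a trial the femoral flexion follows a sinusoid
  plus drift, defaulting to 30° ± ≤25° (normal gait covers roughly
  0–60° of knee flexion), clipped to [0°, 120°]. The knee is imaged
  medio-laterally, so the flexion axis is the optical axis. Frame-to-frame
  rotation steps stay below 5°.
* **Perturbation.** Training poses are the trial poses plus independent
  zero-mean Gaussian noise on the 18 flattened components (defaults:
  5 mm in-plane, 15 mm out-of-plane, 0.05 per 6D component ≈ a few
  degrees); the 6D decoding re-orthonormalises, so noisy draws remain
  valid poses. Draws outside the renderable depth range are resampled
  (cap 100).
* **Images.** The x-ray synthesiser maps a shadow to greyscale:
  low-frequency background shading, implant darkening by a contrast
  factor, optional elliptical occluder blobs crossing the implant region
  (the contralateral leg), and Gaussian pixel noise, clipped to [0, 1].
  With nuisances off and full contrast the image is exactly `1 − shadow`.

The generator emulates silhouette geometry, occlusion and contrast loss.
It does not emulate scatter physics, intensifier distortion, anatomy
(bone, soft tissue) or annotation error; passing tests therefore
demonstrate correctness of the machinery and learnability of the mapping
under controlled conditions, not clinical-image performance.

## Evaluation

Per-sample errors: in-plane translation error `√(Δx²+Δy²)` (per-axis
columns are also emitted, since the literature uses both conventions),
out-of-plane error `|Δz|`, and per-axis relative-rotation angles in
degrees, wrapped to [0°, 180°]. Summaries are empirical quantiles
(linear interpolation, inclusive endpoints), reported per component and
pooled.

The refinement oracle maximises silhouette overlap (Jaccard) over the 12
pose degrees of freedom with Nelder–Mead, restarting from seeded
perturbations of the best-so-far (default budget 2000 evaluations over 3
restarts, a balance of desk-scale runtime against local minima). The
simplex step is 2 mm / 1.5° with 4× larger depth steps, since depth is
nearly unobservable from silhouette scale. The returned pose never has
lower overlap than the initialisation. On rotationally symmetric
geometry the rotation is unidentifiable and only translation is
recovered — the identifiability tests check exactly this.

## Problem sizes in the checked experiments

The recovery experiment trains the tiny regressor on 2000 rendered 64 px
shadows of one toy combination for 20 epochs and evaluates 150 held-out
poses; the closed-loop pipeline runs two combinations at 64 px through
simulate → pretrain → personalise → train-shadownet → predict →
evaluate; the refinement experiment runs at 256 px. These sizes are the
package's desk-scale defaults, chosen so the full suite runs on one CPU
in minutes.

## Known limitations

* Out-of-plane (depth) errors remain an order of magnitude above
  in-plane errors — inherent to single-plane projection, and the loss
  deliberately down-weights depth.
* The `paper`-scale architectures are built and shape-checked but not
  trained at full scale here; the NumPy framework is CPU-bound and the
  published training protocol is far outside desk budgets.
* Reproducibility is guaranteed per platform (BLAS differences can
  change low-order bits across machines).
* The iterative (feedback) variant is implemented with depth-one
  gradient truncation; training it to advantage is an open question even
  at full scale.
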