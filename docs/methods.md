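# Methods

This note documents the model, the numerical choices, and the synthetic study
design behind `polypose`. Everything quantitative stated here is computed by
the test-suite or by `scripts/acceptance.py`.

## Forward model

A moving attenuation volume *V* (linear attenuation coefficients, 1/mm, on a
voxel lattice with a 4×4 voxel-to-world affine) is related to each observed
X-ray *I<sub>n</sub>* by

*I<sub>n</sub> = P(Π<sub>n</sub>) ∘ V ∘ Φ*,

the composition of a deformation Φ, trilinear resampling, and Beer–Lambert
projection under pinhole geometry Π<sub>n</sub> = K<sub>n</sub>[R<sub>n</sub>|t<sub>n</sub>].

Conventions: world coordinates are millimetres; voxel indices are 0-based
with the voxel **center** as its world position; Φ maps output-lattice
coordinates into the input volume's coordinates (resampling convention), so
the warped volume is *V∘Φ* and the identity field reproduces *V* exactly at
voxel centers. Samples outside the volume evaluate to 0 (air).

### Rendering

The source sits at *S = −Rᵀt*; the detector point of pixel *p* lies on the
plane at distance *f* (source-to-detector, from K) along the optical axis.
The ray *r(λ) = S + λ(P−S)*, λ∈[0,1], is clipped to the axis-aligned support
box of the trilinear interpolant (voxel centers ± one spacing), and the line
integral is evaluated by midpoint quadrature over trilinear samples:

*I(p) = ‖P−S‖ · Σ<sub>m</sub> V[r(λ<sub>m</sub>)] · Δλ*.

The default step is half the smallest voxel spacing (Nyquist-style for a
trilinear field); a fixed per-ray sample count is also supported. Midpoint
sampling integrates the piecewise-linear interpolant along axis-aligned rays
essentially exactly: on a homogeneous cube the central-pixel error against
the analytic chord is below 1%, and halving the step changes values by less
than 0.5% (both asserted in the tests). Scatter, beam hardening, spectra, and
detector noise are outside the model.

For a fixed camera, rendering is **linear** in the voxel values, so the
projector precomputes its trilinear stencil once (`Projector`) and exposes
the exact adjoint (backprojection). This pair is the backbone of the
gradient computation: the whole pipeline is differentiated analytically in
NumPy, with no autodiff framework involved.

## SE(3) machinery

Twists are 6-vectors ordered (rotation, translation), so the optimizer's two
step sizes map onto contiguous blocks. `exp` uses Rodrigues' formula with the
SO(3) left Jacobian for the translation; `log` inverts both in closed form
and rejects rotation angles within 1e-7 of π (not unique there; registration
twists are far smaller). Coefficients switch to Taylor expansions below
θ = 1e-6 to avoid cancellation. Round-trip accuracy is better than 1e-9 over
1000 random twists with ‖rot‖ ≤ π−0.1.

The derivative of *y(η) = exp(η)·x* with respect to the twist η — needed for
pose gradients — uses the closed-form SE(3) right Jacobian (SO(3) block plus
the rotation–translation coupling block), verified against central finite
differences. The registration loop evaluates this chain in float32 (the
trigonometric coefficients stay in float64, several suffer cancellation near
θ=0); pose gradients need only a few significant digits and the final field
is rebuilt in float64.

## Polyrigid field

Per-structure weights are precomputed once on the moving volume's lattice
from Euclidean distance transforms (anisotropy-aware, mm) and held fixed
during optimization:

* mass mode (default, hyperparameter-free): *w<sub>k</sub> = m<sub>k</sub>/(1+d<sub>k</sub>²)*,
  with *m<sub>k</sub>* the normalized structure volume under a constant-density
  assumption;
* reciprocal mode: *w<sub>k</sub> = 1/(1+ε d<sub>k</sub>²)*, ε ≤ 1.

Rows of the M×K weight table are normalized to sum to 1. The fused per-voxel
twist is η(x) = Σ<sub>k</sub> W<sub>xk</sub> ξ<sub>k</sub> and the field is
Φ(x) = exp(η(x))·x̃, evaluated for all voxels with one batched exponential.
Off-lattice queries interpolate the normalized weights trilinearly (a convex
combination of rows summing to 1 still sums to 1); beyond the lattice the
weights fade to zero and the field tends to the identity. No clipping is
applied at large distances.

Direct weighted-log fusion is smooth and in practice fold-free for
anatomically plausible (non-interpenetrating) motions, but it is **not**
mathematically guaranteed diffeomorphic: driving two structures through each
other produces a small fraction of folded voxels. The synthetic generator
therefore rejection-samples motions until the ground-truth field is exactly
fold-free (see below), which is also the physically meaningful regime.

## Similarity

The objective is the mean patchwise zero-normalized cross-correlation over
two channels (raw intensity and Sobel gradient magnitude) at multiple scales
(integer block-mean downsampling factors, default {1, 2}); patch size
defaults to 13 px. Patch statistics come from uniform box filters
(mode="constant"), which are self-adjoint, so the analytic gradient with
respect to the rendered image is a short chain of the same filters; the Sobel
channel chains through the (anti-self-adjoint) Sobel convolution. The
gradient is exact for the discrete objective and is verified against finite
differences.

Two masking rules keep the score meaningful: only patches whose window fits
fully inside the image contribute (zero-padded boundary statistics are not
patch statistics), and patches where either image has zero variance are
excluded from the mean (a pair of flat images scores 0). The Sobel channel
additionally drops the outermost pixel ring, whose gradients reflect the
padding rather than the data. Identical images score exactly 1; patchwise
positive-affine intensity changes leave the score at 1.

## Optimization

Both stages run Adam (ascent) with step sizes 1e-2 for rotational and 1.0 for
translational twist components, the best-scoring iterate tracked so the
sequence of accepted solutions is non-decreasing, and a plateau stop
(relative improvement of the best value < 1e-5 over 20 iterations by
default, 300 iterations maximum).

**Conditioning.** Each structure's twist is parameterized about its own
centroid via the constant SE(3) adjoint of the centroid translation. This
changes nothing about the model (the world-frame twist table is recovered
exactly) but decouples rotation from translation in the gradient: rotations
about the off-center world origin drag a translation along and roughly double
the iterations to convergence.

**Polyrigid stage gradient.** For fixed cameras the chain per view is
NCC ∘ projector ∘ trilinear-sample ∘ exp ∘ weight-fusion. The image-space NCC
gradient is pulled back through the projector adjoint to a per-voxel
sensitivity, multiplied by the exact spatial gradient of the trilinear
interpolant at the mapped points, contracted with the closed-form derivative
of the exponential, and accumulated into the K×6 table through the weight
matrix. One iteration on a 64³ volume with two 64² views costs ~0.6 s on one
CPU core.

**Camera stage.** Moving the camera rigidly is exactly equivalent to moving
the volume rigidly: rendering *V∘T* with camera *E* equals rendering *V* with
camera *E·T⁻¹*. The camera stage therefore optimizes a single volume-side
twist per view through the same fixed-projector chain (analytic gradient, no
per-candidate ray retracing) and converts the result back to an extrinsic
correction. A coarse-to-fine schedule (a heavily pooled, raw-intensity
similarity first) widens the capture range. By default the volume is masked
to the anchor structure; on phantoms whose anchor is small, rendering the
full volume is more reliable and is a flag away.

**Single-view depth.** From one view, translation along the source axis only
manifests as a ~1% magnification change per centimetre at typical C-arm
geometry. With desk-scale 64² detectors the optimizer recovers rotation to
<0.5° and in-plane translation to <0.2 mm from 5°/10 mm initialization
errors, while depth stalls near its initial value. This is inherent to
single-view intensity registration, not a defect of the implementation;
multi-view acquisition or higher-resolution detectors resolve it. The tests
assert the observable components.

## Synthetic phantoms

The generator emulates the geometry of the clinical problem, not its
appearance: a soft-tissue ellipsoid (LAC 0.02/mm, near water) containing K
disjoint ellipsoidal bones (0.06/mm, cortical scale), on a centered lattice.
Two deliberate design features make the estimands identifiable:

* **Anisotropic bones** (default radii (12,7,6) and (9,4.5,4) mm): the
  rotation of a near-spherical structure is unobservable in projections.
* **Soft-tissue texture** (seeded smooth random modulation, amplitude 0.3,
  correlation ~3 voxels): pure ellipsoids have rotational near-symmetries
  that create genuine local maxima in pose estimation; real anatomy has none.

A ground-truth case samples per-bone twists (uniform random direction,
uniform magnitude within the configured bounds), **rejection-sampling until
the fused field is exactly fold-free** — draws that would drive bones through
each other are redrawn, since anatomy cannot interpenetrate — and errors out
if the bounds could push a bone outside the field of view. The ground-truth
deformation is built with the same weight mode the registration uses, so the
optimum is attainable and parameter recovery is a sharp test. Cameras are
placed equiangularly on a circular orbit (source-to-isocenter 500 mm,
source-to-detector 1000 mm by default), covering the limited-angle setting
(2 views over 30°) and the sparse-view setting (2–9 views over 180°; note
that 2 views spanning 180° are antiparallel and nearly redundant, which is
what makes that arm of the view-count sweep genuinely under-determined).

What the phantom does **not** emulate: realistic skeletal shapes and
kinematics, soft-tissue-only motion, scatter/noise/polychromatic physics, and
— in the default mode — model mismatch (the true deformation is itself
polyrigid). Passing tests therefore demonstrate the correctness and
conditioning of the machinery, not clinical accuracy on real data.

## Metrics

* **Dice** 2|A∩B|/(|A|+|B|); defined as 1 when both masks are empty.
* **HD95**: directed nearest-boundary distances from both masks are pooled
  before the linearly-interpolated 95th percentile (physical units; boundary
  = mask minus its erosion).
* **Jacobian statistics**: J of the world-coordinate mapping by central
  differences at interior voxels; %Folds counts det J ≤ 0 (the conservative
  convention); σ(log|J|) is the standard deviation of log det J over
  non-folded voxels — 0 for any rigid motion.
* **Silhouettes**: a structure rendered at unit attenuation gives a chord
  thickness map; pixels above half the smallest voxel spacing form the 2D
  mask used for projected overlap.

## Problem sizes in the test-suite

The main recovery study runs five seeds of the 64³ (1 mm) two-bone phantom
with two 64² views 30° apart — per-bone motion up to 10°/10 mm — and checks
pose errors <1°/<1 mm, 3D Dice ≥0.95, and 0.00% folds. Supporting studies
(weight ablation on an 8:1 volume-ratio phantom, the 2→4→8 view sweep, label
erosion 0 vs 2 mm) use the same physical phantom at 32³/2 mm with 32²
detectors, which preserves the geometry at a quarter of the cost. The view
sweep fixes an 80-iteration budget and larger motion (15°/12 mm) so that the
2-view arm is genuinely under-constrained rather than saturated. Erosion
robustness uses larger bones (radii (14,10,8)/(10,7,6) mm) so 2 mm erosion
corresponds to the partial-corruption regime (roughly half the volume
remaining) rather than destroying the small bone outright.

## Dense baseline

`register_dense` optimizes an independent 3-vector displacement per voxel
through the identical renderer and similarity, optionally with a per-voxel
normalized squared forward-difference (diffusion) penalty. It exists as the
under-constrained comparator: on phantom cases it matches or exceeds the
polyrigid model's training-view similarity while producing folded,
anatomically meaningless fields (asserted directionally in the tests); as the
penalty weight grows the field contracts toward a constant translation.

## Known limitations

* Direct log-Euclidean fusion is not guaranteed diffeomorphic for colliding
  motions (see above); a velocity-integration variant would be, at several
  times the cost.
* Weights are frozen on the moving lattice; very large motions would warrant
  recomputing distance maps in the deformed configuration.
* Depth from a single view is weakly observable (see Optimization).
* The similarity treats images as negative log-intensities; raw intensity
  images must be log-converted upstream.
* No intensity-to-LAC calibration: volumes are assumed to already hold
  attenuation coefficients.
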