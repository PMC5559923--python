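# Methods

## Curve evolution model

The segmenter evolves a level-set field `u` on the pixel grid; the binary
mask is `{u > 0}` and, by convention, `u > 0` means *inside the contour*
(the object/vessel phase). The evolution PDE is the balloon-force-only
geodesic flow with the edge-stop function replaced by a signed pressure
force (SPF):

    ∂u/∂t = g_LG · α · |∇u|,   g_LG = g_L + ω g_G.

Curvature and reinitialization terms are deliberately absent: every
iteration the field is re-binarized to ±ρ by sign and convolved with a
normalized Gaussian `K_{σ_reg}` (the selective-binary scheme). Iterated
binarize-then-smooth acts as a discrete curvature flow, so it both
regularizes the contour and removes the need for a signed distance
function. A consequence worth knowing: under zero force a *straight*
contour is a fixed point, but a curved contour shrinks slowly — a
rectangle on a constant image rounds its corners and eventually collapses.
This is inherent to the regularization, not a defect.

Per-iteration order of operations: (1) binarize `u` to ±ρ, (2) smooth with
`K_{σ_reg}`, (3) central-difference gradients (replicate boundary),
(4) region means → global SPF, local fits → local SPF, combine with ω,
(5) explicit Euler update. Because the update magnitude `α·Δt·|spf|·|∇u|`
typically dominates the O(1) field values near the contour, the mask there
effectively snaps to the sign of the combined force each iteration; far
from the contour `|∇u| ≈ 0` and nothing moves. The contour therefore
propagates at roughly the smoothing reach (~2σ_reg) per iteration.

### Forces

* Global: `g_G = (I − (c1+c2)/2) / max|·|` with `c1, c2` the
  Heaviside-weighted means inside/outside (`H_ε(z) = (1 + (2/π)
  arctan(z/ε))/2`). Note the weighting is soft: with ε = 0.5 and the
  smoothed field bounded by ρ = 1, `H(±1) ≈ 0.85/0.15`, so each region
  mean is substantially contaminated by the other phase when the phases
  are unbalanced (vessels are a small minority). In practice the global
  midpoint `(c1+c2)/2` then sits close to the background level, making the
  global force expansionary around bright structures. Users segmenting
  images where the object is the *dark* minority phase should invert the
  image first.
* Local: `f1, f2` are Gaussian-window weighted means of the inside/outside
  phase (four convolutions; an O(N²k²) double-sum oracle in the test suite
  pins the algebra to 1e-10). The local SPF compares each pixel with the
  window-averaged midpoint `(f1+f2)/2`, which tracks smooth bias fields.
* Both SPFs are max-normalized into [−1, 1] so that ω is a meaningful
  relative weight; the combined force is *not* renormalized (scale is
  absorbed by α·Δt).
* All denominators and max-normalizations carry a floor τ = 1e-12: flat
  images produce exactly-zero forces instead of 0/0, and ordinary inputs
  are bit-unchanged.

### Parameters

| name | default | meaning |
|------|---------|---------|
| ω | 0.2 | weight of the global force; the one knob users tune. Smaller → more local detail, larger → blunter, more stable segmentation |
| α | 20 | balloon-force scale; with Δt it sets pixels moved per iteration on [0,1]-scaled images |
| Δt | 2 | explicit Euler step |
| ρ | 1 | binarization magnitude of the level-set field |
| σ_fit, σ_reg | 4 px | Gaussian scale of the local fitting window and of the level-set smoothing; the reference formulation uses a single σ, so they default equal but are exposed separately |
| ε | 0.5 | Heaviside smoothness |
| max_iters | 150 | fixed iteration budget |
| convergence_window | 5 | early stop once the mask is unchanged this many consecutive iterations; 0 reproduces fixed-length runs |

α has no canonical published value; 20 was chosen so that α·Δt moves a
unit SPF across several pixels per iteration on [0,1]-scaled images, and
it is exposed everywhere. Intensities are always rescaled to [0,1] before
evolution so these defaults are image-independent.

### Numerics

Gaussian kernels are discrete, truncated at radius ⌈2σ⌉, and normalized to
unit sum (convolving a constant is exact). All convolutions use the full
2-D kernel with replicate-edge padding — replicate avoids dark-border bias
in `f1/f2` near the FOV rim, and the single convolution path is exactly
reproducible by the brute-force test oracle (separable passes would differ
at corners under replicate padding). Gradients are central differences
with replicate boundary; `|∇u| = sqrt(u_x² + u_y²)`. The loop contains no
randomness: identical inputs give bit-identical masks.

Degenerate states raise typed errors rather than limping on: an all-true /
all-false initialization (`DegeneratePartitionError`) and a contour that
vanishes mid-run (`ContourCollapseError`, reporting the iteration index) —
the latter happens, for example, when a seed contour is placed in a flat
background region farther than the smoothing reach from any object.

## Evaluation protocol

Confusion counts are restricted to a field-of-view mask (the circular
camera aperture of fundus images); Acc/Se/Sp are computed in exact
rational arithmetic from the integer counts, and a zero denominator raises
instead of returning 0, because silent zeros would corrupt dataset
averages. Dataset summaries offer both the per-image unweighted mean (the
default, matching how fundus benchmarks are usually reported) and pooled
counts, clearly separated. Dice (2TP/(2TP+FP+FN)) is included as the
internal phantom-validation metric.

## Synthetic phantoms

The generator emulates three situations at desk scale, with all
randomness flowing from one seed:

* `two_phase_disk` — piecewise-homogeneous disk; the case where global
  region statistics alone suffice.
* `bias_field_blob` — an ellipse under a multiplicative low-order harmonic
  bias field `1 + A·cos(πy/h + φ₁)·cos(πx/w + φ₂)`; smooth intensity
  inhomogeneity that breaks a global two-mean model.
* `vessel_tree` — a random branching tree of ribbons. Centerlines are
  jittered random walks grown inside the FOV disk; each branch has a
  Gaussian cross-section whose FWHM equals the branch width (truth ribbon
  edge = half-peak level), and thin branches are rendered at reduced
  contrast (linearly from half strength at the narrowest width), because
  real capillaries are fainter than trunk vessels. Vessels are bright on a
  dark background, matching the package's object-positive convention; a
  real fundus image should be inverted. Branch centerline lengths and
  widths are recorded so tests can check rasterized area against
  `Σ length × width` analytically.

Default intensities are fg = 0.9 / bg = 0.1 with additive Gaussian noise
and the multiplicative bias applied before clipping to [0,1].

What the phantoms do *not* emulate: the optic disc, vessel tortuosity and
caliber variation along a branch, central light reflex, JPEG artifacts,
and the spatial noise correlation of real sensors. Passing phantom tests
therefore demonstrates the mechanics of the method — force algebra,
convergence, bias-field robustness, protocol arithmetic — not clinical
performance on DRIVE/STARE-class data, which requires the external
datasets.

## Behavior of ω

On the bias-field vessel phantom, raising ω degrades detail fidelity:
Dice at ω = 0.5 is consistently below Dice at ω = 0.2, and the result
moves toward the global-only solution. The *foreground pixel count*,
however, grows with ω on these phantoms: the soft-Heaviside region means
place the global midpoint just above the background level (see the
contamination note above), so the global force widens vessels into their
cross-section skirts rather than suppressing faint branches. The
count-based monotonicity check in the acceptance suite documents this
honestly and currently fails; the Dice-based detail-loss property is the
one the phantom conditions support and is unit-tested.

## Problem sizes

Tests and the acceptance script run on 24–96 px phantoms (a few seconds
per segmentation on one core); these sizes are where the phantom geometry
is still meaningful while keeping the whole suite interactive. The method
itself is O(iterations × N·k²) and handles full 565×584 fundus frames in
tens of seconds.

## Known limitations

* The sign convention requires the object to be the bright phase; there is
  no automatic polarity detection (use `--channel` plus inversion upstream).
* The soft region means bias the global threshold toward the majority
  phase; extremely unbalanced images rely almost entirely on the local
  force unless ω is raised.
* No narrow-band optimization; every iteration touches the full grid.
* Hard masks only — no probabilistic output, so no ROC/AUC.
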