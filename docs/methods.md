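# Methods

This note records the model as implemented, the defaults and why they were
chosen, the numerical conventions, and what the synthetic benchmark does
and does not demonstrate.

## Capsule encoder and routing

Capsule layers follow the standard dynamic-routing formulation: prediction
vectors û_{j|i} = W_ij u_i, coupling coefficients c_ij = softmax over the
*output* capsules j of logits b_ij initialized to zero, weighted sums
s_j = Σ_i c_ij û_{j|i}, and the squash nonlinearity
v = s·‖s‖/(1 + ‖s‖²), whose output length is a probability strictly below
one.  The squash norm is guarded with ε = 1e-7 so squash(0) = 0 without a
division error.  Routing runs 3 iterations by default; after each, the
logits are incremented by the agreement û_{j|i}·v_j.

**Margin and total loss.**  m⁺ = 0.9, m⁻ = 0.1 and the absent-class
down-weight 0.5 are the conventional margin-loss values; all are
configurable.  The reconstruction coefficient is a *distinct* parameter,
0.392, applied to the per-pixel mean-squared error between the decoder
output and the flattened input.  (The two are often both written λ; they
are different quantities here.)

**Routing gradients.**  Backpropagation treats the converged coupling
coefficients as constants of the forward pass: gradients flow through the
final weighted sum, the squash, and the transform W_ij, but not through the
coupling-update recurrence.  This is the natural convention for a manual
(non-autodiff) implementation; with a single routing iteration the
couplings are the uniform softmax of zero logits, independent of W, and the
convention is exact — the finite-difference gradient checks in the test
suite run in that regime.  With 3 iterations the ignored term is the
derivative of a 2-step softmax recurrence and is small relative to the
direct path; training behaviour on the synthetic benchmark is unaffected.

## The two feature lanes

Both lanes are deterministic, parameter-free functions of the input image
and contribute 0 to every parameter total.  Because of that, they are
precomputed once per dataset before optimization rather than re-executed
per batch — the result is identical, the cost is not.

**CLAHE.**  The image is divided into a `tile_grid` (default 8×8) of
tiles; each tile's 256-bin histogram is clipped at `clip_limit` (default
2.0) times the mean bin count, the excess is redistributed uniformly, and
the clipped CDF becomes the tile's intensity mapping.  Tiles are equalized
*independently* — there is no inter-tile interpolation; the operation is
strictly local, which is also what the tile-wise oracle in the test suite
assumes.  Colour images are handled in CIE L\*a\*b\* (D65): only L\* is
equalized and chroma passes through, avoiding hue shifts; a `per_channel`
mode exists for comparison.  The contrast-gain diagnostic (ratio of
processed to original luminance standard deviation) is reported in logs
only and never used in training; it raises on a zero-contrast original,
where the ratio is undefined.

**CDH.**  Pixels are quantized in Lab with uniform half-open bins —
(n_L, n_a, n_b) = (8, 3, 3) factorizing W = 72, mirroring the coarse
chroma binning customary for this descriptor — over L ∈ [0, 100] and
a, b ∈ [−128, 127], values clamped first.  Edge orientation comes from 3×3
Sobel gradients of L\* (reflect boundary); the angle is measured from the
x-axis, folded into [0°, 180°), and binned uniformly into V = 18 levels
(zero-gradient pixels land in bin 0).  For every *unordered* pixel pair at
Chebyshev distance D = 1 (the 8-neighbourhood, each pair visited once),
the Euclidean Lab difference is added to the colour histogram at the
row-major-first pixel's colour index when the orientation bins agree, and
to the orientation histogram at that pixel's orientation bin when the
colour indices agree.  Gating is on quantized indices, not raw values.
The merged descriptor concatenates both histograms (length W + V = 90 at
the defaults).

The network consumes an image-shaped disaggregation of the same
accumulation: channel 1 holds each pixel's orientation-gated mass,
channel 2 its colour-gated mass, channel 3 the gradient magnitude, each
channel divided by its maximum (all-zero channels pass through).  Summing
channels 1–2 over pixels before normalization reproduces the histogram
totals exactly, which the tests assert.  Per-channel max normalization was
chosen over dataset statistics so the layer stays free of learned or
estimated quantities.

A display-table convention worth noting for the evaluation module: the
per-class F1 *percentage* shown in reports is the harmonic mean of the
already-rounded precision and sensitivity percentages — the convention
per-class tables in this field follow — while the raw F1 retained
alongside is computed from exact fractions.  The two differ only in the
second decimal, and only occasionally.

## Architecture and accounting conventions

* Convolutions use valid padding (forced by the 32 → 30 step of a 3×3
  stride-1 convolution); max-pooling is 2×2 stride 2 with ceil-mode
  output (forced by 13 → 7); the primary capsule convolution is 3×3
  stride 2, valid (7 → 3, giving 3·3·16 = 144 capsules of 8 dimensions at
  32×32×3).
* Each convolution is followed by batch normalization then ReLU; the
  post-concatenation order is dropout → batch-norm.  Dropout defaults to
  rate 0.5.
* The class-capsule layer holds only the transforms W_ij (no bias);
  routing logits are transient state, not parameters.
* The decoder is 512 → 1024 → H·W·C with ReLU/ReLU/sigmoid, fed by the
  flattened class-capsule block with all but the chosen class zeroed
  (the true class during training, the argmax at inference).  Its final
  width follows the input (3072 for 32×32×3, 784 for 28×28×1).
* Parameter totals count weights, biases, and four batch-norm terms per
  channel (scale, shift, moving mean, moving variance), the convention
  "total parameters" summaries use.  The printed two-decimal totals are
  insensitive to whether moving statistics are included.
* The baseline network is the original single-lane design: Conv(256, 9×9,
  stride 1, ReLU) → primary capsules (32 channels × 8 dims, 9×9,
  stride 2) → 16-D class capsules → the same decoder; no batch-norm or
  pooling.
* Closed forms used as an independent cross-check: at 32×32×3 the two-lane
  total is 4,631,424 + (K−2)·26,624 and the baseline total
  9,856,768 + (K−3)·270,336; the per-class slopes are the routing
  transforms plus the decoder's first-layer widening (144·8·16 + 16·512
  and 2048·8·16 + 16·512).

**Ablations.**  The removable components are the CDH map, the CLAHE layer,
the first and second conv pairs, the two pooling pairs, and dropout.
Removing a feature lane's extractor feeds that lane the raw image;
removing a convolution removes its paired batch-norm with it (each
conv + BN is treated as one stage); removals apply symmetrically to both
lanes.  A removal set that empties the primary-capsule grid raises a
configuration error at build time.

## Training

Adam at learning rate 0.001, decayed by 0.9 once per epoch, batch size
100.  The best state by validation accuracy (training accuracy when no
validation set is supplied) is restored at the end.  Batch-norm moving
statistics use momentum 0.9 and eps 1e-3.  Runs are exactly reproducible
given the seed: weight initialization, shuffling and dropout masks all
derive from it, and the implementation is pure NumPy with no backend
nondeterminism.

## Synthetic data

The generator emulates the structural properties of real leaf-disease
corpora — strong class imbalance (the `imbalanced_preset` reproduces a
152 : 1000 : 1000 three-class ratio at reduced scale), near-duplicate
images within a class, and non-uniform backgrounds — with anti-aliased
leaf ellipses, spot or streak lesions clipped to the leaf body, plain or
cluttered backgrounds, and Gaussian pixel noise (σ = 0.02 by default).
Every image is drawn from a counter-based stream keyed by
(seed, class, index), so image i of class c is bit-identical regardless of
how many other images are generated.

The `easy_preset` two-class benchmark (healthy vs spotted, plain
backgrounds, high-contrast lesions, 100 images per class) is the smoke
benchmark: the full two-lane network reaches ≥ 90 % training accuracy
within two epochs of CPU training, and a nearest-centroid classifier on
mean-channel features already exceeds 90 % held-out accuracy — the classes
are separable by construction.  Passing it shows the whole pipeline
(feature lanes, capsule encoder, routing, losses, optimizer) optimizes
correctly; it says nothing about accuracy on photographic data, which
varies in pose, scale, illumination and disease morphology far beyond what
the generator produces.  The published-scale experiments (hundreds of
epochs on tens of thousands of real images) are out of scope here; the
desk-scale sizes used throughout — ≤ 200 images of 32×32×3, ≤ 20-image
fixtures at 16×16 for unit tests — were chosen so the whole suite runs on
one CPU in minutes.

## Known limitations

* The image-shaped CDH lane input is this package's spatial reconciliation
  of a descriptor that is classically global; the disaggregation is exact
  in the conservation sense above but any other spatialization (e.g.,
  local histograms) would also be defensible.
* Routing gradients are approximate beyond one iteration (see above).
* CLAHE without tile interpolation can show tile-boundary artefacts at
  coarse grids; that is the intended, strictly-local behaviour.
* The evaluation helpers assume every class appears in the labels when
  computing ROC/PR areas and raise otherwise rather than guessing.
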