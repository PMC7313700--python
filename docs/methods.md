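# Methods

## Pipeline model

The system classifies a dermoscopic lesion from two inputs: an 8-bit RGB
image and a same-size binary mask marking the lesion (region of interest).
It assumes segmentation is given — the mask comes from the imaging
database or an upstream tool; the package performs no segmentation.

Processing has three stages:

1. **Mask application.** Each channel is ANDed with the mask expanded to
   8 bits (mask 1 → 0xFF), so background pixels are exactly zero.
2. **Descriptor extraction (two-pass stream).** The image is scanned
   pixel by pixel, rows top to bottom, each row left to right. Pass one
   accumulates the lesion pixel count L, the centroid numerators
   Σ pᵢⱼ·i and Σ pᵢⱼ·j, the bounding extremities z₁…z₄, and the
   per-channel intensity sums; the centroid and channel means come from
   dividers at the end of the pass. Pass two, which needs those values,
   runs the four symmetry counters (pixels strictly before vs at-or-after
   the centroid row/column) and accumulates squared deviations for the
   channel variances. Variance is the population variance (divide by L,
   not L−1), matching the descriptor definition.
3. **Classification.** The nine normalized descriptors feed a 9–10–24–2
   MLP with sigmoid activations and a constant bias input of −1; the two
   outputs are coded one-hot (melanoma = [1, 0]). The inference decision
   is argmax with ties resolved to melanoma: the coding fixes the target
   vectors but not a threshold, and favoring melanoma on ties errs in the
   clinically cheaper direction (a false positive triggers review; a false
   negative misses a cancer).

### Centroid comparison convention

The centroid coordinates are kept fractional, and the "first half" test is
the strict comparison i < c_x. Truncating the centroid to an integer would
break the exact d₀ = 0 property of even-extent symmetric shapes, which the
synthetic tests rely on. With a fractional centroid the property is exact:
a shape symmetric about a half-integer row splits into equal strict halves.

### Diameter

d₂ = max(z₂−z₁, z₄−z₃) — the larger bounding extent, a plain coordinate
difference (no +1). The off-by-one convention is immaterial because the
normalization gain absorbs any constant scale.

### Normalization

Gains are fitted on a reference image set as Gᵢ = 1/maxₖ(raw dᵢ of image
k); at inference dᵢ = clamp(raw·Gᵢ, 0, 1). Clamping matters: an unseen
image can exceed the training-set maximum, and the uQ0.10 output format
cannot represent values above 1 − 2⁻¹⁰ anyway (saturation enforces the
clamp in fixed mode). A zero reference maximum is an error naming the
descriptor — it means the reference set carries no signal in that
component (e.g. all-symmetric shapes give max d₀ = 0) and no finite gain
exists.

## Fixed-point emulation

The fixed datapath uses Q-format numbers: `sQa.b` / `uQa.b` means a sign
flag, `a` integer bits, `b` fractional bits, value = raw·2⁻ᵇ. Supported
widths are 0–35 integer and 0–15 fractional bits. Documented signal
formats: pixels uQ8.0; descriptors and network outputs uQ0.10; weights
sQ5.10; accumulators uQ35.15/sQ35.15.

Numerical policy, chosen for bit-reproducibility and testability:

* **Rounding = truncation toward −∞** (floor on raw integers) for
  quantization, multiplication and division — the behavior of dropping
  low-order bits in hardware.
* **Overflow = saturation**, not wraparound: accumulator overflow would
  otherwise flip signs silently, and saturation gives a testable contract.
* **Wide accumulators.** All delayed-feedback accumulators run at 15
  fractional bits and up to 35 integer bits. For every supported image
  size the accumulators never saturate, so accumulation is exact integer
  addition — which is also why the vectorized fixed path (raw int64
  numpy) is bit-identical to the per-pixel streaming reference: a sum of
  same-format integers is associative. The test suite asserts this
  equality directly.
* **Intermediate formats** are sized to their value ranges: centroid
  uQ20.15, channel mean uQ8.15, deviation sQ9.15, squared deviation
  uQ18.15, variance uQ16.15. The only per-pixel truncation is the
  squared-deviation product (30 → 15 fractional bits), bounding the
  accumulated variance error by 2⁻¹⁵ per pixel before the divide by L.
* **Fixed-mode normalization** is a truncating division by the quantized
  reference maximum rather than a multiplication by a quantized
  reciprocal: symmetry counts reach 10⁴–10⁵, so a reciprocal gain held at
  ≤15 fractional bits would quantize to zero.
* **Fixed/float parity tolerance** is 4·2⁻¹⁰ per descriptor: at most a
  handful of truncating operations touch each descriptor after the exact
  accumulator stage, each losing less than one output step. Measured
  gaps are ≈1 step.

### PLAN sigmoid

Fixed mode replaces the sigmoid with the PLAN piecewise-linear
approximation (slopes 2⁻², 2⁻³, 2⁻⁵ — shift-and-add in hardware).
Branch boundaries are evaluated on the quantized value of the input,
intervals left-closed exactly as printed. Two consequences are accepted
deliberately:

* the printed branch conditions leave a downward jump of 2⁻⁸ at
  x = ±2.375 (0.921875 vs 0.91796875), so the approximation is monotone
  only between boundaries;
* uQ0.10 cannot represent 1.0, so the saturation branch returns
  1 − 2⁻¹⁰ and the odd symmetry y(x) + y(−x) = 1 holds within 2⁻¹⁰ in
  fixed mode (exactly in float).

The per-neuron weighted sum accumulates in sQ10.10: 25 products of
sQ5.10 × uQ0.10 terms plus a bias cannot exceed 2¹⁰ in magnitude.
Float mode uses the exact sigmoid — training happens in float, so the
fixed/float gap is exactly the quantization cost being studied.

## Training

Plain full-batch gradient descent on the MSE, exact sigmoid, weights
initialized uniform in [−0.5, 0.5] from the seed; stops at the target MSE
(default 10⁻⁶) or the epoch budget, and reports the weights at the lowest
recorded error. Defaults: learning rate 2.0, 3000 epochs — enough for the
synthetic study conditions to converge to ~10⁻⁴–10⁻⁵ MSE in well under a
second; the toy two-example problem reaches 10⁻⁶ with a larger budget.
Optimizer sophistication (momentum, adaptive rates, early stopping) is
deliberately out of scope; the trainer is a reference implementation whose
virtue is determinism. The 0.15 validation fraction mirrors the common
85/15-style hold-out. Weight quantization to sQ5.10 truncates and
saturates per weight, with max error ≤ 2⁻¹⁰.

## Synthetic data

The generator emulates the pipeline's inputs, not dermoscopy optics. A
lesion is a filled ellipse with three controls:

* **asymmetry**: the semi-axes on the +row/+col side may be enlarged,
  producing genuine shape asymmetry that the centroid-split counters
  detect with predictable sign;
* **boundary roughness**: a smooth periodic radial perturbation (harmonics
  2–5, amplitude relative to the radius) — irregular but connected
  borders;
* **color**: lesion pixels drawn per channel from a normal distribution
  clipped to [0, 255] and rounded; constant background.

Ground truth records the *realized* statistics (pixel count, bounding
extents, per-channel mean/SD of the stored integer pixels), so extracted
descriptors can be checked against construction exactly rather than
against nominal parameters.

Class parameter defaults follow the ABCD directions: melanomas are drawn
larger, more asymmetric, rougher, darker and more color-variable than
benign nevi, with ranges separated enough that a nearest-centroid rule
already separates the classes — the end-to-end 95% accuracy criterion then
tests the pipeline's plumbing, not a hard learning problem. The default
dataset canvas is 192×192 so the largest roughened melanoma (semi-axis
up to 34 + 10 asymmetry, roughness factor up to ~1.9) keeps a background
margin. Datasets use a 4:1 benign:melanoma ratio by default, the class
balance typical of curated dermoscopy collections.

What passing tests on this data does **not** show: robustness to real
dermoscopic nuisance (hair, gel, rulers, illumination gradients, texture),
to imperfect segmentation masks, or to class overlap — real lesion classes
are far less separable than the synthetic defaults.

## Evaluation

Melanoma is the positive class. Accuracy = (TP+TN)/total, specificity =
TN/(TN+FP), sensitivity = TP/(TP+FN), computed as exact count ratios and
rounded to one decimal in percent only for display. On the reference
validation composition (22 non-melanoma with two false positives, 8
melanoma with one false negative) these evaluate to 90.0% / 90.9% / 87.5%.

## Degenerate inputs and errors

Empty masks are rejected at load and at extraction; division-by-zero in
the fixed datapath raises an error naming the consuming block; pipeline
stage failures are wrapped with the stage name (`dpim`/`annm`); a
single-class training set is rejected; a lesion touching the canvas
border is a generator error (its statistics would be censored).

## Problem sizes

Default test and acceptance runs use 192×192 synthetic images, datasets of
50–200 lesions, 3000-epoch training, a 2⁻¹² grid for sigmoid fidelity and
10⁴ operand pairs per fixed-point op — sizes at which the whole suite runs
in seconds while every check retains its full resolution (the fixed-point
checks are exact at any size).

## Known limitations

* No segmentation: a lesion mask is required.
* The streaming fixed datapath is emulated numerically; no timing,
  pipelining or resource modeling.
* Real-database replication requires that database's images and trained
  weights; the package reproduces the method and its metric arithmetic,
  and validates the datapath on synthetic conditions instead.
* The diameter surrogate is the bounding extent, not a minimum enclosing
  circle; the two differ on diagonal shapes (consistent gains must come
  from this pipeline).
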