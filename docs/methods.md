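# Methods

This package implements a fully-convolutional classifier family for
detecting standard scan planes in 2-D ultrasound frames, together with a
weakly supervised localisation mechanism that turns image-level class
labels into bounding boxes at inference time. Everything below is the
package's own account of what is computed and why; every empirical number
quoted is produced by the test suite or `scripts/acceptance.py`.

## Model

### Fully-convolutional classification

The flagship architecture (`variant="sononet"`) is a VGG16-style feature
extractor with 13 convolutional layers in five blocks (2-2-3-3-3 convs of
3×3 kernels, channel widths `base_width × {1, 2, 4, 8, 8}`), 2×2/stride-2
max pooling after the first four blocks, and **no** pooling after the fifth
— the output stride is 16 rather than 32 so the class evidence keeps usable
spatial resolution. Every convolution is followed by batch normalisation
and a rectifier. Width-scaled members (base width 64/32/16, and smaller for
desk-scale work) share the block plan.

The fully-connected head of a conventional classifier is replaced by two
1×1 *adaptation* convolutions. For `K` classes, the second adaptation layer
emits `K` **class score maps** `F_k` of spatial size `H/16 × W/16`
(14×18 for a 224×288 frame — this is what `scripts/acceptance.py`
recomputes). The maps are aggregated by their spatial mean into scores
`a_k`, and a softmax yields per-class confidences `c_k`. Mean aggregation
(rather than max) lets the whole image context vote, which matters when
most of a frame is uninformative speckle.

Design choices the source material leaves open, fixed here:

* **First adaptation layer width** — `base_width × 4` channels with batch
  norm and a rectifier, mirroring the halving convention of the family.
* **Second adaptation layer** — linear into the mean pool (batch norm, no
  rectifier), so the maps carry *signed* class evidence; negative evidence
  is meaningful and is exploited by the saliency weighting.
* **SmallNet** — the shallow comparison member is defined here as six
  convolutions (7/5/3/3/3/3 kernels), no batch normalisation, the same
  adaptation head and /16 output stride.
* **Initialisation** — He (variance-scaling) normal with an explicit seeded
  generator; all randomness in the package flows from
  `numpy.random.Generator` arguments.

The network engine (convolution, batch norm, pooling, rectifier, together
with their backward passes) is implemented in NumPy inside `sononet.nn`.
This is deliberate: the localisation mechanism modifies backpropagation at
every rectifier and seeds the backward pass with arbitrary error fields at
the class-score-map layer, so owning the backward pass is the core of the
package rather than plumbing. Convolutions are evaluated as a sum of
`k × k` shifted channel contractions (BLAS matmuls), which keeps desk-scale
training practical on one CPU.

### Training

Mini-batch gradient descent with Nesterov momentum 0.9 and categorical
cross-entropy. The learning rate warms up at 0.01 for 500 iterations, then
starts at 0.1 and is divided by 10 whenever the validation error plateaus
(no new minimum for `plateau_patience` = 5 consecutive evaluations — the
plateau notion is this package's choice; the evaluation interval,
`val_every`, default 50 iterations, is configuration). The batch-norm-free
SmallNet uses initial rate 0.001. 20% of the data is held out for
validation (stratified per class).

Freehand screening data is dominated by background frames, so batches are
*composed*, not sampled i.i.d.: exactly `per_foreground_class` (default 2)
frames of every standard view plus `background_count` (default 26)
background frames — 52 frames per batch with the 13-view clinical
taxonomy. Small class pools are sampled with replacement so the strict
composition stays feasible.

Augmentation: a square crop with side uniform in [174, 224] (scaled
proportionally for other input sizes) at a uniform position, rescaled to
the training size, flipped left-right with probability ½, rotated by a
uniform angle in ±25°. Fixed order crop → rescale → flip → rotate;
bilinear interpolation; out-of-bounds pixels filled with the image minimum
so augmented corners cannot become a bright artefact a classifier could
latch onto.

### Weakly supervised localisation

**Saliency.** The influence of each pixel on class `k` is obtained by
backpropagation. Plain guided saliency differentiates the pre-softmax
score `a_k`; *guided* means that at every rectifier the backward error is
zeroed wherever the forward input or the incoming error is non-positive
(the softmax itself is never differentiated through). The
activation-weighted variant computes

    S = Σ_n h⁰ₙ · ∂hₙ/∂X,     h⁰ₙ = max(hₙ, 0),

where `hₙ` ranges over the neurons of `F_k`: regions whose receptive
fields carry positive class evidence dominate the map, and negative
evidence contributes nothing. Operationally `S` is computed in a single
backward pass seeded with the thresholded map `F_{>0}` — the gradient seed
of the objective `½ Σ (h⁰ₙ)²`.

**A mathematical caveat discovered during verification.** The identity
between the single seeded pass and the explicit per-neuron sum rests on
the chain rule, which holds for true gradients: the package verifies
equality to ≤1e-5 relative error with guided gating disabled. Under guided
gating the identity is **not** exact, because the error-sign gate is not
additive: `max(Σ δₙ, 0) ≠ Σ max(δₙ, 0)` whenever per-neuron error fields
of mixed sign meet at a rectifier. Measured on random small networks the
literal per-neuron loop (each neuron's pass gated by its own error sign)
differs from the single pass by up to ~30% relative error. The package
therefore ships three routes:

* `weighted_saliency` — the single guided pass; the method as used.
* `weighted_saliency_per_neuron(gate="shared")` — per-neuron error fields
  propagated simultaneously with the rectifier gate computed from their
  *sum*; the additive decomposition, exactly equal to the single pass
  (asserted at 1e-5), and the natural reading of "a weighted linear
  combination of per-receptive-field influences".
* `weighted_saliency_per_neuron(gate="independent")` — the literal
  per-neuron reading; retained for comparison, with a test documenting its
  divergence rather than asserting a false identity.

**Boxes.** The saliency map is rectified per the class's *sign policy* —
bright anatomy (bone: femur, spine, lips) casts positive saliency, dark
fluid-filled anatomy (cardiac chambers/vessels) negative, so the policy is
`positive_only` / `negative_only` / `both` per class — then blurred with a
unit-sum 5×5 Gaussian (σ = 1.0, configurable) into a non-negative
confidence map. The map is thresholded with the continuous Isodata rule
(the fixed point `t = (mean below + mean at/above)/2`, iterated from the
global mean to |Δt| < 1e-6; no histogram binning, since the maps are
float-valued). The largest connected component (8-connectivity by default,
ties to the earliest raster-order pixel) receives the minimum axis-aligned
box. All boxes are 0-based, half-open `[rmin, rmax) × [cmin, cmax)`. An
empty or constant map is a reported *localisation failure*, never a
fallback box; failures score as incorrect in evaluation.

### Stream annotation and retrieval

A trained network annotates a frame sequence in order, recording the
softmax vector per frame; retrospective retrieval returns, per class, the
frame with the maximum confidence (earliest on ties). Background training
frames are sampled from video stretches where the probe is *moving* —
frames whose mean-squared distance to their predecessor exceeds a
threshold — because operators hold still around standard planes. The
default threshold is the 5th percentile of the video's own frame-to-frame
distances; this self-calibrates across acquisition settings but assumes
dwells occupy well under 5% of the video (true of real screenings, which
are dominated by search motion). For videos with long dwells, pass an
explicit threshold. "Image distance" is the mean squared pixel difference
— the cheapest metric consistent with minimum-distance freeze-frame
matching; its square root is a proper metric.

## Synthetic phantom data

The generator (`sononet.synthetic`) makes the whole pipeline testable
without clinical data. Frames combine a smooth tissue-like base intensity,
multiplicative speckle (zero-mean smoothed noise scaled by
`speckle_strength` = 0.35), an optional acoustic shadow band (probability
0.25), and a fan-shaped field-of-view mask. Each foreground class renders
one parametric structure with a tight ground-truth box: a bright capsule
("bar", femur-like), a bright elliptical ring ("ring", skull-like), a dark
multi-lobed blob of overlapping ellipses ("lobes", cardiac-like; one
*connected* dark region, as chambers are within the heart), a bright wedge
and a dark spot cluster for larger taxonomies. Background frames carry 0–3
small non-class distractors. Class polarity (bright/dark) determines the
shipped sign policy. Shadow bands are drawn clear of the target structure,
as an operator avoids shadowing the anatomy of interest.

Scripted videos emulate freehand acquisition: a camera window drifts over
a fixed speckled canvas with per-segment motion amplitude (sub-pixel
bilinear sampling so image distance tracks amplitude smoothly); during a
dwell the class structure is present and the amplitude drops; an event log
records true intervals, a designated freeze frame, and the box.

What the phantom does **not** emulate: physical speckle statistics
(Rayleigh amplitude, depth-dependent point spread), anatomical context and
confusable structures, probe pressure deformation, compression artefacts of
real video. Passing tests therefore demonstrate that the mechanism works —
that weak labels suffice to localise the class-specific structure under
speckle, shadows and distractors — not clinical-grade performance.

## Desk-scale study conditions

The end-to-end suite trains a `base_width=8` network on 64×64 phantom
frames (three foreground classes + background; 120 foreground frames per
class and 240 background frames; balanced 32-frame batches; the standard
warm-up/decay schedule; 1000 iterations) and evaluates on 50 held-out
foreground frames per class plus 100 background frames. These sizes were
chosen as the smallest configuration in which the structures remain
resolvable after four poolings (4×4 class score maps) while a full
training run stays comfortable on a single CPU. Scripted-video retrieval
is evaluated over 5 seeds with one dwell per class per video.

## Numerical notes and limitations

* Forward/backward run in float32; analytic gradients of every layer are
  verified against float64 central differences (≤1e-7).
* Batch normalisation uses batch statistics in training and exponential
  running estimates (momentum 0.1) at inference, where the layer is a
  fixed affine map — its backward is then exact, as guided
  backpropagation requires.
* Max-pool ties route the gradient to the first maximum in window order;
  argmax/argmin tie-breaks are always "lowest index / earliest frame".
* Isodata iteration is guaranteed to stay strictly inside (min, max) and
  in practice converges in a handful of iterations; a constant map is an
  error by definition.
* The class score maps at 64×64 input are only 4×4, so each map neuron's
  receptive field covers a large part of the frame; localisation precision
  at this scale comes mostly from guided backpropagation, with the
  activation weighting contributing coarse selection. At clinical
  resolution (14×18 maps) the weighting is proportionally more selective.
* MP4/AVI decoding requires an imageio video plugin; the package's native
  video format is a directory of PNG frames plus an events CSV, which
  needs no codecs.
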