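# Methods

`cellsegnet` implements single-cell segmentation of live-cell microscopy
images by per-pixel classification with small convolutional networks,
together with the quantification layers that sit on top of the masks:
per-object accuracy metrics, lineage tracking with growth statistics,
translocation-reporter ratios, and co-culture cell-type calls. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic-data tests do and do not demonstrate.

## Segmentation as patch classification

Each pixel of a microscopy image is classified as *background*, *cell
boundary*, or *cell interior* (plus a second interior class in the
4-class semantic mode) from the square patch centered on it. The
classifier is a conv-net: rounds of convolution (3–5 px filters), a relu
transfer function `relu(x) = max(0, x)`, and optional 2×2/stride-2
max-pooling, followed by fully connected layers of depth q (relu between
hidden layers, none after the class-score layer). The **receptive field**
— the patch side that influences one output — is fixed by the conv/pool
size arithmetic: we define architectures whose conv stack reduces exactly
one receptive-field patch to a 1×1 feature vector, so
`receptive_field(spec)` is computed by inverting that arithmetic from a
1×1 output. Receptive field should be on the order of a cell diameter:
the defaults are 31 px for bacteria and 61 px for mammalian
nuclei/cytoplasm; small "test family" networks (receptive fields 9–31,
8–16 filters, 2–3 rounds) exist so that every property can be exercised
in seconds to minutes on one CPU, while the full-scale family (4+ rounds,
64 filters, q = 3) expresses production-sized architectures.

Training minimizes the soft-max cost

    Cost = − Σ_images log( e^{s_correct} / Σ_classes e^{s} )
           + λ Σ_{w ∈ conv filter weights} w²

by mini-batch gradient descent (plain SGD or RMSprop, default RMSprop
with learning rate 1e-3, batch 256, λ = 1e-5). The L2 penalty covers
convolution filter weights only — not fully connected matrices or biases.
Gradients are computed by backpropagation written out analytically in
NumPy (im2col convolutions, argmax-routed max-pool, batch-norm with the
standard chain rule); a finite-difference check over every layer type is
part of the test suite. Weight initialization is fan-in-scaled Gaussian
(sd = sqrt(2/fan_in)), needed for trainability at 4+ conv rounds; batch
normalization (per-channel, batch statistics during training, running
statistics at inference) is on by default, dropout on fully connected
activations is available but off. During training the cost is averaged
per batch rather than summed — identical optima, learning-rate scale
independent of batch size.

Gradient checks are performed at a generic point (all biases nudged off
zero): a network whose pre-activations are exactly zero sits on the relu
kink, where central differences legitimately disagree with the
subgradient convention.

### Dense (fully convolutional) inference

A whole image is scored at every pixel without patch extraction by
evaluating the same weights with d-regularly-sparse (dilated) kernels:
each conv layer uses dilation d, each max-pool becomes a 2-point dilated
max with stride 1 after which d doubles, and the fully connected layers
act as 1×1 convolutions over the channel axis. This is exactly
equivalent — not approximately — to classifying the patch around every
pixel; the suite asserts max abs difference < 1e-4 at every valid pixel,
and observed differences are at float round-off (~1e-15). The image is
reflect-padded by half the receptive field so the score map is full-size;
`valid_region` marks the pixels whose receptive field contained no
padding.

## Normalization

Every image is (1) divided by its median pixel value and (2) reduced by
its local mean over a window equal to the network's receptive field, per
channel, identically at training and inference time. Step (1) makes the
pipeline invariant to multiplicative illumination changes — exact up to
1-ulp float rounding, since (c·x)/(c·median) and x/median round
differently; step (2) removes slowly varying background. The averaging
filter uses reflected borders (scipy's `reflect`, which duplicates the
edge sample); the border rule is a config choice the underlying method
leaves open. Maximum-value and no-normalization modes exist only for
ablation. Note the residual mean after local-mean subtraction is not
zero: on an n-pixel random image it fluctuates at order sd/sqrt(n).

## Training data

Class maps derive mechanically from instance masks: a cell pixel
8-adjacent to background or to a different cell is boundary (dilated to a
configurable width, default 1 px); remaining cell pixels are interior.
Patch centers are sampled uniformly without replacement with equal
per-class counts — min(smallest availability, cap) per class, default cap
100,000/class so a full-scale annotated image yields ~300k patches — and
a stratified, seeded 10% is held out for validation. Patches are
extracted at batch-assembly time and augmented on the fly with the 8
rotations/reflections of the square (the class label is invariant);
nothing is materialized. Shearing augmentation is intentionally absent.

## From score maps to instances

Scores are softmax-normalized per pixel; ensembles (default 5 networks
from different random initializations) are combined by pixel-wise
averaging of the probability maps. Masks are produced by:

* **Global thresholding** of the interior probability (default 0.6 for
  bacteria; 0.5–0.75 works for nuclei), 4-connected components (thin
  bacterial gaps must separate), minimum area 20 px (bacteria) / 100 px
  (nuclei). Because the interior class excludes the boundary ring by
  construction, components can optionally be re-expanded by the boundary
  width (`grow_px`, via label expansion that never merges neighbors);
  the end-to-end studies use grow_px = 1.
* **Adaptive thresholding** (local mean + offset) for images with very
  dim objects that a global cut misses.
* **Nuclear-seeded active contours** for mammalian cytoplasms: a
  morphological geodesic active contour initialized at the union of the
  nuclear seeds balloons outward over the interior-probability field and
  halts where probability falls below a stop threshold (default 0.5,
  iteration cap 100, smoothing 1); the evolved foreground is then split
  between seeds by marker-based watershed on the inverted probability, so
  colliding fronts separate along the inter-cell ridge. Every instance
  contains its seed; each seed yields at most one instance. The
  active-contour parameters and the collision rule are package choices —
  the underlying method cites the technique without constants.

## Evaluation

Reference and computed instances are matched greedily by descending
pixel overlap, one-to-one (an exhaustive maximum-weight assignment is
used as a test oracle only). Matched pairs score the Jaccard index
JI = |R∩S|/|R∪S| and Dice index DI = 2|R∩S|/(|R|+|S|) (so DI =
2JI/(1+JI) identically); aggregate means are reported both penalized
(unmatched reference cells contribute 0) and matched-only, because
aggregation conventions differ between studies. The movie-level quality
statistic flags cell-frames whose area grew ≥30% from the previous frame
— in bacterial movies such a jump almost always means two cells were
merged — and reports 100·flagged/transitions; display rounding is one
decimal below 1% and integer above (69/11,909 → 0.6%, 21/145 → 14%). The
denominator is cell-frame transitions; per-track denominators are
computable from the same lineage.

Co-culture type calls use the cellular classification score: per cell,
each type's pixel scores are summed over the cell's pixels and normalized
across the type classes; the predicted type is the argmax and the scores
sum to 1 by construction. Co-culture instance masks come from
thresholding the *sum* of the type-interior probability maps.

## Tracking and growth

Linking solves a Jaqaman-style augmented assignment problem per frame
pair: link cost = squared centroid displacement, gated at a maximum
displacement (default 25 px); birth/death alternatives are priced at
1.05× the maximum observed gated link cost (the 100th percentile —
configurable; lower percentiles undercut genuine links when all motions
are small, which splits tracks on near-static colonies). A division is
recorded when an unlinked new object lies within the gate of a linked
object that lost ≥30% of its area; the parent track ends and two daughter
tracks begin. Gap closing is off by default (missed detections restart
tracks). Instantaneous growth rate is (A_{t+1} − A_t)/A_t per cell-frame;
parent-to-daughter transitions contribute negative rates (≈ −0.5) flagged
as divisions, matching the negative tail such histograms show. The
spatial growth map paints each instance with its rate (background NaN).

## KTR quantification

For each tracked cell and frame the nuclear mean is measured over the
nucleus mask and the cytoplasmic level by two routes: cytorings —
rings of 5–25 px around the nucleus (dilation minus nuclei, clipped to
the cell) — and a 2-component Gaussian mixture over all cytoplasm pixels,
whose **higher-mean component** estimates the compartment in
communication with the nucleus (fluorescence is highest near the
nucleus, so the higher mean is the operational proxy). The EM fitter
initializes means at the 25th/75th intensity quantiles with equal weights
and the sample variance, tolerance 1e-6 on the log-likelihood, 300
iterations, variance floored at 1e-10× the sample variance; components
are reported sorted by mean. At least 50 pixels are required. On data
with no second mode EM overfits a split of the single Gaussian —
component means separate by roughly one sd while the mixture still
reproduces the sample moments; this degeneracy is documented, not an
error. The nuclear/cytoplasmic ratio is invariant under global scaling of
the reporter channel since numerator and denominator scale together. The
nuclear mean uses the raw channel by default; background subtraction is a
caller choice.

## Synthetic microscopy

The simulator is invented infrastructure: the underlying method was
demonstrated on real images that are not redistributable, so every
downstream stage is exercised on generated scenes with exact ground
truth. Cells are minimal parametric shapes:

* **Rods** are capsules (rectangle plus semicircular caps), radius 4 px,
  dividing at total length 34–36 px. Growth is exponential *in area*:
  each frame area ×(1+g), with capsule length derived from area, so the
  closed form A0(1+g)^t holds analytically and the rasterized total
  tracks it within 2%. At the frame a rod divides, the two daughters
  exactly tile the parent's previous footprint (the capsule split at its
  midplane), so daughter areas sum to the parent's area pixel-exactly;
  daughters then grow as independent capsules with a small orientation
  jitter. Overlaps are relaxed by pushing capsules apart along
  center-to-center vectors; masks are made disjoint by assigning
  contested pixels to the deepest (most negative signed-distance) cell.
  A colony reaching the frame edge stops the movie early with a
  truncation flag.
* **Mammalian cells** are ellipses perturbed by radial harmonics of
  order 2–4 (amplitude sd 0.025), each containing exactly one nucleus
  (ellipse at ~0.42 of the short axis, centroid within a quarter short
  axis of the cell center). Two morphology classes are separable by
  shape and texture: class A is elongated (axis ratio 2.6) with a smooth
  dark cytoplasm, class B is round (ratio 1.05) with a brighter,
  finer-grained texture; their mean eccentricities differ by > 0.3.
  Placement is rejection sampling with a retry cap; exceeding it raises.
* **Phase rendering**: background 1.0, interiors darker (rods 0.45;
  blobs by class), a 2-px bright halo around cells, Gaussian blur
  (σ 0.7), additive Gaussian noise (sd 0.03–0.05). This captures the
  cues a phase-contrast classifier must learn — dark interiors, bright
  halos, cell-cell gaps — not optics: no PSF model beyond the blur, no
  photobleaching, no 3-D.
* **KTR movies**: static round cells with a nucleus, a perinuclear
  "near" compartment (nucleus dilated by 7 px, clipped to the cell) and
  a distal "far" compartment. Per frame, a schedule gives the nuclear
  fraction f of the exchangeable pool; the far compartment stays at mean
  1.0, the near compartment at (1−f)·3.0, and the nucleus receives the
  balance, so total reporter per cell is conserved exactly before noise.

Identical specs produce bit-identical arrays: each generator derives one
`numpy` Generator from its spec seed and uses no other randomness.

What passing on these scenes shows — and does not. The synthetic scenes
verify the machinery end to end: that dense inference equals patch
classification, that a trainable signal propagates from rendering through
training to per-cell masks, that tracking reconstructs a known lineage,
and that the quantification layers recover parameters they were
generated from. They do not certify accuracy on real microscopy: real
phase contrast has structured artifacts, debris, focus drift, and
morphology far richer than perturbed ellipses, and the reported synthetic
Jaccard/Dice values should not be read as expected real-data accuracy.

## Study sizes

The end-to-end reference studies are sized for a single CPU: the
bacterial study trains receptive-field-31 classifiers on a ~20,000-patch
balanced dataset sampled from six frames of one simulated colony
(8 initial cells), six epochs, three training seeds, and evaluates median
matched per-cell JI on the final frame (~12–18 cells) of a held-out
moderate-density colony; near-confluent colonies segment measurably
worse, consistent with the density dependence real data shows. The
co-culture study trains the 4-class receptive-field-21 network on ~12k
patches from three scenes and evaluates ~20–30 held-out cells. The
mixture-recovery study uses n = 10⁴ pixels over 20 seeds.

## Known limitations

* No GPU path; the NumPy implementation is practical at test-family
  sizes and small images, not for paper-scale training runs.
* Multi-resolution fully connected heads and conditional-random-field
  refinement are out of scope; shearing augmentation is deliberately
  omitted.
* Tracking implements linking plus division detection only — no gap
  closing across multiple frames, no merge handling, 2-D only.
* The exact full-scale per-layer architectures are configuration inputs
  (the config system expresses them); the defaults are representative,
  not a reproduction of any published table.
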