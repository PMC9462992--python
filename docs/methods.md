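# Methods

`aopmeter` measures the angle of progression (AoP) — the clinical index of
fetal head descent — from 2-D transperineal-ultrasound-like images. The AoP
is the angle at the inferior (right) endpoint of the pubic symphysis (PS)
between the PS long axis and the line tangent to the fetal head (FH)
contour. The pipeline has two parts: a multitask encoder–decoder network
that recognizes the standard plane, segments PS/FH and localizes the two PS
endpoints; and an exact geometric post-processing stage that fits an ellipse
to the FH contour and constructs the tangent.

## The network

One shared encoder (five blocks of two 3×3 conv + batch norm + ReLU; blocks
1–4 end in 2×2 max pooling followed by an efficient-channel-attention unit;
block 5 is the bottleneck, so the decoders need four upsampling levels to
restore full resolution) feeds three decoders:

* **Task 1 — standard-plane recognition.** Two residual blocks on the
  bottleneck, global average pooling, a fully connected layer, softmax over
  {nonstandard, standard}. AoP is only defined on the standard plane, so
  the rest of the pipeline is gated on this decision.
* **Task 2 — segmentation.** A U-Net decoder with encoder skip connections
  and a per-pixel 3-class softmax (background / PS / FH).
* **Task 3 — endpoint heatmaps.** A parallel decoder ending in a sigmoid
  over three unit-peak Gaussian heatmaps (right endpoint, left endpoint,
  PS-axis midpoint). Each level is fed by an attention-fusion (AFM) gate: a
  single-channel sigmoid mask, learned from the previous level's shared and
  landmark features, multiplies the current shared (Task 2) features, which
  are concatenated with the upsampled landmark stream.

The channel-attention kernel size is adaptive, `k = |(log2 C + b)/γ|_odd`
with γ = 2, b = 1, where `|·|_odd` truncates and adds one if even
(k(2)=1, k(64)=3, k(256)=5). Upsampling is bilinear followed by
convolutions (checkerboard-free). Convolution weights use He-normal
(Kaiming) initialization; batch norms start as the identity.

Two output-head choices matter at small training budgets:

* the heatmap head's bias starts at −4, so the sigmoid begins near the
  background rate (~0.02). Endpoint pixels are rare positives; a
  neutral-start sigmoid head spends most of a short optimization budget
  desaturating toward zero and its diffuse argmax tilts the short PS axis,
  which the AoP amplifies. Prior-bias initialization is the standard remedy
  for rare-positive detection heads.
* the third heatmap: the loss weights (1.0, 0.8, 0.6) imply three maps but
  only two endpoints exist. The third map is the PS-axis midpoint with the
  smallest weight; the right endpoint — the AoP vertex — carries the
  largest. This assignment is configurable.

The network and its training loop run on a compact reverse-mode autodiff
engine over NumPy arrays (`aopmeter.autodiff`): conv2d as a channels-first
im2col GEMM, pooling/upsampling with exact adjoints (bilinear resampling as
a cached sparse operator), fused batch-norm gradients, Adam, and a step
learning-rate schedule. Gradients of every operator are verified against
central finite differences in the test suite.

## Losses and two-stage training

Stage 1 trains encoder + Task 2 + Task 3 on standard-plane images only:

    L_total = w1 (θ1 L_Dice + θ2 L_SLF) + (1 − w1) L_MSE,   w1 = 0.5

with homoscedastic-uncertainty scalings θi = exp(−si) and a + si/2
regularizer per learnable log-variance (si frozen at 0 reduces to the fixed
mixture). Stage 2 loads the stage-1 encoder, freezes it (configurable) and
trains the classification head with binary cross-entropy on standard +
nonstandard images. Freezing guarantees stage 2 cannot degrade the
segmentation/landmark branches; it also makes the bottleneck features of
each image constant, so they are cached once and the head trains on the
cache — mathematically identical to re-running the frozen encoder.

* **Dice loss** pools foreground classes (PS, FH):
  `1 − 2Σyp/(Σy + Σp)`; empty truth with empty prediction is defined as 0.
* **Shape-constrained loss (SLF)** encodes a convexity prior for the FH:
  for foreground pixels p, q and r on the segment between them, a convex
  prediction should be at least as confident at r as at the pair. The loss
  is the expectation over (uniform foreground pair, uniform collinear
  pixel) of `max(0, (1−p_p)(1−p_q)(p_p+p_q−2p_r))`, restricted to triplets
  whose ground-truth labels are all foreground. The exhaustive sum is
  O(N²L), so training uses a seeded Monte-Carlo estimate (256 triplets per
  image by default); an exhaustive mode exists for small masks and is
  tested against an independent brute-force loop. The clamp at zero is
  deliberate: the unclamped form rewards overshooting at interior points,
  which (amplified by the learnable θ2) drives the loss to −∞. By default
  the prior is applied to the FH class only; the PS capsule is convex too
  and can be included via configuration.
* **Heatmap MSE** weights the (right, left, midpoint) maps by
  (1.0, 0.8, 0.6) and averages per pixel, so its magnitude is
  resolution-independent.

Optimization: Adam from lr 1e-4, ×0.1 every 20 epochs, batch size 2,
rotation (−30°, 30°) and scaling (0.9, 1.1) augmentation applied with
identical parameters to image (bilinear), mask (nearest), endpoints
(closed-form affine) and heatmaps (rebuilt from the transformed endpoints).
Model selection: lowest validation total loss (stage 1), highest validation
accuracy (stage 2). A NaN in any loss aborts with a diagnostic.

## Geometry

The FH boundary is the 0.5-level contour of the largest connected
component; the ellipse is fitted with the direct least-squares conic method
(4AC − B² = 1 constraint, numerically stabilized block partitioning, data
centered before fitting). Tangent construction uses the polar line (chord
of contact): intersecting the polar of the external point with the conic
yields both tangency points exactly, branch-free, and every result carries
a discriminant certificate (≤ 1e-6 in tests). Of the two candidates the
one forming the **larger** angle at the right endpoint against the ray to
the left endpoint is selected (the tangent along the leading, distal head
contour); a "min-angle" override exists because the clinical convention is
a documented choice here, not derivable from first principles. Ties break
toward larger y. The angle is reported in (0°, 180°]. Measurement runs in
original-image coordinates (network predictions are mapped back through the
recorded resize factors), so the AoP is resolution-independent; it is
invariant under rigid motions and uniform scaling to numerical precision,
and to < 0.5° under mask rasterization.

## The phantom generator

Real clinical images cannot ship with the package, so every stage is
exercised on seeded synthetic phantoms with analytically known truth: a
bright convex elliptical FH region, an elongated PS capsule (rotated
rectangle with semicircular caps) whose axis endpoints are the landmark
truth, multiplicative speckle `image·(1 + 0.15·g)` clipped to [0, 255], and
nonstandard planes in which the FH or PS is absent, the FH is truncated by
the frame, or only noise remains. The analytic AoP is computed from the
generating ellipse and endpoints through the same tangent construction used
at measurement time, so the stored truth is exact rather than
rasterization-limited. Placement ranges put the head below-right of the
capsule with a 4–12 px gap; the resulting AoP distribution spans roughly
125–180°, overlapping the clinically reported range for the second stage of
labor. Default scale is 96×96 px at 0.2 mm/px so distance metrics land in
plausible clinical magnitudes; intensities (background 30, PS 220, FH 170)
are free parameters chosen for well-defined but non-trivial contrast under
speckle.

What the phantoms do **not** emulate: acoustic shadowing, attenuation,
log-compressed Rayleigh speckle statistics, probe-dependent geometry,
anatomical variability beyond ellipse/capsule shapes. Passing the phantom
study demonstrates that the architecture, losses, training loop and
geometry are implemented correctly and can recover known structure — not
clinical performance.

## The desk-scale study

The reproducible end-to-end experiment (also run by
`scripts/acceptance.py`) uses 26 patients × 10 images (6 standard + 4
nonstandard), split patient-wise 160/40/60 images, `base_channels=8`,
96×96 inputs, 25 stage-1 and 15 stage-2 epochs — sizes chosen so the whole
study runs in minutes on one CPU core. Evaluation on the held-out patients
reports classification accuracy/precision/sensitivity/specificity, Dice
(PS, FH, pooled), endpoint distances in mm, the PS-axis angle error (APT,
computed on undirected lines, reported in [0°, 90°]), |ΔAoP| against the
analytic truth, and Pearson/Bland–Altman agreement (limits mean ± 1.96·SD
with the sample standard deviation).

## Numerical choices and edge cases

* Conic sign convention: A > 0, interior negative; tangent construction
  refuses points inside or on the ellipse (no tangent exists).
* Convolutions feeding a batch norm carry no bias (a constant pre-BN shift
  is exactly removed, so such a bias would be a dead parameter); output
  heads keep their biases.
* Heatmap decoding: per-map argmax, row-major first on ties; an all-zero
  map raises a detection failure instead of fabricating a coordinate.
* Patient-wise split: patients are shuffled by seed, then greedily assigned
  to the set minimizing squared deviation of per-stratum image counts from
  the 5:2:3 targets; exact in divisible cases.
* Degenerate metrics (zero denominators, empty classes) report NaN and are
  flagged, never silently dropped.
* Augmentation endpoints leaving the frame: the draw is retried up to 10
  times, then the sample passes through unaugmented.
* Eq-style input validation fails fast: unknown YAML keys are rejected.

## Known limitations

* At 96×96 the PS is ~26 px long, so a 2–3 px endpoint error already tilts
  its axis by several degrees; |ΔAoP| at desk scale is dominated by this
  lever-arm effect, not by the ellipse fit (geometry-only recovery from
  ground-truth masks is ≤ 0.2° on average).
* Dice for the thin PS capsule trails the FH because the pooled Dice loss
  is dominated by the larger structure.
* The classifier is trained on phantom nonstandard modes; real nonstandard
  planes are far more heterogeneous.
* Single 2-D frames only: no frame-to-frame tracking, no 3-D volumes, no
  DICOM ingestion.
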