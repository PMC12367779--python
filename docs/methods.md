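# Methods

## Box representation and coordinate conventions

All geometry lives in image pixel coordinates: origin at the top-left,
x right, y down. A rotated box is stored in the long-side five-parameter
form `(cx, cy, w, h, θ)` with `h ≥ w > 0` and `θ ∈ [−90°, 90°)` the rotation
of the long side, measured counterclockwise *as displayed on screen* (i.e.
θ > 0 turns the long side from +x toward −y). The interval is half-open
because θ and θ+180° describe the same rectangle; constructors normalize.
Squares are angle-ambiguous modulo 90° and are canonicalized to [−45°, 45°);
this non-identifiability is inherent, not a bug.

The four-vertex (eight-parameter) form orders vertices screen-
counterclockwise starting from the box-frame corner `(−w/2, −h/2)`, which
guarantees that the edge `v2→v3` spans the long side and `v3→v4` the short
side — exactly the pairs the trait formulas consume. `from_quad` accepts any
cyclic start; quads that deviate from a rectangle by more than a relative
tolerance (default 1e-3) fall back to a rotating-calipers minimum-area
enclosing rectangle.

Rotated IoU uses Sutherland–Hodgman clipping of one convex quad by the
other plus the shoelace formula; this is exact for convex polygons, so the
package's IoU carries no grid or sampling error. Tangent boxes have IoU
exactly 0. Greedy descending-score NMS is the final-box filter everywhere.

## Annotation dialects

roLabelImg XML stores `robndbox` elements whose angle is in radians in
[0, 2π) (screen-clockwise) and whose (w, h) are edge lengths along the
tool's local axes, unsorted. Reading converts to the canonical long-side
form (swap sides and shift the angle by 90° when the long side lies along
the tool's local y). DOTA lines are written with the canonical vertex order
and one decimal place, bounding the write→read round-trip error at 0.05 px
per coordinate. Boxes whose quad partially leaves the canvas are kept (they
are annotation truth) with a logged warning.

The 7:2:1 split is a seeded uniform shuffle with sizes
`round(n·rᵢ/Σr)` and the rounding remainder assigned to the training set,
so 1220 items give 854/244/122. Stratification is left to the caller.

## Augmentation

Every image transform moves labels by the same rigid map it applies to
pixels: rotations add their angle to θ and rigid-map centers, flips negate
θ and mirror centers; side lengths are never rescaled, so box areas are
exactly preserved. Arbitrary-angle rotations expand the canvas to contain
the rotated image (no annotation is silently truncated); 90° multiples use
exact array rotation. Cropping keeps a box iff its center lies in the
window. Denoising is a fixed 3×3 median filter. The default expansion
recipe — original plus rotations by 45°, 90°, 135° and 180° — multiplies a
dataset by exactly 5 (244 → 1220). Which transform each source image should
receive beyond that recipe is not specified anywhere authoritative, so
flips, brightness, denoise and crops are opt-in spec fields.

## Synthetic scenes

The generator renders the imaging conditions the package targets: a dark,
slightly green background (darkroom imaging), elongated green blades at
arbitrary orientations, mild Gaussian sensor noise. A blade is the
superellipse `|2η/h|⁴ + |2ξ/w|⁴ ≤ 1` in its box frame: convex, tapering
toward both tips, touching all four box sides, and wide enough near the
tips that the minimum rotated rectangle of the rendered mask recovers the
stored box to about a pixel (a pure ellipse has knife-edge tips that
pixelate away). Scene defaults — 640×640 canvas, 4–12 leaves, lengths
80–240 px, aspect ratios 3–8, noise σ = 3, overlap permitted up to IoU
0.4 — describe a realistic pot image of one to four seedlings at the 640-px
working resolution; tests and the smoke experiment scale the same model
down (96-px canvas, 2–3 leaves) to keep CPU runtimes in minutes. Placement
is sequential rejection sampling (100 retries per leaf) with a placement
error when the overlap constraint cannot be met.

What the generator does *not* emulate: perspective, leaf curvature,
self-occlusion by stems, specular highlights, soil texture. Tests passing
on these scenes therefore validate the geometry, losses, optimization and
bookkeeping of the pipeline — not real-world detection accuracy, which
requires real annotated images.

## Detector

The network is a YOLO-style single-stage rotated detector:

- **Backbone** — MobileOne stages. The depthwise block trains three
  parallel path types (k over-parameterized 3×3 depthwise convolutions,
  a 1×1 depthwise "scale" path, and a normalization-only skip at stride 1),
  the pointwise block two (k 1×1 convolutions plus skip); each path carries
  its own batch normalization. `reparameterize()` folds each normalization
  into its kernel, pads 1×1 and identity kernels to 3×3, and sums — after
  which the block holds exactly one convolution. With frozen normalization
  statistics the fusion is algebraically exact; the test suite bounds the
  deployed-vs-train discrepancy at 1e-5 per block and 1e-4 end to end
  (observed: ~1e-14). The branch count k defaults to 4 (the originating
  MobileOne convention; an over-parameterization count, not the channel
  count).
- **Neck** — compact CSP/PAN: top-down upsample-and-concat, bottom-up
  downsample-and-concat, with an ECA module after every CSP fusion block.
- **ECA** — per-channel global average pooling, a shared 1-D convolution
  across channels of adaptive odd kernel size `k = odd(|log₂C/γ + b/γ|)`
  with γ = 2, b = 1 (so C = 64 → 3, C = 256 → 5), and a sigmoid gate; it
  preserves shape and contracts magnitudes.
- **Head** — one 1×1 convolution per scale (strides 8/16/32), preceded by
  ECA, emitting per anchor: box offsets (x, y, w, h), objectness, class
  scores, and logits over `n_angle_bins` (default 180, one degree per bin).
  Box sizes decode as `(2σ(t))²·anchor` against *short/long-side shaped*
  anchors — since the regression target is always (short, long), anchors
  are tall-thin pairs and no rotated anchor variants are needed. The angle
  decodes as the argmax bin (≤ 0.5-bin quantization), then rotated NMS.

## Composite loss

`L = L_class + L_conf + L_loc` with

- `L_class`: binary cross entropy on class logits (the printed form of the
  BCE is implemented with the standard minus sign; as literally printed it
  would be non-positive);
- `L_conf`: an *unnormalized* double sum — positives contribute
  `(C − Ĉ)²` with Ĉ the rotated IoU between the decoded prediction and its
  ground truth (recomputed each step, treated as a constant target), and
  negatives contribute `λ_noobj·C²`. The negative-branch indicator is
  β^noobj (the printed equation repeats β^obj in both sums, which would
  zero the term whose weight is explicitly described as down-weighting
  object-free cells). λ_noobj is not specified anywhere; 0.5, the classic
  YOLO objectness down-weight, is the default.
- `L_loc = (λ₁/N)Σ obj·L_reg + (λ₂/N)Σ L_CSL + (λ₃/N)Σ L_class` with
  λ₁ = 1, λ₂ = 0.5, λ₃ = 1 and N the number of positive anchors. The
  angle is decoupled from the regression vector: (x, y, w, h) trains with
  CIoU (`1 − IoU + ρ²/c² + αv`, α treated as a constant factor, GIoU
  selectable), and θ trains as a circular classification against a
  Gaussian-smoothed label (window radius 6 bins, σ = radius/3, wrapping at
  the ±90° boundary). A `theta_in_reg` switch restores the coupled reading
  for comparison. The CSL term subtracts the soft target's self-entropy,
  making it a KL divergence: non-negative, exactly zero at the target, and
  with the same gradient as plain cross entropy — this keeps the "every
  term is zero at the exact target" invariant testable.

Target assignment is the YOLOv5 scheme: shape-ratio matching of the box's
(short, long) sides against each anchor (threshold 2.5 at desk scale, 4.0
exposed), in the center cell and the up-to-two nearest neighbor cells.

## Training

Plain SGD with momentum 0.937, weight decay 5e-4, learning rate 0.01 and
batch size 8 as defaults; gradients are averaged over the batch from
batch-of-one forward passes (equivalent for every loss term used) and
clipped to a global norm of 10. Two numerical choices matter at desk scale:

- **Frozen-statistics phase.** With effective batch 1, train-mode batch
  normalization is instance normalization, which disagrees with the
  running-statistics eval path. After `freeze_bn_frac` (default 0.5) of the
  epochs, running estimates are frozen and used in training too; the affine
  parameters keep learning. This removes the train/eval mismatch and is a
  precondition for exact branch fusion.
- **Cosine learning-rate decay** to a tenth of the initial rate.

The standard desk-scale experiment (`rotphenex.experiments.overfit_smoke`)
trains the width-0.25 detector on five 96-px scenes for 1000 epochs
(about five minutes on one CPU) and checks ≥ 10× total-loss reduction and
≥ 80% of leaves re-localized at rotated IoU ≥ 0.5. Full-scale training
(640 px, 300 epochs) is supported by configuration but is a GPU-scale
undertaking and not exercised by the test suite.

## Evaluation

VOC protocol with rotated IoU: greedy confidence-descending one-to-one
matching, TP at IoU ≥ 0.5 (the threshold is exposed; nothing authoritative
fixes it, 0.5 is the convention of the baselines this family of models is
compared against), all-points interpolated AP, mAP as the class mean.
Trait agreement is the R² of the least-squares line of extracted versus
measured values, per trait.

## Trait extraction

Traits are computed from the canonical quad by the vertex-pair formulas.
Inclination is reported in [0°, 90°] — the absolute-value arctangent cannot
distinguish left from right lean — and the signed angle is kept in the
output table. Traits are computed in pixel units with optional millimeter
calibration supplied by the user (`ScaleCalibration`); no normalization of
vertex coordinates is applied, because no definition of such a
normalization is available and the pixel-plus-calibration path is
unambiguous. An optional `plant_height_derived` column (vertical pixel
extent over all leaf quads) is provided but flagged as derived — it has no
formula in the trait table.

## Numerical and testing choices

- The rasterization oracle for rotated IoU samples only the *intersection*
  membership on a 1000×1000 sub-pixel grid over the overlap of the two
  axis-aligned extents (box areas are exact), keeping the quantization
  error orders of magnitude below the 1e-3 assertion bound while staying
  fast enough to run hundreds of pairs.
- Gradient correctness of the in-package autodiff engine is verified
  against central finite differences for every op the network uses,
  including grouped/strided convolution.
- Acceptance-facing computations (geometry oracles, reparameterization
  bounds, trait recovery, the overfit experiment) are recomputed from
  scratch by `scripts/acceptance.py` under a caller-supplied seed; nothing
  is cached or hard-coded beyond the published comparison-table inputs.

## Known limitations

- Synthetic scenes are geometric stand-ins; no claim is made about accuracy
  on real wheat images, whose dataset is not publicly deposited.
- The detector is single-class by default (multi-class is configurational
  but untested beyond shape contracts).
- Desk-scale training is full-batch on a handful of scenes; convergence
  behavior at the full-scale configuration (hundreds of images, batch 8)
  is supported but not characterized.
- CIoU's α is treated as a constant in the gradient (the standard
  implementation practice); the loss value is unaffected.
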