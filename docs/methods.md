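# Methods

This note documents the models, procedures, and numerical choices behind
`hueprior`, and what the synthetic test substrate does and does not show
about real cultivation imagery.

## Hue representation and the color database

All hue arithmetic uses the half-scale convention: hue in degrees divided
by two, stored as integers in [0, 179], so division by 180 normalizes to
[0, 1]. RGB→HSV conversion goes through `skimage.color.rgb2hsv`; the hue
fraction is rounded to the nearest half-scale bin. Pixels with undefined
hue (zero saturation) are assigned hue 0 — they are achromatic, so any
assignment is conventional, and 0 keeps the plane integer-valued.

A `HueRecord` is one image's 180-bin histogram of pixel fractions over its
fruit-body region, with the pixel count. Pooling over an environment is a
pixel-count-weighted mean, so the pooled vector equals the hue distribution
of all fruit-body pixels in that environment taken together; per-image
equal weighting would over-represent small fruit bodies.

The fruit-body region defaults to rasterized annotation boxes. Boxes
inevitably include background, so `record_from_image` accepts a saturation
floor that drops weakly saturated pixels, whose hue is numerically
unreliable (hue resolution in an 8-bit RGB image degrades as S·V shrinks)
and which in shelf imagery are mostly substrate and hardware. The library
default is 0 (no filtering); the `analyze-hue` command defaults to 0.4,
which in our scenes removes the dim substrate while keeping all cap pixels
(drawn with S ≥ 0.45).

## Interval estimation

The retained hue interval for an environment is the **minimal-width
contiguous circular window** whose pooled-histogram mass reaches a coverage
target *q* (default 0.90; wider 0.95 where a conservative interval is
wanted). The hue axis is treated as circular (bin 179 adjoins bin 0), so a
red regime straddling the origin is representable. Ties on width break
toward the smaller start index, making the estimate deterministic. A
wrapped winner is reported as two forward intervals. Equality at exactly
*q* is accepted with a 1e-12 absolute slack to absorb float accumulation.
The estimator is verified against an exhaustive scan of all 180×180
circular windows computed by direct summation.

Coverage-window estimation is our choice of rule; a field deployment would
calibrate *q* against the cost of admitting background hues (larger *q*
widens the window).

## The fourth channel

`make_hue_mask` keeps `hue/180` on pixels whose hue lies inside any
retained interval — endpoints inclusive — and zeroes the rest, so retained
pixels carry graded hue rather than a binary flag. RGB planes are scaled to
[0, 1] for plane-range homogeneity. Presets: `greenhouse`/`semi_open` →
`[[4, 38]]`, `automated` → `[[110, 155]]`, and a union preset `merged =
[[4, 38], [78, 155]]` for images of unknown provenance. The merged preset's
cool band deliberately starts at 78 rather than 110 — the two figures both
appear in the source material for this design and the discrepancy is
surfaced here rather than silently resolved; the per-environment presets
use 110.

## ColorWeight

A seeded, forward-only feature module on the masked hue plane:

- Three conv stages with strides (2, 4, 2) and kernels (3, 5, 3) — the
  only single-convolution stride triple realizing 640→320→80→40; the
  stride-4 stage gets the larger kernel for adequate receptive field.
  Channels 1→32→64→64, each stage followed by batch normalization
  (inference statistics) and SiLU, the YOLO-family idiom.
- Global average pooling to 64 (a plain flatten could not produce a
  64-vector), then `Linear(64, 64)` → the residual-injection projection.
- Statistics: per-channel spatial max and mean of the final block (two
  64-vectors), plus the scalar max and mean of the raw input each embedded
  to 64 by a shared learned 1→64 map (the input has one channel, so a
  bridging map is needed to make all four blocks 64-long), concatenated to
  256 and mapped by `Linear(256, 64)`.
- Weights: fan-in uniform (Kaiming-uniform bounds), drawn once from a
  seeded generator; identical seeds give bitwise-identical modules. The
  flow generalizes to any square input side divisible by 16.

## Hyperedge generation with color injection

Tokens are spatial feature vectors (n×d). The baseline generator pools
tokens (per-channel max and mean → 2d), projects the pooled summary to m
prototype deltas and m dynamic offsets, adds learned global prototypes, and
assigns participation by a row softmax of token–prototype similarity at
temperature 1/√d (m defaults to 8). Color enters additively at two points:
the ColorWeight projection is residually added to the mean-pooled summary
(through a bias-free adapter when widths differ), and the statistics
projection feeds a bias-free linear map added to the dynamic offset. The
offset path was chosen over concatenation because it leaves the
participation shape unchanged. Both injections vanish exactly at zero, so
the color-free baseline is a special case — a property the tests pin down
exactly.

Hyperedge messages are participation-weighted token means; an edge with
zero participation mass yields the zero message by convention.

The "same-color regions cohere" behavior is demonstrated as a statistical
property: tokens derived from a half-masked hue input split into
color-bearing and color-free groups, and over 20 seeded trials the
within-minus-between cosine similarity of participation rows is positive
and its mean exceeds the color-free baseline's. At freshly initialized
weights the absolute similarities are small (participation is near
uniform); the property is directional, not a trained effect.

## Stacked gated attention

Each layer applies standard multi-head scaled dot-product self-attention
(default 4 heads) and fuses with the carried state through an elementwise
gate `g = sigmoid(Linear([Attn; H_prev]))`, `H = g·Attn + (1−g)·H_prev` —
so every output element lies between the attended and carried values, and
saturating the gate recovers the identity (g→0) or pure replacement (g→1)
limits. Default depth is 2, keeping the module's parameter budget small.
The final output is a learned softmax-weighted sum of the per-layer states
(uniform at initialization); feature maps are tokenized by flattening the
spatial grid and restored on exit. No positional encoding is used — the
module operates on already spatially structured detector features.

## Synthetic scenes

The generator emulates the aspects of cultivation imagery the color-prior
stack actually depends on: environment-conditioned hue regimes, stage
hue-separability, background clutter outside the interval, partial
occlusion by hardware, dimming, blur, and small targets — each scene is
640×640 with YOLO TXT labels, bitwise-deterministic given its seed.

- Objects are ellipse clusters with stage-dependent morphology: `base`
  small low-contrast disks, `mulberry`/`coral` clusters of 3–8 tiny caps,
  `forming` single mid-size caps, `maturation` large flattened caps with a
  hue pushed toward its band's upper edge.
- Object hues are drawn from per-stage equal sub-bands of the environment
  interval shrunk by a 2-bin edge margin, so stages are hue-separable and
  8-bit round-trips cannot push a pixel outside the generating interval.
  Cap saturation is kept ≥ 0.45 so quantized hue stays faithful.
- Background substrate and clutter hues are sampled at least 2 bins
  outside every retained interval.
- Occlusion draws a gray strut across the object (tracked in a debug
  mask); dimming scales the value channel; blur is Gaussian. Dimming and
  blur default to off, mirroring the geometric-only augmentation policy at
  train time; evaluation-style runs enable them explicitly.
- Per-scene seeds derive from one root via `SeedSequence.generate_state`
  reduced mod 2³¹; the rule is recorded in the dataset manifest.

What passing tests on this substrate show: the estimation, masking,
feature, and metric machinery is correct and the hue-prior mechanism works
when hue really does separate foreground and stages. What they do not
show: performance on real crops — real fruit bodies have texture, specular
highlights, intra-stage hue overlap, and annotation noise the generator
deliberately omits; no photorealism or radiometric camera model is
attempted.

## Dataset pipeline

Augmentation is geometric only (translation, rotation, scaling);
photometric edits are excluded to preserve the color statistics the stack
depends on. Rotated boxes become axis-aligned hulls (YOLO TXT cannot
express rotation); boxes clipped below 20% of their transformed area are
dropped. Non-square images are letterboxed (uniform scale + symmetric
black padding) by default — padding preserves every label, whereas
cropping can destroy them. Splitting shuffles by seed and partitions with
largest-remainder rounding, so 100 ids under 8:1:1 give exactly 80/10/10;
the shuffle is unstratified, with stratification left to the caller.

## Metrics

Matching is greedy in descending confidence; a prediction is a true
positive iff it shares the class of, and has IoU ≥ 0.5 with, an unmatched
ground truth. AP uses 101-point interpolation (the COCO convention) and
mAP@0.5 is the unweighted mean over classes with ground truth. The
missed-detection rate is unmatched ground truths over all ground truths.
A prediction that localizes a ground truth (IoU ≥ 0.5) with the wrong
stage counts as a maturity misclassification; the rate divides by matched
plus misclassified associations. F1 is computed at a confidence threshold
(default 0.25). Zero-denominator rates report 0 with a warning rather than
raising.

## Separability demonstration

The four-channel benefit is demonstrated with a deliberately small head: a
multinomial logistic regression staging object crops from their per-plane
statistics (mean, std, 6-bin histogram per plane). Scenes are rendered in
the cool regime with per-scene dimming drawn from [0.35, 1.0] and 20%
occlusion; 30 scenes ≈ 180 crops, 35% held out. RGB statistics drift with
the dimming factor while the masked hue plane is brightness-invariant and
zero on clutter, so the same head scores materially higher with the fourth
channel (typically ~0.65–0.83 vs ~0.38–0.46 held-out accuracy across
seeds). Problem sizes here and in the acceptance script (6-scene hue
databases, 30-scene separability runs, 20-seed coherence trials) were
chosen as the smallest that make the statistical properties stable.

## Known limitations

- All neural-style modules are forward-only with seeded random weights;
  nothing here trains, and no compatibility with any released detector
  checkpoint is claimed.
- The hue-interval estimator assumes a unimodal (after circular wrap)
  target regime; a genuinely bimodal crop distribution would be better
  served by estimating per-mode windows.
- The misclassification rate attributes each wrong-stage prediction to its
  best-IoU ground truth without enforcing one-to-one assignment, which can
  double-count a ground truth under duplicate predictions.
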