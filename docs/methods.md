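# Methods

`retinaflow` simulates intra-operative retinal microscope video as layered
scenes with exact dense-flow ground truth, trains a multi-task
flow+segmentation network on those records, and evaluates any flow source
with a point-tracking protocol.  This note documents the models, the
parameters that matter, and the design decisions taken where the design was
genuinely open.

## Scene model and ground-truth flow

A frame is an alpha-over composite of three layer roles:

* **retina** (bottom, opaque): a fundus texture — either a user-supplied
  frame reduced by the retina-crop extractor, or a procedural texture;
* **tool** (middle): zero, one or two metallic instruments, each a group of
  three sub-layers (cast shadow, shaft, glare overlay) that move together;
* **fov** (top): a black vignette with a circular transparent hole
  (radius U[0.4, 0.8]·H, centre U[0.4, 0.6] of each dimension, rim
  softened by a Gaussian blur of a fixed 15 px kernel).

Each layer carries a chain of transforms.  Flow-producing transforms have
closed-form displacement fields:

* affine (translation magnitude U[0, 10] px with uniform direction;
  rotation U[−5°, 5°]; scaling U[0.9, 1.1]) — `f(p) = A(p−c) + c + t − p`;
* pincushion distortion — radially outward `d(r) = d_max (r/r_corner)³`
  with `d_max` ~ U[10, 50] px, the cubic being the leading term of the
  standard radial lens model;
* bubbling (injection ripple) — compact-support
  `d(r) = a · sin(πr/R) · e^{−(r/R)²}` with centre U[0.2, 0.8] of each
  dimension, radius R ~ U[0.15, 0.3]·H and amplitude a ~ U[2, 10] px (the
  amplitude interval is this package's choice; only the centre/radius
  intervals are externally prescribed).

A chain's total flow composes left to right as
`f_ac(p) = f_ab(p) + f_bc(p + f_ab(p))`.  The transformed frame is rendered
by *inverting* the total forward flow (exactly for affine chains; by a
fixed-point iteration, 10 rounds, for radial chains — all simulator flows
have displacement gradients well below 1, so the iteration contracts) and
sampling the source layer bilinearly.  This guarantees the warp-consistency
identity `warp_backward(frame2, flow) ≈ frame1` that the audit measures.

A `double_exposure` modifier blends warped and unwarped colour with weight
α ~ U[0.3, 0.7] (0.05 probability on retina chains) while the stored flow
remains the full motion — ghosting from sudden eye movement with an
unambiguous training target.  Photometric transforms (global brightness
±15, feathered local brightness ±40 in a disc of radius U[0.1, 0.3]·H,
Gaussian blur ≤ 5 px) change colour only, are drawn per layer with
probabilities 0.25 / 0.10 / 0.10, and are applied to the second frame as an
inter-frame appearance change.  Finally both frames receive Gaussian sensor
noise (σ ~ U[1, 5] counts) and a JPEG encode/decode round trip (quality
U{60..90}); the noise and quality intervals are this package's defaults.

### Ground-truth semantics

* `flow_full(p)`: the flow of the topmost layer with opacity > 0.5 at `p`
  in frame 1 (shadows are at most 0.5 opaque, so they never override).
* `flow_simple(p)`: the **retina** flow everywhere inside the field of
  view, zero outside — the training target.  Tool motion is erased, which
  is what teaches an estimator to inpaint retinal motion through
  occlusions.
* Segmentation masks label in/out of the FOV circle (1 = retina visible or
  occluded by a tool, 0 = outside); tools do not change the mask.
* An `occlusion` mask marks pixels whose colour mixes layers with
  different motions (tool/shadow/glare support, the blurred FOV rim, and
  pixels that warp into the moved vignette's black): the single-flow warp
  identity cannot hold there, so fidelity audits exclude them.

### The 16-subset recipe

The default configuration produces 16 subsets × 2000 records = 32 000
pairs at 512×384 px.  Subsets 1–5 are retina-only with one transform family
each (translation, rotation, scaling, pincushion, bubbling); subsets 6–10
add the FOV layer (families: translation, rotation, scaling, bubbling, and
rotation+scaling combined for the tenth — the source recipe lists six
family names for five subsets, so the trailing pair is folded into one
subset); subsets 11–16 add one (11–13) or two (14–16) tools, every layer
drawing an independent translation/rotation/scaling chain.  Variant `nl`
disables shadows, glare and the tool HSV matching; `nl_nb` additionally
zeroes both brightness-change probabilities.

### Procedural stand-ins

Clinical walk-through recordings cannot ship with the package, so the
bottom layer defaults to a procedural texture: a smooth red-orange HSV
field with vignette, a brighter elliptical disc, and a vessel tree grown by
branching random walks with width decay, darkened toward dark red.  The
parameters were tuned once to satisfy the testable postconditions (two
intensity modes, vessels locally darker, determinism) — not for
photorealism.  Likewise the three tool templates (light pipe, cutter,
forceps) are drawn procedurally as tapered metallic shafts with
kind-specific tips.  Passing tests on these textures demonstrates the
*pipeline* (geometry, bookkeeping, losses, protocol) is sound; it says
nothing about appearance-domain transfer to real surgical video, which
requires real textures via `--fundus-dir`/`extract_retina_crop`.

Tool placement follows the stated intervals: template scale U[0.8, 1.5],
shaft widening 1→U[1.5, 3] growing linearly with the distance of the shaft
axis point from the image centre (a flat-shaded proxy for the 3-D pose of
an instrument pivoting at a scleral port), rotation U[−80°, 80°], tip at
U[0.2, 0.8]·H vertically and U[0.15, 0.5]·W (light pipe) or U[0.4, 0.85]·W
(others) horizontally, Gaussian blur kernel {3, 5, 7} px.  Tool colour is
converted to HSV; hue and saturation are set to the retina's circular-mean
hue and mean saturation and the value is rescaled to a uniform draw in
[0, mean retina value].  The shadow is the pre-blur tool support translated
by offset U[0, 70] px at angle U[−45°, 45°] with opacity U[0, 0.5]; glare
is 1–5 white faded ovals of radius U[2, 12] px at equal arc-length spacing
along the shaft centreline, with yellow/blue crests at opacity
U[0.1, 0.6].

## Network and cost

The estimator is a FlowNetSimple-pattern encoder–decoder: 6 input channels
(two concatenated RGB frames, scaled to [−0.5, 0.5]), ten encoder convs
(7/5/5 then 3×3 kernels, six stride-2 stages, 64→1024 base channels), and
a decoder that at each level bilinearly upsamples the coarser feature map
and flow, concatenates the matching encoder skip, and applies a 3×3 conv.
Prediction heads emit flow (plus 2 segmentation logits in the `comb`
variant) at five scales, 1/64 to 1/4 of the input; the `branch` variant
instead runs a second, half-width decoder for segmentation.  All
activations are leaky ReLUs (slope 0.01); channel counts scale with a
width multiplier, rounded to multiples of 8.  At width 1.0 the model has
34.3 M parameters.  Up-convolutions are realised as bilinear resize + 3×3
conv (equivalent receptive behaviour to transposed 4×4 convs with fewer
checkerboard pathologies).

The cost has four terms: (1) the mean end-point error per scale, averaged
over scales with equal weight (coarse scales carry the global-motion
signal; averaging per pixel across pooled scales instead starves them of
gradient and we observed training collapse to near-zero predictions);
(2) an L2 weight-energy penalty, λ_reg = 1e−7; (3) a summed softmax
cross-entropy on the segmentation at every scale (majority-pooled masks),
λ_seg = 1e−3; (4) a total-variation penalty λ_var = 1e−6 on the finest
flow prediction: the per-pixel magnitude of ∂f/∂x + ∂f/∂y (forward
differences; the absolute value is taken per pixel since a signed sum is
not a penalty), masked to zero in a 3 px band around the FOV border so the
genuine flow discontinuity there is not smoothed away.  Coarse-scale flow
ground truth is block-average-pooled with magnitudes divided by the pool
factor, so every scale predicts in the pixel units of its own grid.

Training uses Adam (β₁ 0.9, β₂ 0.999) with the exponential schedule
lr₀ · 0.95^(step/decay_step); the full-scale defaults are lr₀ = 1e−4,
batch 10, decay step 1e4, 100 epochs, 95/5 train/validation split.

### Desk-scale training benchmark

`translation_smoke_benchmark` is the package's end-to-end learning check:
200 retina-only pure-translation records at 64×48 px (no photometric
augmentation or degradation), a width-0.25 / 4-level network, 30 epochs.
At this scale the free training hyper-parameters are re-chosen (the
full-scale settings above are tuned for 32 000 records): batch 2,
lr₀ = 1e−3, global gradient-norm clipping at 2, random horizontal/vertical
flip augmentation with consistently flipped flow, stochastic weight
averaging over the last 30 % of epochs, and final selection between the
SWA and best-validation weights on the 20-record validation split.  The
reference point is the zero-flow predictor, whose EPE equals the mean GT
displacement (≈ 5 px for U[0, 10] translations); across seeds the trained
network reduces it by roughly 50–70 %.  This verifies gradients, optimiser
and data plumbing — it is far below the scale needed for the real task.

## Tracking protocol

Points advance by `p ← p + f_t(p)` with bilinear flow sampling.  A point
leaving the frame, or outside the FOV mask at an annotated frame, is
invalid from then on and excluded from statistics.

* **s-EPE**: for every 11-frame fragment between consecutive annotations,
  the point is re-seeded at the start annotation and the L2 error at the
  fragment end is recorded; fragments are tracked in both directions when
  backward flows exist and all errors are pooled.
* **l-EPE**: error at the final frame of the full track (forward from the
  first annotation and backward from the last, pooled).
* **grid EPE**: every in-FOV pixel of frame 1 is a vertex ("grid size of a
  single pixel"); vertices run forward through the odd frames and back
  through the even frames, and the distance between final and initial
  position is reported.  An invertible-but-wrong flow cannot cheat this to
  zero; a non-inverse constant flow of 1 px/frame accumulates exactly
  2·steps px.

The synthetic benchmark clip applies a smooth sinusoidal affine camera
path to a fundus texture; because affine flow fields are linear in
position, bilinear sampling of the ground-truth flow is *exact*, so GT
tracking errors are at interpolation noise (≪ 0.5 px) and evaluator bugs
surface immediately.  Annotations are the four strongest well-separated
gradient maxima inside the FOV, propagated through the known motion.  With
`with_tool=True` a cutter sweeps horizontally through an annotated point
mid-clip; the "full" flow sequence overrides retina motion with the tool's
motion under its mask, while the sweep amplitude is capped so that a point
dragged along by the full flow stays inside the frame and therefore inside
the statistics.  Tracking the inpainted (retina) flows versus the full
flows quantifies, in silico, the benefit of tool-flow suppression.

## Numerical choices and limitations

* Flow convention: forward (frame 1 → frame 2), components (x, y),
  0-based coordinates, x rightward, y downward; `.flo` files are
  little-endian Middlebury format, bit-exact on round trip.
* All sub-pixel sampling is bilinear; out-of-bounds policy is explicit
  (fill + validity mask for warping, nearest-edge extrapolation for flow
  composition) so evaluation can exclude invalid samples.
* Retina/FOV layers warp with nearest-edge extrapolation (no border
  holes); tool layers warp with zero fill.
* JPEG round trips disable chroma subsampling at quality ≥ 95 so the
  near-lossless setting is actually near-lossless.
* Record sampling is a pure function of (subset seed, record index); a
  placement that pushes a tool off-canvas is retried with a fresh sub-seed
  up to 10 times.
* Audit problem sizes: the simulator audit uses 200 records at 256×192 px
  spread over all 16 subsets; the dataset-recipe check builds 2 records
  per subset at full 512×384 px.  These sizes were chosen once as
  representative desk-scale samples.
* Not modelled: rolling shutter, chromatic aberration, vignetting
  gradients, ERM fragments and staining dyes, physically based glare, and
  any reproduction of clinical benchmark data.
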