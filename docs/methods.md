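# Methods

This note records the model, the conventions and the genuinely open design
choices made in this package, in the package's own words. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model

**Encoder.** The input is a single-channel H×W frame, min–max normalised to
[0, 1] per frame. A three-layer convolutional stem (3×3 convolution → batch
normalisation → ReLU, with 2×2 max-pooling between the layers) produces
feature maps at resolutions H, H/2 and H/4; all three are kept for skip
connections. The H/4 map is cut into non-overlapping patches, flattened and
linearly projected to D dimensions, and learned position embeddings are
added: `z₀ = [x_p¹E; …; x_pᴺE] + E_pos`. The patch size is expressed in
*input* pixels (P = 16 for the speech configuration), so the token grid is
(H/P)×(W/P) — the stem's 4× downsampling is compensated by taking P/4-pixel
patches on the feature map, and N = HW/P² (256 tokens for a 256×256 frame).
With the identity stem the same formula applies to raw pixels. Tokens pass
through n pre-norm transformer layers
(`z′ = MSA(LN(z)) + z`, `z = MLP(LN(z′)) + z′`), a final layer norm, and are
reshaped row-major to a (H/P)×(W/P)×D grid.

The transformer width/depth is not fixed by the architecture; the default is
the standard base setting (D = 768, n = 12, 12 heads, MLP 3072) and a "tiny"
setting (D = 64, n = 2, 4 heads, MLP 128) is defined for desk-scale work.
A deeper residual stem could be substituted for the three-conv stem — the
encoder is pluggable — but the three-conv form is the default.

**Decoder.** Four stages of bilinear 2× up-sampling followed by a 3×3
convolution, batch normalisation and ReLU take the token grid from H/16 back
to H; the three stem maps enter by channel concatenation before the
convolution of stages 2–4. Default stage widths are (256, 128, 64, 16),
tiny widths (32, 32, 16, 16).

**Refinement module.** A 1×1 convolution predicts a 2-channel directional
field from the stage features. The features are then resampled along that
field for N = 6 steps, `Fᵏ(p) = Fᵏ⁻¹(p + DF(p))`, with bilinear
interpolation at fractional coordinates and border clamping outside the
grid; the field is read once and reused for all N steps (the recurrence
indexes DF(p), not a per-step re-prediction), so the warp is one sparse
sampling operator applied N times. `Fᴺ` is concatenated with `F⁰` and fused
by a 1×1 convolution. Refinement modules sit after each of the three skip
connections, deepest first; the fourth arm of the 0–4 ablation places a
module after the first (skip-less) stage. The module's own *predicted* field
drives rectification at both training and inference time; the ground-truth
field is only a supervision target.

**Aggregation.** Every refined map is projected to num_classes channels by a
bias-free 1×1 convolution, bilinearly up-sampled to the decoder output
resolution and summed with the decoder head's own projection. Bias-free
projection makes an all-zero refined map an exact additive identity, and the
projection-before-sum order makes the addition well-typed across stage
widths (the alternative, summing before projection, is impossible for
heterogeneous channel counts without extra convolutions).

## Directional-field ground truth

For each foreground pixel p, DF(p) = (p − b)/‖p − b‖ where b is the nearest
boundary pixel under Euclidean distance; boundary pixels themselves and
background carry (0, 0) (the b = p case would divide by zero). A boundary
pixel is a pixel whose 4-neighbourhood (default) contains a different label,
with out-of-grid treated as background. Ties among equidistant boundary
pixels are broken by row-major order, making the field a pure function of
the mask. Channel order is (dx, dy) in 0-based pixel-centre coordinates.

Two conventions are implemented because "the boundaries of the vocal tract
and articulators" can be read either way: `per-class` (default — each class
refined against its own contour) and `union-foreground` (all class
boundaries shared). Neither is claimed as the original intent; both satisfy
the same oracle.

The fast path uses a KD-tree with exact tie resolution: squared pixel
distances are integers, so all boundary pixels at the minimal integer
squared distance are enumerated and the row-major smallest chosen — this
matches the exhaustive brute-force implementation bit for bit, which the
tests assert on random blob masks.

## Losses, metrics and model selection

The soft Dice loss is `1 − mean_fg (2Σpg + ε)/(Σp + Σg + ε)` with ε = 1e−5,
averaged over the six foreground classes (background excluded, matching the
evaluation). Directional-field supervision is the mean squared vector error
over foreground pixels, at each refinement module's resolution
(ground truth down-sampled by nearest index), weighted by λ (default 1.0;
λ = 0 disables it). The supervision loss form is a package choice — the
field-learning idea fixes the target but not the loss.

Gradients flow through the warp with respect to the *feature values* only;
the displacement coordinates are constants under differentiation. The DF
head therefore learns from its supervision loss alone, which is consistent
with treating the ground-truth field as a supervision target, and keeps the
warp's adjoint exact (the transpose of the sparse sampling operator).

Evaluation uses the per-class Dice coefficient (defined as 1.0 when the
class is absent from both masks) and the unqualified (100th-percentile)
symmetric Hausdorff distance between boundary pixel sets. When one side
lacks the class the Hausdorff value is *undefined* and recorded as missing —
never 0, never silently infinite. Distances are in pixels unless pixel
spacing metadata is present, in which case they are scaled to mm; the
report's `units` field is mandatory.

"Validation accuracy" for model selection is the mean foreground Dice on the
validation set — the same quantity the evaluation tables report.

## Closure analysis

A frame is closed iff any soft-palate pixel is 8-adjacent to a head pixel,
optionally restricted to a rectangular posterior ROI. The ROI exists because
in real anatomy the palate is permanently attached to the hard palate
(within the head class) anteriorly; the phantoms are built so the default
full-frame ROI is unambiguous. Events are maximal closed runs (inclusive
intervals). Matching: a predicted event overlapping no ground-truth event is
*additional*; overlapping ≥ 2 is *merged*; overlapping exactly one is
*correct* when both endpoints are within ±1 frame (covering both one-frame
extension and one-frame shrinkage — the shrinkage side is a package
decision, as published schemes only state extension); a ground-truth event
with no overlapping prediction is *missed*; ground-truth events covered only
by a merged prediction are neither correct nor missed. If several
single-overlap predictions hit the same ground-truth event, the earliest
tolerant one is the match and the rest are additional, preserving
`total = correct + additional + merged` exactly.

Frame metrics are accuracy, false-positive rate (predicted closed, truly
open) and false-negative rate, as percentages; they partition the frames, so
they sum to 100 exactly.

## Synthetic phantoms

The generator emulates the structure of a public midsagittal speech-MRI
dataset (5 series of 105, 71, 71, 78 and 67 frames of 256×256 pixels; the
series lengths as printed sum to 392): per-subject temporal series, seven
labels, and per-frame binary closure labels. Geometry is parametric
(bands, a rectangle flap, an ellipse tongue) rather than image-sampled, so
contact is exact by construction: on scheduled-closed frames the palate tip
is 4-adjacent to the posterior wall; on open frames the gap is 3 px (≥ 2 px
contract). Intensities are per-class base levels plus additive Gaussian
noise (σ = 0.02 by default) — a stand-in for tissue contrast, not a claim
about MR physics (no coil profile, banding, or motion artefacts). Random
blob masks (thresholded smoothed noise) provide oracle fixtures.

Because the phantoms have piecewise-constant intensities, sharp class
boundaries and a rigid geometry, passing tests demonstrate the correctness
of the machinery (shapes, gradients, oracles, event logic) — not
segmentation accuracy on real speech MRI, which has soft tissue contrast,
motion blur and annotation noise.

## Problem sizes and numerical choices

Desk-scale work uses the tiny configuration on 64×64 phantoms: the learning
smoke recipe trains on 8 frames, full-batch Adam at lr 1e−3 (a standard
fast-convergence choice for few-step full-batch optimisation; the 2e−4
default belongs to the full 150-epoch regime), at most 300 steps. Oracle
equivalences run on 32×32 blob masks (100 for the directional field, 50
pairs for the metrics). The ablation scaffolding runs two optimizer steps
per arm on 32×32 phantoms — it demonstrates completion and report shape,
not the refinement-count effect, which requires real data at scale.

All tensors are float32; Adam uses bias-corrected moments; max-pooling
splits gradient evenly across tied maxima; bilinear resizing aligns grid
endpoints and is exactly the identity at unchanged size. Determinism:
model weights are a pure function of the configuration seed
(`numpy.random.Generator`), batch order of the training seed, and the
phantom generator of its own seed; identical seeds reproduce results
bit for bit.

## Known limitations

- The few-step smoke training is seed-sensitive: the vocal-tract airway has
  the lowest intensity contrast against background in the phantoms, and with
  some seeds the Dice loss leaves that one class on a plateau within the
  300-step budget (its class Dice stays at 0 and the mean foreground Dice
  sits near 0.83 instead of ≈0.99). This is an optimisation plateau of the
  soft Dice objective at tiny step counts, not a gradient defect — all
  parameters receive gradients and most seeds converge fully.
- The network runs on the package's own NumPy autodiff engine: single
  process, CPU only. The default (base-width) configuration is practical for
  inference and small studies, not for 150-epoch training on real series.
- No pretrained weights; initialisation is truncated-normal/He from the
  seed. A weight-loading hook exists via `load_state_dict`.
- 2-D only; no 3-D fields, signed distance transforms or level sets.
- Closure analysis stops at event classification; automatic velopharyngeal
  insufficiency diagnosis is out of scope.
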