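# Methods

## Problem setting

A single frosted leaf is photographed face-on against one of three
field backgrounds: *blurred* (defocused low-contrast canopy), *soil*
(brown clod texture), or *weeds* (green clutter, some of it touching
the leaf). The task is to label every pixel as background, clear leaf
tissue, or frost, and to report the Frost Coverage Ratio
FCR = 100·A_frost/A_leaf with severity staged as
level I (0, 30], II (30, 60], III (60, 100] percent. An FCR of
exactly 0 is reported as level NONE; the staging starts strictly
above zero.

## The segmenter

**Colour representation.** RGB is converted to HSV with all three
channels — including hue — rescaled to [0, 255], so channel weights
act on comparable ranges. Hue cyclicity is ignored in gradient
computation; red-adjacent hues can therefore show spurious gradients.
This is harmless for green foliage but is a known limitation for,
say, autumn-red leaves.

**Gradient fusion.** Per-channel gradients use the 4-neighbour
Laplacian magnitude (centre −4, N/S/E/W +1, replicate-padded).
Channel weights are the product of fixed weights w = (0.5, 1.2, 0.8)
for H/S/V and adaptive entropy weights ε_c (each channel's histogram
entropy, normalized to sum one), renormalized so the combined colour
weights sum to one. Either pure scheme is recoverable: set the fixed
weights equal to get pure entropy weighting, or feed equal-entropy
channels to get the fixed table. The edge term adds λ·(Sobel +
Laplacian) of the V channel, λ = 0.7 by default. Every component map
is first rescaled to [0, 1] by its own maximum because raw Laplacian
and Sobel responses differ by orders of magnitude; λ then trades off
comparable quantities.

A 13-tap antisymmetric least-squares derivative kernel
(t[i] = i/182, i ∈ [−6, 6]), applied along x and y and combined by
the per-pixel max of absolute responses, is provided as an edge-detail
diagnostic; the taps are configurable.

**Robust normalization.** Before refinement the fused map is divided
by the mean gradient above its own isodata cut — an estimate of the
typical strength of a genuine edge — and clipped to [0, 1]. Dividing
by the global maximum instead lets a few extreme frost-texture
responses set the scale and pushes weak-but-real leaf contours below
the suppression threshold; a fixed high percentile fails the opposite
way on nearly-smooth scenes, where it lands in the noise floor.

**Adaptive morphological refinement.** For each kernel in the
background's schedule (blurred [3], soil [3, 5], weeds [3, 5, 7]),
one pass applies a plain grey closing followed by
opening-by-reconstruction, and each pass ends by zeroing values below
`morph_threshold` (default 0.2 on the normalized scale; values
outside [0.1, 0.4] trigger a validation warning). Passes repeat up to
`iterations` times (default 5, accepted range 5–10) with fixed-point
short-circuiting — in practice one or two passes converge. The
closing comes first and is deliberately non-geodesic: derivative
operators leave thin double ridges flanking every step edge, and the
closing merges them into bands thick enough to survive the
reconstruction marker. With the geodesic opening first, a thin closed
contour has an empty erosion marker and is erased wholesale.

**Leaf localization.** The refined map is thresholded by isodata,
bounded above by `255·morph_threshold` (after refinement the
histogram is {0} ∪ [threshold, 1], and unbounded isodata would split
the survivors rather than separate them from background, discarding
the weaker half of the contour). The binary edge mask is closed by
dilate/fill-holes/erode with a background-keyed bridging radius, the
largest 8-connected component is kept as the leaf, and a
background-keyed binary opening shaves off clutter welded to the
contour ((radius, opening iterations) = blurred (3, 0), soil (7, 8),
weeds (3, 20) — soil texture breaks the contour into longer gaps,
weed blobs weld onto it). The final erosion goes one step further
than the dilation because the gradient ridge straddles the true edge
by about one pixel. These constants were chosen from a leaf-IoU sweep
on generator scenes (seeds disjoint from the test suites). If the
refinement suppresses the entire map — possible only for an ideal
razor-sharp noise-free contour thinner than the smallest kernel — the
unrefined map is used. A scene whose largest candidate component
covers less than 1 % of the image raises `NoLeafError`. In soil/weed
mode the leaf mask additionally gets the plain 3×3 opening that also
defines area accounting (below).

**Frost/no-frost split.** Frost is bright and desaturated. Candidate
pixels must satisfy the whiteness priors V ≥ 150 and S ≤ 100 (the
characteristic frost intervals on the 8-bit HSV scale; the same
values seed the HSV-box baseline). When the leaf contains a genuine
mixture (candidate fraction between 2 % and 98 %), isodata thresholds
on the within-leaf V and S distributions sharpen the cut:
T_v = max(isodata(V), 150), T_s = min(isodata(S), 100). Pure
adaptive thresholds without the priors would bisect the unimodal
distribution of a frost-free leaf and hallucinate frost on half of
it; the priors alone handle the degenerate all-frost and no-frost
leaves where isodata has nothing to separate.

**Area accounting.** In blurred mode A_leaf = count(leaf) +
count(frost). In soil/weed mode the label support is first cleaned by
a plain 3×3 binary opening (erosion then dilation) and both A_leaf
and A_frost are counted inside the cleaned mask — counting frost
outside the cleaned support could push FCR above 100 %.

## Baselines

ExG (excess green 2g−r−b on chromaticity-normalized channels,
binarized by Otsu on the index map), Otsu on the V channel
(exhaustive between-class-variance search, lowest-threshold
tie-break), K-means on RGB triples (k-means++ init, brightness-ranked
clusters), fixed HSV boxes (frost S ∈ [0, 100] ∧ V ∈ [150, 255],
leaf H ∈ [50, 120], first-match precedence frost → leaf →
background), and plain isodata. For benchmark comparison each
baseline is lifted to a three-class prediction by a documented
adapter (`reports.predict_labels`); the adapters inherit each
method's characteristic failure (ExG cannot see frost as vegetation,
global thresholds confuse bright soil with frost), which is what the
comparison is designed to show.

## Synthetic scenes

The generator emulates the three field conditions with exact ground
truth. One superellipse leaf (semi-axes 0.22–0.38 of the image side,
random orientation) carries green tissue (H ≈ 68–92, S ≈ 160–195,
V ≈ 115–160 with gentle shading), a midrib plus 4–7 darker secondary
veins, and frost grown as dendritic patches: nuclei scattered in the
leaf interior accrete stochastically along their 8-connected frontier
until the requested pixel count is hit exactly, so the stored FCR is
exact integer arithmetic. Frost colour is desaturated and bright
(S ≈ 15–70, V ≈ 185–240); on the same scale the backgrounds are a
heavily blurred greenish-grey gradient (blurred), brown mid-frequency
texture (soil), or a darker soil base with 8–13 green elliptical
blobs whose hue lies inside the leaf's band, at least one touching
the leaf border (weeds). Gaussian sensor noise (σ = 3 grey levels) is
added after compositing and can be disabled for exact-case tests.
Scene size defaults to 256×256 — large enough for the 7×7 kernel
schedule, small enough for fast test runs. All randomness flows from
one integer seed; repeated calls are byte-identical.

Benchmark grids draw per-level coverage targets uniformly within each
stratum, 0.5 pp inside the boundaries ([0.5, 29.5], [30.5, 59.5],
[60.5, 99.5]), so pixel rounding can never flip a scene across a
level boundary and the per-cell level histogram is exact.

What the generator does *not* model: specular highlights, shadows,
uneven illumination, motion blur, multi-leaf occlusion, or the
partial-transparency of thin early frost. Passing tests therefore
demonstrate correctness of the algorithmic chain and its behaviour
under controlled clutter, not field-robustness to illumination
effects.

## Evaluation metrics

R_ms is the mean over images of |p_s − p_a|/p_a (class pixel counts,
prediction vs truth) in percent — blind to location, so it can be 0
while pixels sit in the wrong place. Dice is the mean spatial overlap
2|P∩T|/(|P|+|T|); a pair with both masks empty scores 1.0 (perfect
agreement on absence). Reporting both separates "how much" from
"where" errors. Average precision R_a = 100·(1 − mean relative
error) compares estimated against reference coverages per severity
level. Benchmark totals are unweighted means across the three
backgrounds.

## Numerical choices and degenerate inputs

- Entropy uses log base 2 (bits); any base yields the same weights
  after normalization. 0·log 0 = 0. A fully constant image gets
  uniform weights (1/3, 1/3, 1/3).
- Isodata starts at the midpoint of the value range and stops when
  the update falls below 0.5 grey level; constant inputs raise.
- Otsu ties break toward the lowest threshold; the foreground is
  strictly above the threshold.
- All convolutions replicate-pad; binary erosion of a full mask is
  the identity.
- Connectivity is 8-connected throughout, matching dendritic frost
  morphology.
- K-means uses at most 100 Lloyd iterations with tolerance 1e-4 and
  rejects k larger than the number of distinct colours.
- The RGB↔HSV round trip is exact only to ±4 per channel: hue
  quantized to 8 bits moves reconstructed RGB by up to 3 levels at
  full saturation, plus rounding.

## Known limitations

- Single-leaf scenes only; the leaf is assumed to be the largest
  coherent structure.
- Hue is treated as a plain scalar; red-adjacent hues gradient
  artefacts (see above).
- The whiteness priors assume 8-bit exposure discipline; heavily
  over-exposed green tissue could cross V ≥ 150, though it would
  still need S ≤ 100 to be called frost.
- Soil backgrounds remain the hardest condition: texture noise sits
  in the same S/V gradient band as the leaf contour, and residual
  coverage errors concentrate there.
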