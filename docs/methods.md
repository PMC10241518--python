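# Methods

`gainscope` simulates a cued object-detection experiment with a convolutional
neural-network observer and asks which consequences of a multiplicative
attention gain actually carry its behavioral benefit.  This note documents
the models, the choices behind their parameters, and what the synthetic
setting does and does not show.

## The observer model

The observer is a four-block feedforward CNN patterned on CORnet-Z, whose
blocks map onto primate V1/V2/V4/IT.  Each block is a convolution (7×7
stride 2 in the first block, 3×3 stride 1 afterwards), a ReLU, and a 2×2
stride-2 max pool, giving block outputs of 56×56, 28×28, 14×14 and 7×7 for a
224×224×3 input.  The encoding of an image is the spatial average of the
last block's 7×7 feature map; per-category task readouts are logistic
regressions (L2, C = 1.0, liblinear) on that encoding.

The network, including all gradients, is implemented directly in NumPy.
Backpropagation is needed in two roles — training the observer and
computing input-gradient receptive-field maps — and the same hand-written
backward passes serve both.  Max-pool ties route gradient to every tied
element; ties occur essentially only among ReLU zeros, where the upstream
ReLU mask removes the gradient again, so the convention has no measurable
effect.

**Scale.**  The default configuration keeps the *full CORnet-Z spatial
geometry* — 224-px composites, 112-px base images, σ = 56 px gain width, a
7×7 final map — and shrinks only the channel widths (16/32/64/128 instead of
64/128/256/512) and the dataset sizes.  This is deliberate: the
necessity/sufficiency analysis divides the final feature map by a
per-position gain map, and whether that works depends on the final map's
spatial resolution relative to unit receptive fields.  The architecture's
theoretical receptive-field support at the last block is ≈85 px regardless
of input side, so shrinking the image side to 64 px makes every final-layer
unit effectively global; we verified that at that scale a per-position (or
even per-channel) output rescaling can recover only a minority of the gain
benefit, while at the full 224-px geometry the necessity/sufficiency
behavior reproduces.  Narrow channels cut compute ~30-fold; a full experiment runs in
roughly ten CPU-minutes.

**Training.**  The observer is trained from scratch (Adam, lr 1e-3, 12
epochs, softmax cross-entropy) to classify single full-size base images into
the 8 synthetic categories; readouts are then trained on a held-out image
split and evaluated on a third split.  Chance classification is 1/8; the
desk observer typically reaches 40–70% held-out accuracy — far above chance
but intentionally imperfect, since the study needs a mid-range operating
regime.

## Synthetic stimuli

No external images are used.  A category is a parametric texture family: an
oriented grating (orientation spread evenly over 180°, spatial frequency 3–9
cycles/image) windowed by a shape mask (disk, square, annulus or cross),
tinted by a muted category color, plus independent Gaussian pixel noise.
Within-category variability comes from random phase, orientation jitter
(±4° sd), position jitter and the noise.

The default contrast (0.65), noise sd (0.6) and color saturation (tints
blended 45% toward neutral) were chosen once so that a trained observer
operates in a mid-range regime — single-image readout validation AUC around
0.9–1.0 and composite distributed AUC around 0.7–0.8, well off ceiling,
comparable to human cued-detection performance — and are not adjusted per
experiment.

Detection composites tile four base images from four distinct categories
into a 2×2 grid; the human protocol builds exactly 80 grids per category (40
with a target, 10 per corner), the model protocol places all targets in the
NW corner (the network is translation invariant) with configurable counts.
Discrimination composites use only the two pair categories, target at NW,
the other three quadrants A or B with probability ½ — so A-target
composites contain on average 2.5/4 A-images and distributed performance
exceeds chance by construction.  Masks are seed-deterministic permutations
of the composite's pixel locations (luminance-matched by construction).
At desk sizes, model-protocol target images are sampled with replacement
when a split has fewer images than requested composites; the full protocol's
uniqueness constraint is kept for discrimination targets.

What the generator does *not* emulate: natural-image statistics, clutter,
within-category semantic variability, or any luminance/contrast confound
between categories.  Passing tests therefore show that the *mechanisms*
behave as claimed on category-discriminable inputs, not that effect sizes
transfer to natural images.

## Attention models

* **Gaussian gain** multiplies input pixels by
  g(r,c) = (β−1)·exp(−((r−r0)² + (c−c0)²)/(2σ²)) + 1, centered on the cued
  quadrant's center ((B/2−0.5, B/2−0.5) in 0-based pixel coordinates — the
  exact pixel is an implementation choice), σ = 56 px, β ∈ {1.1, 2, 4, 11}.
  Analyses that depend on a single strength use the evaluated β whose
  detection benefit is closest to the human-scale cueing benefit of
  ≈ +0.09 median AUC — gain strength calibrated against behavior, the way
  attention strength is normally anchored in observer models.  For the
  narrow-channel observer this matching typically selects β = 2 (it is
  somewhat more gain-sensitive than the full-width network).  An explicit
  ``reference_beta`` overrides the matching.
* **Flat quadrant gain** replaces the Gaussian by its spatial mean over the
  cued quadrant, combined with a quadrant-isolated forward pass: each image
  quadrant runs through the network alone (zero padding) and the
  per-quadrant feature maps are stitched.  A 112-px quadrant yields 3×3
  final maps, so the stitched map is 6×6 rather than 7×7; the tested
  property is the isolation contract (no unit depends on pixels outside its
  quadrant), not the stitched geometry.
* **Normalized exponentiation** raises activations to an exponent ξ and
  rescales the map to conserve its L1 mass, amplifying relative differences.
  It is applied to block outputs (post-ReLU, post-pool); an all-zero map is
  returned unchanged as the limit convention.  The amplification measurement
  classifies first-block units as inside/outside the gain field analytically
  (support center ± 2 FWHM of the geometric support vs the field's 2σ disc)
  and uses a bias-free copy of the observer so the gain bookkeeping is exact.

## Receptive-field analysis

Sensitivity maps are |d activation / d pixel| summed over RGB and averaged
over a batch of task composites (default 12; moments are insensitive to
sum-vs-average).  A map is treated as an unnormalized density; its mean and
central second moments give the RF center and covariance, and
FWHM = 2√(2 ln 2)·σ per axis, scalarized as the mean of the two per-axis
FWHMs.  Maps with mass below 1e−8 (dead units) are flagged invalid and
excluded from population statistics.  Effective gain is std(activity with
attention)/std(without) across stimuli, undefined (NaN) at zero baseline
variance.  Unit samples are drawn with density ∝ exp(−d/λ), λ = image
side/4, concentrating analysis near the attended locus.

## Counterfactual rewiring

All three variants copy the trained observer and modify wiring only.

* **Shift-only**: block-1 activations are bilinearly resampled along a shift
  map built from last-block RF displacements measured under Gaussian gain —
  for each pixel, the inverse-distance-weighted (1/(d+1)) average of the
  k = 20 nearest sampled units' shifts, blurred with σ = 8 px.  No gain map
  is applied anywhere.  One caveat: bilinear interpolation smooths the
  resampled activations, and because the narrow-channel observer's feature
  maps are spatially high-frequency on these noisy textures, the std-based
  effective gain of sampled units averages ≈0.85 rather than 1.  This is an
  interpolation artifact, uniform over stimuli, and leaves detection AUC at
  baseline (the tested null).
* **Structure**: every kernel tap is multiplied by the gain at its input's
  image-space position and the kernel rescaled so its L2 norm is unchanged
  (per output position — a locally connected layer).  The norm is computed
  over taps that read real input only: letting zero-padding taps participate
  would trade L2 mass between padded and interior taps and leak a large net
  gain at border units, defeating the manipulation's purpose.  A gain that
  is constant across a kernel's support cancels exactly.
* **Shrinkage**: the last block's 3×3 taps are moved to
  x′ = f(d)·x + (1−f(d))·mean(x) with
  f_β(d) = 1 − β·exp(−2.44 d²/112²)·cos(2.89 d²/112²), β ∈ [0.1, 0.4], d the
  unit's image-space distance to the locus, and re-expressed on the grid by
  bilinear splitting (weights sum to 1, conserving kernel mass).  The sign
  convention is chosen so f = 1 means identity; f(0) = 1−β contracts the
  kernel near the locus.

## Propagated gain

The propagated gain map is the per-position effective gain of the final
feature map (std ratio across stimuli, averaged over channels).  Channels
whose baseline std falls below 1e−3 of the median channel std are excluded:
their ratios are numerically meaningless and otherwise inject large outlier
entries.  Sufficiency multiplies a no-gain model's final maps by this map;
necessity divides a gained model's final maps by it.

## Readout variants

The masked readout zeroes final-map positions outside the top-left 4×4
(of 7×7) before average pooling and reuses the same trained prediction
layers — the rescaling this implies leaves a linear readout's ranking, and
hence AUC, unchanged.  An unpooled variant that retrains a classifier on the
flattened final map is available through the library API.

## Behavioral statistics

Sensitivity is d′ = Z(H) − Z(FA) with the log-linear (count+0.5)/(n+1)
correction applied only when a rate is exactly 0 or 1.  The duration curve
d′(t) = α·log(κt + 1) is fitted by Levenberg–Marquardt least squares with a
multi-start over κ ∈ [1e−3, 1e−1] /ms; by default the two cueing conditions
share κ and differ in α.  AUC and d′ interconvert by d′ = √2·Z(AUC).
EZ-diffusion uses the closed-form transform (scaling s = 0.1) from
(P_correct, mean RT, RT variance) to (drift, bound, non-decision time); the
forward moment equations are implemented alongside and the two are exact
inverses.  Bootstrap intervals are seeded percentile intervals with
n = 1000.

Two synthetic trial generators define the behavioral study conditions.  The
detection table draws choices from an unbiased observer with
d′(t) = α_cond·log(t/163.6 + 1), α_distributed ≈ 1.50 (consistent with a
d′ = 1 threshold at 155 ms) and a focal/distributed ratio of 1.67, at the
six protocol durations (8.3–266.7 ms), 400 trials per cell.  The EZ table
draws accuracy and RT moments directly from the EZ forward model with a
focal/distributed drift ratio of 1.61, bound ratio 1.57 and non-decision
times 0.26 s vs 0.38 s.  The two parameterizations cannot be satisfied by a
single table simultaneously, so each estimator is validated by recovery on
its own table.  RT marginals are moment-matched normals (negatives
rejected), not first-passage-time densities: adequate for validating a
moment-based transform, silent about RT shape.

## Numerical conventions and degenerate inputs

Activations are float32; analysis statistics are computed in float64.
Coordinates are 0-based (row, col); the NW quadrant is rows and cols
[0, B).  AUC counts ties as ½ (Mann–Whitney).  Readout training requires
both classes; AUC requires non-empty score sets; suppressive gain fields
(β < 1) are rejected; zero-norm kernels pass through rewiring unchanged;
divide-by-zero gain maps raise.  Every stochastic step takes an explicit
seed, and an experiment is a pure function of its config.

## Known limitations

* Channel widths are 4× narrower than CORnet-Z's and the observer is trained
  on 8 parametric categories, so absolute AUC values are not comparable to
  ImageNet-scale results from the full-width network; only directions,
  orderings and null-vs-effect contrasts are.
* The quadrant-isolated model's stitched 6×6 geometry differs from the plain
  7×7 map (the odd final side does not tile); comparisons against it rely on
  the pooled encoding being scale-consistent.
* RF population metrics use a few hundred gradient maps at 12-image batches;
  individual-unit estimates are noisy, and only population-level statements
  are tested.
* The d′-curve fit's κ is weakly identified from noisy 6-point data (a
  near-ridge with α); the α ratio is stable, duration thresholds less so.
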