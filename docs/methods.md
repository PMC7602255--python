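# Methods

This note records the model, the parameter choices that matter, the
numerical conventions, and what the synthetic-data experiments do and
do not establish.

## Pipeline and assumptions

The pipeline assumes a single pigmented melanocytic lesion that is
darker than the surrounding skin, photographed under roughly uniform
illumination. Images of any resolution are resampled (bilinear, aspect
ratio not preserved) to 256×256 RGB; all later stages work on that
grid. Preprocessing smooths each plane with a 5×5 Gaussian (σ = 1,
reflective borders) and histogram-equalizes the grayscale plane
(BT.601 luma weights 0.299/0.587/0.114, classic cumulative-histogram
mapping). Segmentation thresholds the *smoothed* RGB planes, not the
equalized gray: per-plane Otsu on an equalized color image is
ill-defined, while the equalized gray plane is what the texture
descriptor sees. No explicit hair removal is performed; smoothing and
the morphological cascade are the only artifact mitigation, which is a
known limitation on real dermoscopy with dense hair.

## Segmentation

Per-plane Otsu maximizes the between-class variance over all 256
candidate levels with ties broken toward the smallest level; the lesion
is the `≤ t` (darker) class. A plane with a single occupied level is
degenerate and contributes an empty mask. The three plane masks are
combined by majority vote (≥ 2 of 3), which tolerates one noisy plane;
AND/OR are available as configuration. Cleanup order: area opening
(minimum 100 px at 256×256 — a speckle pre-filter well below the later
5% cutoff), binary median cascade 7×7 → 5×5 → 3×3 (reflective borders),
morphological opening-then-closing with a disc whose radius is 1% of
the short image side (3 px at 256), repeated twice, then removal of
components below 5% of the image area. If nothing survives the 5%
filter, the largest pre-filter component is kept so the pipeline always
produces a feature vector; a fully degenerate image (e.g. constant
color) yields an empty mask and is flagged. Components are 8-connected
throughout; coordinates are 0-based (row, col). Contours are obtained
by Moore border following with Jacob's stopping criterion, giving one
closed, clockwise, 8-connected pixel chain per component — on a binary
raster this is exactly the border an edge detector would return, with
an explicit pixel ordering.

## Gabor-entropic descriptor

The 40 kernels follow the complex Gabor-wavelet family with envelope
parameter σ = 2π and 31×31 spatial support, the dominant convention for
this 5-scale/8-orientation bank. The analytic DC-compensation term
exp(−σ²/2) ≈ 2.7·10⁻⁹ is retained, but truncating the sampled grid to
31×31 reintroduces a residual mean (severe at the coarsest scale, where
the envelope's std is 16 px); the residual mean of each sampled kernel
is therefore subtracted, making every kernel exactly DC-free. This is
what guarantees that a constant ROI produces (numerically) zero
response, and with it the descriptor's invariance to a global
illumination rescaling.

Responses are computed by FFT convolution of the ROI bounding-box crop,
padded by half-sample symmetric reflection; statistics are restricted
to lesion pixels. Each magnitude map is divided by its maximum over the
ROI, histogrammed into 64 equal-width bins over [0,1], and reduced to
(Rényi, Tsallis, Fisher) with entropic order α = 2 and log base 2
(bits). Choices: 64 bins balance histogram resolution against the
~10³–10⁴ ROI pixels available; α = 2 (the "collision" order) is the
standard nonextensive default; both are configurable. Fisher terms with
p_i = 0 are skipped — no epsilon, keeping the measure finite and
scale-free. A magnitude map whose raw maximum is below 10⁻⁹ × the ROI
intensity scale carries only float noise; normalizing it would amplify
rounding error into a fake histogram, so such maps contribute the
degenerate triple (0, 0, 0). Feature order is filter-major:
j = μ + 8v, components (3j, 3j+1, 3j+2) = (Rényi, Tsallis, Fisher).
Min–max normalization to [0,1] is fitted on training vectors only;
unseen values are clipped and constant components map to 0.

The descriptor is exactly invariant to positive intensity scaling
(tested to 10⁻⁹). Rotation by 90° permutes the orientation index by 2,
so per-filter entropies agree as a multiset up to resampling error;
no rotation-invariant re-indexing is applied. General scale/rotation
invariance is *not* claimed or enforced.

## Multilevel network and training

The multilevel activation is implemented as the shifted sum
φ_r(x) = Σ_{λ=1}^{r−1} f(x − (λ−1)c): a staircase with r plateaus at
≈ 0, 1, …, r−1 spaced c apart, which reduces identically to the
logistic f at r = 2. (The per-branch form f(x) + (λ−1)f(c) with a free
λ does not define a single-valued function; the shifted sum is the
reading consistent with plateaus at 0..r−1 and with the r = 2 limit.)
Defaults: hidden layers 10+10 neurons with r = 3, β = 1, c = 10; output
neuron r = 2 so the score is a probability-like value in (0,1) that can
be thresholded at 0.5 — a multilevel output would be incompatible with
0/1 targets. Full-multilevel mode is available in configuration.

Training is damped Gauss–Newton on the per-sample residuals: the
Jacobian ∂output/∂w is backpropagated analytically (verified against
central finite differences to 10⁻⁵ on the full 120-10-10-1
architecture), and (JᵀJ + μI)Δw = Jᵀe is solved by Cholesky
factorization with an lstsq fallback. μ starts at 10⁻³, shrinks ×0.1 on
acceptance and grows ×10 on rejection; a step is accepted only if the
full-batch MSE decreases, so the accepted-step MSE sequence is
non-increasing, and 25 consecutive rejections end training. Weights
initialize uniformly on (−0.5, 0.5) from a seeded generator; training
is bit-deterministic given the seed. The damped normal equations are
solved directly rather than by iterative conjugate gradients — for
~1,300 weights the direct solve is exact and fast. Cross-validation
uses MSE threshold 10⁻³ and at most 100 epochs per fold; separable
feature sets converge in well under that.

The multilevel-vs-plain-sigmoid comparison harness uses a fixed
synthetic three-level task (three 2-D Gaussian clusters with targets
0, 1, 2): a grading-style problem where the staircase output can
represent all three targets while a plain sigmoid, bounded in (0,1),
cannot — so the multilevel network's final training MSE is expected to
be at or below the plain network's in almost every matched-seed run.
This realizes the qualitative "multilevel learns better" claim as a
reproducible measurement; it does not show an advantage on tasks whose
targets a plain sigmoid can already represent.

## Evaluation conventions

All indices are percentages of the pooled cross-validation confusion
counts. Printed values are 2-decimal, with specificity *truncated*
(96.875 → 96.87) and PPV/NPV rounded to one decimal (88.888… → 88.9),
matching the worked reference arithmetic. AUC uses the rank/midrank
method; the pooled-score AUC is the headline and the per-fold mean is
also reported. Stratified k-fold assignment is a seeded within-class
shuffle followed by round-robin, so per-fold class counts differ by at
most one; with 200 samples and k = 5 every fold is an exact 160/40
split. The normalizer and the network are fitted per fold on the
training portion only. A percentile-bootstrap CI helper (2,000
resamples, seeded) is provided for per-sample metrics; it is a
convenience, not a validated inferential procedure.

## Synthetic cohort: what it emulates and what it does not

The generator draws a perturbed-ellipse lesion (low-order harmonic
boundary modulation; benign amplitude 0.08, malignant 0.35 of the
radius) occupying 10–35% of a 256×256 frame, dark (mean 80) on lighter
skin (mean 190) with Gaussian pixel noise (sd 12), smooth background
shading, and 3-octave band-limited intra-lesion texture with
class-dependent amplitude (benign 5, malignant 20 intensity units —
chosen so the classes are separable by texture statistics but overlap
under noise); malignant lesions additionally get two-region pigment
variegation (±25). Colors are a fixed skin-tone tint of the gray
field. Everything is deterministic given the seed, per-sample streams
included.

This emulates the cues the pipeline is built to exploit — dark-lesion
polarity, border irregularity, texture contrast — and nothing else: no
hair, bubbles, rulers, color constancy shifts, multi-lesion frames, or
realistic pigment network morphology. Passing the synthetic
experiments therefore shows the machinery is correct and sensitive to
the intended cues; it does not certify real-dermoscopy accuracy. A
PH2-style directory adapter is included so the identical pipeline can
be pointed at real data without code changes.

Problem sizes used by the test suite and the acceptance script — an
80-image cohort (20% malignant), Dice measured on 20 samples, 5-fold
CV, a 10-run learning-curve comparison — keep a full from-scratch
reproduction under a minute on one CPU while leaving every measured
quantity stable across seeds. One caveat on the label-shuffled control:
with a 20% minority class, a null classifier drifts toward the 80%
majority-call rate, so shuffled-label accuracy lands between chance
(50%) and 80% rather than at 50% exactly; observed values are ~60–68%.

## Known limitations

- No hair/bubble artifact handling; heavy artifacts will corrupt both
  the mask and the descriptor.
- The 5% size filter assumes one dominant lesion; multiple comparable
  lesions are all kept and pooled into one descriptor.
- LM training is full-batch and direct-solve: fine to a few thousand
  weights, unsuitable far beyond that.
- The descriptor's rotation behaviour is permutation-equivariant in
  the orientation index, not rotation-invariant.
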