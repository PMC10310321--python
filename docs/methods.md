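# Methods

This note documents the models, estimators and simulation conditions the
package implements, the numerical choices behind them, and what the synthetic
data can and cannot establish about real experiments.

## Synthetic morph stimuli

Each morph sequence interpolates between a sequence-specific "cat" prototype
and "dog" prototype shape.  Shapes are star-polygon blobs with radius
`r(θ) = R·(1 + Σₖ aₖ cos(kθ + φₖ))` over harmonics k ∈ {2,3,4,5} (low) and
{9,11,13} (high).  The two categories share the low-frequency amplitude
distribution (Normal(0.08, 0.02) per sequence) and differ **only** in the
high-frequency amplitudes: ≈0.005 for the cat prototype versus
Normal(0.22, 0.015) for the dog prototype.  Morph level p blends the two
amplitude vectors with weight p/100.  The base radius is rescaled by
`1/sqrt(1 + Σa²/2)` so the enclosed area — hence mean luminance — is
independent of spikiness; base radius is Uniform(0.43, 0.47) per sequence,
phases, rotation and fill color are per-sequence draws.  Category is therefore
a phase-invariant property of local contour spatial frequency, not a template:
no linear function of pixels can express it across sequences, while rectified,
spatially pooled filter responses can.

`colinearity ∈ [0,1]` sets how much of the background texture (variance
share) and position jitter is common to all levels within a sequence.  At the
default 0.9, images within a sequence are strongly linearly related in pixel
space (measured mean within-sequence pixel correlation ≈ 0.9 versus ≈ 0.4
between sequences), which is what lets a pixel readout interpolate between
adjacent morph levels under random splits and why the sequence-holdout regime
is the informative control.

Morph levels are integers on [0,100]; label 1 ("dog") iff level > 50, label 0
iff < 50.  An exactly-50 image gets an explicit label assigned at generation,
alternating across sequences, because a reward rule at the midpoint is
otherwise undefined.

## Simulated observers

`P(dog | image) = lapse/2 + (1 − lapse)·logistic(slope·(level − bias) + δᵢ)`
with a per-image offset δᵢ ~ Normal(0, image_effect_sd) drawn once per
observer per image, and independent Bernoulli repetitions.  Defaults
(slope 0.15 logit/%, bias 50, lapse 0.02, image_effect_sd 1.0, 10 repetitions
per image) give steep, nearly symmetric psychometric curves with reliable
image-level idiosyncrasies — the regime in which image-level split-half
reliability is high while remaining below 1.  Offsets are resampled per
observer, so between-subject image-level agreement can arise only through the
shared stimulus (the morph level); this is what makes the within- versus
between-subject comparison meaningful.

## Encoders

The fixture encoder is a seeded random-weight CNN (He-initialized, ReLU):
conv1(5×5/2,8) → pool1 → conv2(3×3,16) → pool2 → conv3(3×3,32) → pool3 →
conv4(3×3,32) → pool4 → conv5(3×3,64) → fc6 (256 fully connected units on the
2×2 adaptive-average-pooled conv5).  Ten named layers; "first half" = the
floor(L/2) earliest.  Untrained filters suffice here because the synthetic
category signal is local spatial-frequency energy, which rectified random
filters transmit; the coarse pooling before fc6 trades spatial detail for the
translation tolerance that cross-sequence generalization requires.  Input is
bilinear-resized to 224×224 and channel-normalized by the standard means
(0.485, 0.456, 0.406) and SDs (0.229, 0.224, 0.225).  The pixel baseline
flattens raw images row-major.

## Category readout

L2-penalized logistic regression; the inverse regularization strength C is
chosen from nine log-spaced values 1e−5…1e5 by stratified fivefold CV on the
training data only, then the readout is refit at the chosen C.  Ties in inner
CV accuracy resolve to the **largest** tied C — the least-regularized of the
equally scoring values — so separable data is fit sharply rather than left at
the 0.5 probability tie.  Predicted label is 1 iff predicted probability
≥ 0.5 (ties to 1).  Random splits are stratified by morph level (falling back
to unstratified, logged, when a level is too small); extra splits are drawn,
and recorded, until every image has been held out at least once.  Feature
matrices are z-scored per dimension across the stimulus set before fitting —
a label-free preprocessing step, analogous to the fixed image normalization,
without which the heterogeneous per-dimension scales of conv-layer features
dominate the L2 penalty.

Because L2-penalized linear fits depend on training rows only through inner
products, any n×d feature matrix with d > n is losslessly replaced by the
n-column factor of its Gram matrix before fitting; predictions are unchanged
to numerical precision and the fits become O(n²).

## Neural predictivity

Per electrode and layer: outer 5-fold CV; within each training fold a ridge
map with penalty selected by efficient leave-one-out generalized CV
(`RidgeCV`); held-out predictions concatenated across folds and correlated
(Pearson) with held-out mean responses.  Correlation on concatenated
predictions rather than per-fold averages avoids degenerate small-fold
correlations; its known cost is a *pessimistic* null — fold means
anti-correlate with held-out folds, so pure-noise electrodes average r ≈ −0.08
at n = 300 rather than 0.  Tests assert the meaningful direction (no spurious
positive predictivity) instead of exact zero.

Reliability: mean over random repetition-half splits of the correlation
between half-mean vectors, Spearman–Brown corrected (2r/(1+r)); for an
electrode with unit signal variance and noise SD σ over R repetitions this
converges to `1/(1 + σ²/R)` after correction, which the tests verify.  Noise
correction divides raw r by √reliability; electrodes under the reliability
floor (default 0.1) are excluded rather than corrected, and corrected values
above 1 are flagged, never clipped.  The early-vs-late contrast is an
unpaired t over per-layer median corrected fits (df = L − 2); peak selection
is argmax of the median with ties to the earlier layer.

**Electrode simulation is low-rank by design.**  An electrode's signal is a
random combination of the generating layer's top 10 principal directions
(standardized to unit variance, so `noise_sd` is in signal-SD units).  This
mirrors the low-rank shared covariance of real population recordings, and it
is also the regime in which the generating layer is identifiable: with dense
i.i.d. (or sparse single-unit) mixing weights, every sufficiently wide layer
of a CNN fits the signal equally well on desk-scale image sets and layer
recovery is impossible in principle.  Identifiability additionally requires
stimuli rich enough to decorrelate the layers' dominant subspaces: layer
recovery is exercised on a 24-object × 8-view pool of rotated shapes on noise
backgrounds, not on the morph stimuli, whose stimulus manifold (sequence ×
level × jitter) is too low-dimensional to distinguish layers.  Under these
conditions (reliability ≈ 0.7 via noise_sd = 2.07 at 10 repetitions, 24
electrodes), electrodes generated from the IT-like layer conv5 are assigned
peak layer conv5 in 20/20 seeded runs with median corrected fits within
[0.91, 0.94]; electrodes generated from an early layer (pool1) at lower
reliability yield a significant early-over-late half contrast.

## Pseudo-oddity protocol

A trial is three images, two views of object *i* and one of object *j* (the
oddity), position randomized.  For a held-out sample trial, `n_pseudo`
(default 100) pseudo-experiments are synthesized; each draws `n_trials`
(default 52) training trials from the two objects' remaining views, excluding
the sample's three images.  Every pseudo trial mirrors the sample's role
structure — object *i* typical, object *j* oddity.  This is deliberate: if
the roles are balanced across training trials, the target "which slot
differs" becomes a relational (XOR-like) function that **no linear classifier
over slot-concatenated features can learn** — performance stays at 1/3 at any
object separation.  With fixed roles the multinomial L2 logistic classifier
(fixed C = 1, three slot-blocks of features, target = oddity slot) learns a
position-equivariant contrast between the two objects.  Outcomes are
binarized (predicted slot = true slot) and averaged over pseudo-experiments;
object-level performance averages each object's trials over all partner
oddities.  Structure-free features (object separation 0 in the synthetic
feature fixture) give object-level performance at the 1/3 chance level;
performance rises monotonically with separation.

## Consistency estimators

For items = images or morph levels, each iteration splits every item's trials
into two random halves (an odd trial count sends the extra trial to a random
half), forms the two half-mean vectors, and records their squared Pearson
correlation; 100 iterations give a distribution of fits, summarized by the
median.  The between-subject variant replays the same split template on both
subjects and compares subject i's first half with subject j's second half —
so both measures are equally powered, and a subject compared with an exact
copy of itself reproduces the within-subject distribution exactly.
Image-level analyses refuse items with fewer repetitions than a configurable
floor (default 8), mirroring the exclusion of under-repeated experiments;
simulation studies lower the floor explicitly.

Model-to-behavior fits are OLS of behavior on model per-item values with an
intercept (slope β, R², slope t with df n−2, or F(1, n−2)); group curves are
compared the same way on aligned (experiment, level) points.  The empirical
percentile of a model fit within a between-subject reference distribution is
the fraction of reference values ≤ the fit (median percentile when the model
contributes many iterations).  Calibration holds by exchangeability: when the
model's per-item values are produced by the same random-half process as a
reference subject, the model value and the reference values are conditionally
i.i.d. given the data, so the percentile is discrete-uniform — verified by KS
test over 200 simulations.

## Split-half oracle

The split-half estimator is validated against an independent brute-force
implementation: 10,000 re-splits of the *same* trial table, computed directly
with numpy array operations on the raw responses.  For a flat (slope-0,
no-image-effect) observer both medians sit near the small positive value
implied by correlating 40-item binomial noise vectors; note this conditional
median (re-splitting one dataset) is the estimator's own distribution, which
is the quantity the oracle must reproduce.

## Problem sizes and determinism

Default study conditions: 7 sequences × 11 levels (77 images) at 64 px,
colinearity 0.9; 100 readout iterations; 10 behavioral repetitions; 100
consistency iterations; oddity fixtures with 6 objects × 12 views (protocol
checks run at n_pseudo = 20 with smaller object counts on the separation
ladder); encoding-model checks on a 24-object pool with 24 electrodes and 20
seeded runs.  Every stochastic operation takes one integer seed expanded
through a counter-based scheme (`SeedSequence` keyed by stage/entity labels),
so adding electrodes, subjects or sequences never perturbs earlier draws, and
the full pipeline writes byte-identical summaries on re-run.  The pipeline's
master seed fans out to stages via a SHA-256 hash of (seed, stage name).

## What the synthetic data does not show

The generators emulate the *structure* of a morph-discrimination study —
colinear discrete morphs, reliable image-level choice variance, low-rank
electrode signals — not its content.  Passing tests demonstrate that the
estimators and protocols are implemented correctly and behave as designed
under known ground truth; they do not license quantitative claims about real
cortical data, real morphed photographs (which carry texture and semantic
cues absent here), or pretrained networks.  The spatial-frequency category
cue is one deliberately simple stand-in for "category-relevant information";
real stimuli mix many cues with unknown linear accessibility.  Encoding-model
layer recovery, in particular, is contingent on the low-rank electrode model
and rich stimuli, and the morph-stimulus demonstration that recovery *fails*
on an impoverished stimulus manifold should be read as a caution for
experimental design, not a defect of the fits.
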