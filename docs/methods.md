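# Methods

## The analysis in one paragraph

`lfbmil` re-creates, on synthetic data with known ground truth, a weakly
supervised analysis of Luxol-fast-blue–stained brain histology: slides are
tiled, each tile becomes a feature vector, an attention-based
multiple-instance classifier predicts from the bag of tiles whether the
donor had antemortem cognitive impairment, the learned attention is used to
localize the evidence (white matter vs grey matter), dark-blue positive
pixels quantify myelin staining in the highest-attention tiles, and
association statistics connect the model's probability estimates and stain
metrics to pathoclinical covariates. Because the corresponding human cohort
is not openly deposited, every step is exercised against a synthetic slide
generator that plants a myelin-pallor effect of known size, so the tests
check *recovery of planted structure and calibration under the null* rather
than reproduction of cohort-specific numbers.

## Synthetic cohort and slides

`generate_cohort` draws donors with age ~ Normal(`age_mean` = 85,
`age_sd` = 8 years); the true impairment state is Bernoulli with a logistic
dependence on age (slope `age_ci_slope` = 0.08 per year, anchored so a
mean-aged donor has probability `p_impaired` = 0.5). Braak stage, CERAD,
ARTAG and cerebrovascular disease are drawn with mild positive enrichment
in impaired donors. Cognitive measures (CDR, MMSE, clinical diagnosis) are
deterministic functions of the true state, then corrupted as a unit with
probability `label_noise` (default 0.1, so recorded measures contradict the
truth for ~10% of donors) and masked per measure with probability
`missingness` (default 0.2). Generated CDR values occasionally exceed 3
before capping, exercising the cap rule.

`generate_slide` renders a 1024×1024 px slide (config `slide_px`): an
elliptical tissue piece split by a wavy boundary into grey matter (pink
background, dense dark nucleus dots) and white matter (light-blue
background, sparse dots), with the white-matter share set by `wm_fraction`
= 0.45. Myelin is drawn as short anti-aliased dark-blue strokes; the target
dark-pixel density is `base_density` = 0.18 of white-matter area, reduced
by `effect_size` (default 0.3) in truly impaired donors over a `patchiness`
fraction of white-matter tiles (default 1.0 = uniform). The white-matter
background carries per-pixel multiplicative intensity texture (sd 0.25,
truncated at [−0.85, +2.5] sd so unstroked background never enters the
dark intensity band). The spread is wide enough that the light-blue band
holds the background's lower intensity tail, which makes the light count's
response to a global gain match the dark count's in sign and approximate
elasticity around gain 1 — the property that lets the dark/light ratio
cancel per-slide gain. The cancellation is local: under gain spreads
several times the default, fixed intensity gates produce
threshold-crossing effects that no count ratio can undo. Finally the whole image is
multiplied by a per-slide gain ~ Normal(1, `stain_gain_sd` = 0.05),
emulating systemic staining variation across slides. Ground truth
`true_tile_density` is the dark-band pixel fraction of each 256 px tile
measured on the rendered image *before* the gain, so stain-quantification
recovery can be tested against it.

What the generator does **not** emulate: real histologic texture, specific
lesions, scanner optics, or several correlated sources of technical
variation. Passing tests therefore demonstrate that the pipeline recovers a
planted staining reduction under per-slide intensity confounding and label
noise — not that it would detect myelin loss in any particular real cohort.

## Labelling

A donor is cognitively impaired (CI) on the evidence of CDR ≥ 0.5, a
clinical diagnosis of impairment, or MMSE ≤ 24; CDR above 3 is capped at 3.
The default `any_evidence` policy calls a donor CI if *any* available
measure is positive, NCI if at least one measure is available and all are
negative, and excluded when no measure is available. A `hierarchical`
policy (first available measure in the order CDR → diagnosis → MMSE decides
alone) is retained as an option because the source description admits both
readings; the two differ only for donors whose first available measure
disagrees with a later one.

## Tiling and features

Tissue is segmented by thresholding median-smoothed HSV saturation
(threshold 0.05, disk radius 2); all disconnected pieces are kept. The tile
grid is anchored at the image origin, partial edge tiles are dropped, and a
tile is kept when at least `min_tissue` = 0.5 of it is tissue. The default
feature extractor is deliberately hand-crafted and deterministic: a 24-bin
hue histogram gated at saturation ≥ 0.15, per-channel mean and s.d., a
16-bin intensity histogram, and gradient-magnitude statistics, zero-padded
to D = 1024. Any callable mapping a tile to a fixed-length vector (e.g. a
pretrained CNN trunk) can be plugged in through the same interface; the MIL
contract only requires informative fixed-length vectors.

## Attention-MIL model and training

Gated attention pooling over a shared ReLU embedding (D → 64), attention
width 48, linear 2-class bag classifier, and an auxiliary instance
classifier that receives binary pseudo-labels on the top-8 and bottom-8
attention tiles (instance-clustering weight 0.3). Training is Adam at the
learning rate 2e-4 with dropout 0.25 on the embedding, one bag per step,
early stopping on validation loss with patience 10 (validation AUC
optional), max 150 epochs.

The bag cross-entropy is weighted inverse to class frequency so the
implied prior stays at 0.5 under cohort imbalance, and after early
stopping the classifier bias is recentered so that the midpoint of the two
classes' mean training logits maps to probability 0.5 (an intercept-only
calibration; the shift is strictly monotone, so rankings and AUC are
unaffected, but the fixed 0.5 decision threshold used for balanced
accuracy and for the predicted-group comparison becomes meaningful).

Two further numerical choices matter at desk scale and are defaults in
`MILConfig`:

* **Feature standardization.** Per-dimension z-scoring fitted on the
  training bags and stored with the model. The handcrafted features are
  small-valued and mostly zero-padded; without standardization the
  attention logits stay near zero and attention never differentiates
  tissue.
* **Decoupled weight decay (4e-3 per step) on the embedding and attention
  parameters only.** Softmax attention over a dozen tiles is prone to
  winner-take-all collapse: one white-matter tile absorbs the attention
  mass and every *other* white-matter tile is pushed below the grey-matter
  tiles, inverting median-based region summaries. Moderate decay keeps the
  attention logits smooth so attention spreads over the evidence-bearing
  compartment; the region effect direction is stable across a fivefold
  range of the decay (0.002–0.01) with unchanged AUC. The classifier heads
  are exempt: decaying them compresses the output probabilities around the
  majority-class prior, which empties one side of the fixed 0.5 decision
  threshold.

Cross-validation is Monte Carlo: 10 independent label-stratified 80/10/10
splits keyed by donor, largest-remainder rounding within class. Fold AUCs
are compared to chance with a one-sample Wilcoxon signed-rank test using
the normal approximation with continuity correction (no tie correction;
fold AUCs are effectively continuous). The averaged ROC is vertical
averaging of per-fold curves linearly interpolated on a common
101-point FPR grid. The best fold maximizes the arithmetic mean of AUC and
balanced accuracy.

## Interpretation and stain quantification

Attention is z-transformed per slide (sample s.d.; constant attention maps
to zeros). Tiles are assigned to grey/white matter by the region label at
their center pixel; per-slide region medians of the z-scores are compared
across slides with a paired t-test, excluding (and counting) slides that
lack tiles in either region. The `top_k` = 100 highest-attention tiles per
slide (all tiles, with a warning, when a slide has fewer) feed positive
pixel counting.

RGB → HSI uses the classic arccos formulation (I = (R+G+B)/3,
S = 1 − 3·min/sum, H undefined at S = 0). The default bands are artifact
choices matched to the generator's palette, not published values: dark blue
= hue 240° ± 40°, S ≥ 0.15, I ∈ [0, 120); light blue = same hue and
saturation gates, I ∈ [120, 220). Tiles with zero dark pixels are dropped
as outliers (a config flag switches to dropping tiles empty in either
band); slides are summarized by median dark count and median dark/light
ratio over retained tiles. Because a multiplicative stain gain leaves hue
and saturation exactly unchanged, gain can move counts only through the
intensity gates; the ratio partially cancels this, and the simulation-based
test asserts the resulting variance-inflation ordering rather than exact
invariance. Group comparisons are Welch t-tests; the joint (dark count,
ratio) distribution is summarized by a Gaussian product-kernel 2-D density
with normal-reference bandwidths per axis.

## Association statistics

Rank correlations are Spearman with average ranks and the t-approximation
p-value, on pairwise-complete observations. Differential correlation
between groups uses the Fisher z difference
z = (atanh ρ_A − atanh ρ_B)/√(1/(n_A−3) + 1/(n_B−3)) with an empirical
two-sided p from permutations of group membership,
p = (1 + #{|z_perm| ≥ |z_obs|})/(P + 1); the smallest attainable p is
1/(P+1). The default P = 10,000; calibration tests use P = 199, which bounds
the p-value granularity at 1/200 — sufficient to estimate a rejection rate
near 0.05.

Conditional independence of X and Y given Z is tested by the asymptotic
G-test: continuous variables are discretized into quantile bins (default 3
levels), G = 2N·MI(X;Y|Z) in natural-log units with 0·log 0 = 0,
df = (|X|−1)(|Y|−1)|Z|, empty conditioning strata dropped from the df with
a warning. With an empty conditioning set this reduces exactly to the
marginal G-test. Both G and raw MI are reported. One known behaviour of
discretized conditional tests: conditioning on a *coarsely* binned
continuous mediator leaves residual within-stratum dependence and inflates
the conditional rejection rate (about 32% at 3 levels for a linear chain at
n = 500); structure-recovery analyses therefore use 5 quantile levels,
where the chain's conditional independence is retained while marginal
dependence remains fully detected. The pipeline's cohort-level tests keep
the 3-level default, where sample sizes per stratum are the binding
constraint.

## Problem sizes and determinism

The demo profile runs 120 donors with one 1024×1024 slide each (~12 kept
tiles per slide) through all ten folds; the matched null uses the same
profile with effect size 0 and permuted labels. Calibration checks use 200
replicates (differential correlation, marginal G-test) and 100 chain runs
at n = 500. Every random draw descends from the seeds in `RunConfig`;
identical configs give bit-identical cohorts, pixel-identical slides, and
identical headline numbers.

## Known limitations

* The handcrafted features are nearly sufficient statistics for the
  planted effect; real-cohort difficulty (heterogeneous pathology,
  staining batch structure, scanner variation) is far higher, and the demo
  AUC should not be read as an estimate of achievable real-data AUC.
* Attention localization is assessed only at tile granularity and with a
  dozen tiles per slide; median-based region statistics at this scale
  required the weight-decay choice described above.
* The HSI band defaults are generator-matched artifact values; applying
  the stain module to real imagery requires re-annotating the bands.
* The G-test's chi-square reference is asymptotic; with quantile-forced
  margins it runs conservative at small n.
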