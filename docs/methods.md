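# Methods

`flavorlink` implements a sensomics analysis chain for a designed food
study: a trained quantitative-descriptive panel scores a set of products on
a 0–100 line scale, the same products are profiled by untargeted LC-MS and
GC-MS, and cross-validated multivariate models are used to rank metabolite
features by how well they predict each sensory attribute and each
compositional factor. This note records the models, the defaults and why,
and what the synthetic generator does and does not emulate.

## Panel model and standardization

Assessors differ in how they use the scale: each has an additive offset and
a multiplicative gain. Scores are therefore z-scored one attribute at a
time within each assessor across products,

    y~_ijk = (y_ijk − ȳ_ik) / s_ik ,

with sample (n−1) SDs throughout, and mapped back to score units,

    y~*_ijk = ȳ_k + y~_ijk · sp_k .

Two pooled-SD forms are implemented. The default, `conventional`, is the
root-mean-variance pooled SD sp_k = sqrt(Σ_i s_ik² / I): it is the only form
for which the back-transformed data actually recover the original
per-attribute spread, which is the stated purpose of the back-transform.
The `literal` mode, sp_k = Σ_i s_ik / (I·(J−1)), reproduces a historically
printed variant of the formula; it is dimensionally a mean SD shrunk by
1/(J−1) and compresses the back-transformed spread accordingly. Both are
kept and distinguished by tests; analyses default to `conventional`.

Sessions are averaged per (assessor, product, attribute) before any
modeling: the standardization and the mixed model are indexed by assessor,
product, attribute only. Constant (assessor, attribute) slices carry no
ranking information and are dropped with a warning (configurable to a hard
error). Sensory responses ν_jk — the regression targets — are the
across-assessor means of the back-transformed scores.

## Product-effect F values

Per attribute, discriminability of the products by the panel is quantified
by the F statistic of the product fixed effect in a linear mixed model with
a random assessor intercept. The fit is exact profiled REML: with a single
random intercept, V = I + λZZ′ inverts group-wise in closed form, so the
REML criterion is a smooth scalar function of log λ, minimized by bounded
search (xatol 1e-10) with an explicit check of the λ→0 boundary. The F
value is the Wald statistic of the J−1 product contrasts divided by its
degrees of freedom; the denominator df is the residual count
n − I − J + 1, which equals (I−1)(J−1) on complete data, where the statistic
coincides with the classical two-way (product + assessor blocks) ANOVA F to
~1e-8. The critical value is the upper-α quantile of F(J−1, df_den),
α = 0.05 by default. This in-package fit exists because general-purpose
mixed-model optimizers converge too loosely (~1e-5 relative on F) for the
exact agreement the balanced case should show; statsmodels' MixedLM is used
as an independent cross-check in the test suite, never as the
implementation.

F can be computed on raw or standardized scores; on standardized input it
is invariant to per-assessor affine transforms of the raw data.

## Feature-table preprocessing

Fixed step order: blank filter → QC RSD filter → natural-log transform →
technical-replicate averaging → autoscaling. Filters precede the
transforms; log/average/autoscale follow the conventional order for
intensity data.

* Blank filter: a feature is dropped when mean(study) < ratio ×
  mean(blank); default ratio 5, a common untargeted-metabolomics
  convention. Features absent from blanks are always kept.
* QC RSD filter: features whose relative SD over the pooled-QC injections
  exceeds 0.30 (default) are dropped; fewer than 3 QCs makes this a warned
  no-op.
* Log transform: natural log; any monotone base is equivalent after
  autoscaling up to scale. Zeros are replaced per feature by half its
  minimum positive value before logging; all-zero features are dropped.
* Replicate averaging: arithmetic mean on the log scale, one row per
  product; QC/blank rows are dropped (or passed through on request).
* Autoscaling: per-feature center and unit variance (sample SD); constant
  features dropped.

Every step appends its parameters and removed feature ids to a processing
log; replaying the log on the raw table reproduces the processed matrix
bit-for-bit, which the tests assert. PCA is plain SVD on the (defensively
re-centered) matrix with a fixed sign convention: the largest-magnitude
loading of each component is positive.

Isotope/adduct deduplication is out of scope (performed upstream by the
peak picker in real workflows); correlated feature blocks are retained and
the simulator plants them deliberately.

## Estimators

PLS is NIPALS with standard deflation, centering only (the pipeline
autoscales upstream). Convergence is to 1e-13 on the weight vector, which
keeps predictions within 1e-8 of a machine-precision reference; scores are
orthogonal to 1e-8 by construction. Discriminant analysis uses one-hot
dummy responses with argmax decoding; exact ties go to the earliest
training label. Predictions at any truncated component count come from the
same fit, which the elimination ladder exploits. VIP uses the
Y-variance-weighted form, so Σ_f VIP_f² = p identically; multi-response
models sum explained-variance weights over responses.

The regression forest is bagging over scikit-learn decision trees with
mtry = ⌈p/3⌉ and unlimited depth (conventional regression-forest defaults;
300 trees by default in the selection engine, 500 in standalone use).
Bootstrap indices are drawn explicitly so each tree's out-of-bag rows are
known; importance is OOB mean decrease in accuracy — the average increase
in OOB MSE when one feature column is permuted within the OOB rows. This
is written in-package because no installed library exposes OOB permutation
importance for regression forests.

Metrics: BACC = Σ_i (TPR_i + TNR_i)/(2L) over L classes (0.5 is the random
baseline for balanced binary problems); Q² = 1 − PRESS/TSS on out-of-fold
predictions; RMSEP is the root-mean-squared out-of-fold error.

## Repeated double cross-validation selection

Per repetition, samples are split into n_outer stratified folds (by class,
or by response quantile for regression). Holding out each outer fold, an
n_inner-fold inner CV runs over a descending geometric feature ladder
(×0.9 per step, floor 2, i.e. elimination fraction 0.10): at each step the
engine is fitted per inner fold, features are ranked by the inner-fold-mean
importance (VIP at the error-minimizing component count in 1..5, or forest
MDA), the inner validation error is recorded (misclassification count for
classification — balanced accuracy is reporting-only — or RMSEP), and the
worst 10% of features are dropped. From the fold's validation curve, n_min
is the smallest ladder size within (1+tolerance) of the minimum error
(tolerance 0.05), n_max the largest, n_mid their rounded geometric mean;
the outer-training set is refitted at each size on the fold's top-ranked
features and the held-out fold predicted. Rank fusion is the arithmetic
mean over ladder steps of the within-step rank, with absent features
scoring step size + 1.

Across repetitions (folds reshuffled each time), per-feature scores are
averaged, set sizes are medians, and performance is computed from the
pooled out-of-fold outer predictions only — BACC or Q² — so the inner
selection cannot leak into the reported number; a permuted-response
sentinel test asserts this collapses to the null level. The headline
`performance` is reported at the mid set size; min/mid/max values are all
stored. Protocol defaults mirror the study scale: 4 outer folds and 500
repetitions for classification, 9 folds and 200 repetitions for
regression; tests and the acceptance script run 2–30 repetitions, which
leaves the expectations unchanged and only widens Monte-Carlo noise.

Everything is deterministic under the config seed: repetition seeds are
spawned from a master `SeedSequence`.

## Synthetic-data generator

The generator defines the study conditions the tests run under: 27
products over five compositional factors (oil type, tomato dosage, yeast
product ∈ {S99, G28, O31, YPr, none}, yeast dosage, heating), 14 assessors
scoring 26 attributes in 4 sessions, and two platform tables (defaults: 500
LC-MS-style, 300 GC-MS-style features). The packaged 27-product design is a
package-constructed layout consistent with those factor levels (24 yeast
rows cycling tomato/oil/heat contexts, plus a 3-product no-yeast arm); the
26 attribute names are placeholders over the real odor / flavor /
mouthfeel / aftertaste / afterfeel categories.

Panel scores follow y = clip(a_i + b_i·μ_jk + ε, 0, 100) with a_i ~
N(0, 8²), log b_i ~ N(0, 0.15²), ε ~ N(0, 6²) per session. These noise
magnitudes are free parameters chosen as plausible trained-panel
variability, not estimates of any dataset; the clipping fraction is
reported so tests can keep it negligible. Incomplete designs use a cyclic
balanced scheme whose rotating per-assessor blocks keep every product
assessed in every session.

Feature tables put the true product contrast (the unit-variance
standardized μ of the marker's attribute) on the log scale: markers get
baseline_f ± marker_effect × c_jk plus technical noise of log-SD
sqrt(log(1+CV²)); non-markers get baseline plus noise. Correlated blocks
(adduct/isotope analogues) share a per-injection latent factor 3.2× the
residual SD, fixing pairwise correlation ≈ 0.91 ≥ 0.9 by construction.
Blank-background contaminant features sit at study-level intensity in
blanks (so the blank filter removes exactly them); ordinary features sit 6
natural-log units lower in blanks. QCs are the pooled study mean plus
technical noise, interleaved every 10 study injections; the first 12
products (matching the study's quadruplicate subset) are injected in
4-fold technical replication. A master seed spawns panel/LC-MS/GC-MS
sub-seeds in that documented order, making whole bundles byte-identical
across runs.

What the generator does **not** emulate: retention-time or spectral
structure, batch drift, missingness mechanisms, nonlinear
sensory–concentration psychophysics (Stevens-type compression), and
between-assessor disagreement beyond offset/gain. Passing tests therefore
demonstrate correctness and calibration of the statistical machinery under
the stated generative model, not instrument-level realism.

## Numerical choices and degenerate inputs

Sample (n−1) SDs everywhere; NIPALS rank tolerance 1e-10 and convergence
1e-13; REML search bounded to log λ ∈ [−15, 15]; importance-rank ties break
by feature position, prediction ties by training label order; CSV floats
are written as shortest round-tripping repr and parsed in round-trip mode
so write→read is exact. Constant slices/features/responses are dropped with
warnings where harmless and raise where the request is unanswerable
(constant y, empty class). PCA truncates beyond-rank component requests
with a warning.

## Known limitations

The rank-fusion and ladder details (geometric schedule, absent-feature
penalty, median set sizes) pin down one reasonable member of the rdCV
family; other fusions change feature ranks slightly but not the calibration
properties the tests assert. Q² is reported from pooled outer predictions;
per-repetition averaging is a near-equivalent alternative that is not
exposed. The forest engine inside the ladder is markedly slower than PLS
and is intended for condensed (GC-MS-like) tables.
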