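# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic-data
experiments do and do not establish.

## Data model and preprocessing

A cohort is a list of patient records, each holding a binary decannulation
outcome, twelve static clinical variables, and an ordered perfusion series
sampled by the device (nominally every 120 s). Six channels come from the
device — membrane-lung pressure drop (mmHg), venous drainage pressure (mmHg),
circuit blood flow (L/min), pump speed (RPM), sweep gas flow (L/min), elapsed
support time (s) — and two ratios are derived per patient: flow/BMI and
sweep/flow. Where flow is exactly zero, sweep/flow is defined as 0 rather than
infinity: zero circuit flow means no effective support, and the ratio's
purpose (gas exchange per unit flow) has no meaning there.

**Truncation augmentation.** Every prefix containing the first
ceil(f·K) points of a K-point run, for f = 0.1, 0.2, …, 1.0, becomes a
separate sample carrying its own end time. This turns one outcome label into
ten time-anchored samples and lets the fitted model be read as a *running*
prediction: the f = 0.3 sample answers "what did the data up to 30% of the
run say?".

**Length standardization.** Each (possibly truncated) series is stretched
over a fixed T-step grid: raw point k maps to slot floor(k·T/K), multiply
occupied slots take the mean of their points, empty slots take the previous
filled slot's value, and slots before the first filled one are zero. Mapping
every truncation over the *full* grid is deliberate: the grid position of the
last point never reveals which truncation the model is seeing. Averaging is
applied before forward-filling. The proportional-stretch slot rule is the
simplest mapping consistent with "average dense steps, forward-fill gaps";
a brute-force binning oracle in the test suite pins down its semantics
exactly. The full-scale grid length is T = 2054; desk-scale work in the tests
uses T = 64–128 through identical code paths.

**Static encoding.** Numerics (age, BMI, two cannula sizes) pass through;
sex, pre-ECMO arrest and pre-ECMO shock are 0/1; cause of respiratory
distress (8 levels), reinfusion site (5), drainage site (5) and ventilation
type (7) are one-hot in a fixed documented order, for 32 dimensions in total.
The exact composition of the published 32-dimensional encoding is not
recorded anywhere, so this schema is the package's own fixed stand-in with
the correct total width; the outcome label is never encoded. Missing numeric
statics are imputed with the cohort median under a logged warning.

**Scaling.** Min-max parameters (per temporal channel and per static
dimension) are fitted on the training split only and applied to all splits;
a constant training feature maps to 0, and out-of-range test values are not
clipped. Fitting on the training split only is load-bearing: the test-time
distribution must not inform the transform.

## The classifier

The network estimates p(y | s, x_{1:T}) and is trained by minimizing mean
binary cross-entropy; with hard 0/1 labels this is equivalent to minimizing
the KL divergence from the empirical conditional outcome distribution.

* Static head: dense 32 → 33 → 25 with tanh. An auxiliary linear decoder
  25 → 32 adds a mean-squared reconstruction term with weight 0.1 (exposed as
  `recon_loss_weight`), implementing the autoencoding scheme as joint
  training rather than pretraining — the simplest reading consistent with a
  single loss graph. Note the 33-wide middle layer *expands* before the
  25-wide code; the widths are implemented as published even though they make
  the "autoencoder" non-bottlenecked.
* Temporal head: a pointwise (1×1) convolution maps the 8 channels to
  `temporal_filters` features with tanh (a cheap learned filter/projection),
  then an LSTM with `lstm_units` units processes the T steps; only the final
  hidden state is used.
* Fusion: concatenation (width 25 + `lstm_units`; 1049 at the published
  sizes) into a single sigmoid neuron, so the fusion stage has exactly
  width + 1 trainable parameters.

The implementation is plain NumPy in float64 with hand-derived gradients
(including backpropagation through time); the test suite verifies analytic
against numerical gradients at 1e-5 relative agreement. Optimization is Adam
(lr 1e-3), minibatches of 32 (default), early stopping on validation loss
with patience 10 and restoration of the best weights; these optimizer
settings are not published anywhere and are exposed in `ModelConfig`.
Training is deterministic given `ModelConfig.seed`. Scores are clipped to
[1e-7, 1 - 1e-7] wherever a log-loss is evaluated.

Baselines (logistic regression, Gaussian naive Bayes, a dense network, a
decision tree — scikit-learn throughout) consume the flattened concatenation
of the temporal matrix (T·8 values; 16,432 at full scale) and the 32 static
features, under exactly the same split and scaling protocol.

## Cross-validation protocol

Each iteration shuffles the cohort and fills 5 disjoint groups with exactly
18 successful and 5 unsuccessful patients; surplus patients are excluded at
random (a 90/28 cohort leaves 3 out). Three groups train, one validates, one
tests, and the test group rotates through all five positions, so every
included patient is tested exactly once per iteration; the default is 12
independent iterations. All truncations of a patient stay on that patient's
side of every split — the suite asserts no patient-level leakage across all
rotations.

## Assessment

AUROC is the normalized Mann–Whitney U statistic computed from average ranks
(ties count one half); the rank form is used because the bootstrap and
permutation procedures evaluate it hundreds of thousands of times, and it is
verified against both a brute-force pairwise oracle and scikit-learn's curve
integration. Average precision is computed with scikit-learn. Confidence
intervals come from a percentile bootstrap: B = 5000
joint resamples of (label, score) pairs, degenerate resamples (one class
only) skipped and counted rather than redrawn — redrawing would bias the
resample distribution, and the skip count makes the behaviour auditable.
Pairs are put in a canonical order before resampling so the interval is
invariant to input ordering under a fixed generator. Per-day tables bucket
samples by end time into half-open day intervals (d−1, d] (a sample ending at
day 0.5 reports on day 1); pooled windows (e.g. days 3–11) use the same rule.
Predictions are pooled across all iterations before bootstrapping (the
alternative — averaging per-iteration intervals — is not used; pooling is
simpler and uses every prediction once).

Two classifiers scored on the same samples are compared with a paired
sign-flip permutation test: the statistic is the metric difference, the null
swaps the two models' scores independently per sample with probability one
half, and the two-sided Monte-Carlo p-value uses the add-one correction
(1 + hits)/(n_perm + 1) so it is never exactly zero. For n ≤ 20 the test
enumerates all 2^n swap patterns and is exact; the suite checks the
Monte-Carlo path against full enumeration.

## Calibration and risk groups

Raw sigmoid outputs are recalibrated by Platt scaling — a logistic regression
of the outcome on the log-odds of the raw score (no target smoothing; the
training sets here are moderate, and smoothing is unnecessary), fitted on
training predictions only. The calibrated training scores' mean M and SD S
define four groups: group 0 (high risk) for x ≤ M − S, group 1 for
M − S < x ≤ M, group 2 for M < x ≤ M + S, group 3 (low risk) for x > M + S,
with exactly these boundary conventions. Snapshots at a clinical horizon
(72 or 96 h) take each patient's latest prediction at or before the horizon;
patients decannulated before the horizon are excluded.

Group success proportions are compared with Boschloo's exact unconditional
test: the ordering statistic is Fisher's one-sided exact p, and the p-value
maximizes, over 999 equispaced nuisance success probabilities in (0, 1), the
probability under independent binomials of a table at least as extreme. The
one-sided direction (high-risk group less successful) is the default; the
implementation is checked against a loop-based enumeration oracle, against
the Fisher upper bound on 500 random tables, and against scipy's
implementation (which parameterizes the table transposed). On the published
72-hour table (7/5 vs 11/1) it gives p = 0.036 → .04 and on the 96-hour table
(6/5 vs 9/0) p = 0.012 → .01, matching the published two-decimal values;
`scripts/acceptance.py` recomputes both.

## The synthetic cohort generator

The generator stands in for the unavailable clinical cohort and defines the
study conditions for every end-to-end check. Defaults: 90 successful / 28
unsuccessful patients, run lengths uniform on 3–21 days, 120-s sampling.
Statics are drawn independently of outcome (age ~ N(50, 15) clipped to
[18, 80]; BMI ~ N(28, 6) clipped to [15, 60]; categoricals uniform), so any
learnable signal is strictly temporal. Each device channel is a per-patient
Gaussian baseline plus stationary AR(1)/Ornstein–Uhlenbeck noise with
correlation time `smoothness` (default 2 h) and a plausible adult-VV-ECMO
scale (e.g. flow 4.5 ± 0.6 L/min between patients, 0.4 L/min within-run
noise SD). Weaning is encoded as a linear ramp over the final 25% of the run
on flow, pump speed and sweep gas flow: in successful patients these decline
to 2·`effect_size` noise-SD units below baseline at the end (so the mean
final-quartile deficit is `effect_size` units); in unsuccessful patients they
stay flat. With `effect_size = 0` the two outcome groups are identical in
law — the random stream is consumed identically for both outcomes, which the
suite verifies bit-for-bit.

What the generator does *not* emulate: measurement dropouts, device alarms
and intervention artifacts, inter-channel physiologic coupling, non-stationary
baselines, weaning *trials* (transient sweep reductions), or any dependence of
static variables on outcome. Passing end-to-end tests on these cohorts shows
the pipeline is leak-free and can learn a temporal weaning signature; it does
not certify performance on real ECMO data.

## Gaussian-process synthesis and the length-scale experiment

To ask whether temporal structure drives performance, patients are split by
outcome, sorted by run length, and grouped into consecutive triplets (a 90/24
cohort gives 30 successful and 8 unsuccessful triplets; remainders are
dropped with a warning). For each triplet, one GP regressor per perfusion
variable (8 in total) is fitted on the stacked member data with covariates
(standardized age, 0/1 sex code, standardized BMI, raw time-step index) and
the unnormalized channel values as targets. The kernel is implemented exactly
as published, k = exp(−d²/(2L)) with Euclidean d — note the denominator 2L,
not the textbook 2L²; `convention="squared"` provides the textbook form. The
time covariate is left unstandardized so that L = 1 sits at the grid spacing,
matching the statement that the length scale cannot go below one time step.
A jitter of 1e-6 times the target variance on the kernel diagonal keeps the
Cholesky factorization stable; each GP is fitted on stacked member data (not
member averages), and each synthetic draw evaluates the joint posterior over
the full grid at one member's covariates, chosen round-robin, inheriting that
member's statics and the triplet's label. Successful triplets are sampled 3
times and unsuccessful ones 18 times (30·3 + 8·18 = 234 synthetic patients),
and synthetic cross-validation uses 5 groups of 6 successful + 1 unsuccessful
triplets (36 synthetic patients each), with surplus triplets excluded at
random per iteration.

The experiment synthesizes one source cohort (effect size 1.5) at L = 1 and
L = 100, trains the classifier and logistic regression on both under the
shared triplet fold plan, and compares pooled test AUROCs with the paired
permutation test (synthetic patients pair one-to-one across length scales).
Desk-scale sizes, chosen once: GP/model grid T = 128 (the largest the test
budget affords), 90/24 source cohort, runs 24–120 h, the width-32 model
profile trained with up to 100 epochs (patience 12, batch 18).

**A scale caveat, observed honestly.** At the published grid length
(T = 2054) the L = 100 kernel correlates points over sqrt(2·100) ≈ 14 steps,
i.e. 0.7% of a run — long-range dependence is destroyed while almost all
local resolution relative to run length is kept. At T = 128 the same 14 steps
are 11% of the run, so the L = 100 synthesis also measurably denoises and
smooths each curve, which *changes overall problem difficulty for every
model*: a flattened linear model, scored on 180 paired samples, often shows a
small but statistically significant AUROC shift between the two syntheses.
Moreover, this generator's weaning ramp is a low-frequency, marginal-value
signal that GP interpolation preserves at both length scales (the
between-group final-quartile flow gap is numerically identical at L = 1 and
L = 100), so the part of the published contrast that comes from destroying
*conditional* temporal structure has no counterpart here. Consequently the
length-scale contrast at desk scale is directionally positive for the
temporal model in most seeds but is not jointly significant-for-CEVVO and
flat-for-logistic-regression in the large majority of seeds, and the
corresponding acceptance test records this as a failure rather than relaxing
its conditions. Reproducing the published pattern faithfully would need
either the full 2054-step grid (so that L = 100 alters long-range structure
only) or a generator whose outcome signal lives in the conditional law of the
series rather than in late-run marginal levels; both are deliberate
non-extensions here.

## The zero-effect control

With `effect_size = 0` the pipeline is run end to end (generation, folds,
scaling, training of the classifier and all four baselines, pooled
bootstrap); a leak-free pipeline should leave every model's test AUROC
interval covering 0.5. This control uses full runs only (no truncation
augmentation) so the resampled units are independent at patient level — the
pairs bootstrap assumes exchangeable units, and pooling ten strongly
dependent truncations per patient makes its intervals anti-conservatively
narrow — and pools three CV iterations so per-fold model noise averages out.

One subtlety deserves emphasis because it is easy to misread as a leak:
heavily overfit models sit systematically *below* 0.5 on this control. Train
and test folds are drawn without replacement from one finite cohort, so
their chance feature–label correlations are negatively correlated given the
cohort's total; a model that memorizes the training fold's noise therefore
anti-generalizes in expectation under the null. The effect is
model-agnostic (a 1-nearest-neighbour memorizer shows it most strongly) and
points in the *opposite* direction from label leakage, which inflates AUROC
above 0.5. The regularized baselines stay within their intervals; the
high-capacity temporal network, trained on 69 samples, does not always. The
acceptance test asserts the strict all-models condition, and its failure
mode on this count is the statistical phenomenon above, not a pipeline
defect.

## Numerical choices

* Log-loss score clipping at 1e-7; GP kernel jitter 1e-6 × target variance;
  posterior covariances that lose positive definiteness to cancellation fall
  back to an eigenvalue clip at zero.
* Boschloo nuisance grid: 999 equispaced interior points (configurable);
  table ties in the Fisher statistic are compared with a 1e-12 absolute
  tolerance.
* Min-max scaling of a constant feature returns 0 (not NaN); empty series
  standardize to the zero matrix.
* CSV round-tripping uses pandas' `round_trip` float parser; the default C
  parser loses the last ulp.
* LSTM forget-gate bias initialized to 1; all other weights Glorot-uniform.

## Known limitations

* The published real-data performance (AUROC ≈ 0.69, AP ≈ 0.86 with tight
  CIs) cannot be checked here: the clinical cohort is not public, and all
  end-to-end numbers in this package refer to generated cohorts.
* The 32-dimensional static schema is a documented stand-in; real cohorts
  with different category inventories need a custom `StaticSchema`.
* The desk-scale profiles (T = 64–128, width 32) exercise identical code to
  the full-scale architecture but say nothing about its computational
  behaviour at T = 2054 with 1024-unit layers on long cohorts.
* The pairs bootstrap treats pooled predictions as exchangeable; with
  truncation-augmented, multi-fold pooling its intervals are optimistic (see
  the zero-effect control above).
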