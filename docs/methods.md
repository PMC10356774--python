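# Methods

`ehrseq` implements a longitudinal diagnostic-forecasting workflow for
coded healthcare trajectories: cohort and label construction from
visit-level claims tables, a multitask-pretrained transformer encoder over
(code, code-type, temporal-bucket) embedding sums, fine-tuning for a rare
binary outcome, isotonic calibration, bootstrap evaluation, and
integrated-gradients interpretation. Everything runs on one CPU at the
"desk scale" described below, against a bundled synthetic claims
simulator; the statewide discharge datasets that motivate the design are
access-restricted and out of scope.

## Cohort construction and labeling

The prediction anchor is the **index visit**: a patient's chronologically
last visit in the index year (default 2018), so that at least one full
year of follow-up is observable. The model's inputs are all visits up to
and including the index visit. The binary label is positive iff any
outcome diagnosis code occurs strictly after the index date and within 365
days of it; outcome codes at or before the index set a `prior_outcome`
flag instead, and `filter_first_event` removes such trajectories for the
first-event analysis. We deliberately count outcome codes *at* the index
visit as prior outcomes rather than events: index-visit codes are model
inputs, and treating them as targets would leak the label.

Diagnosis codes are truncated to their first three characters (after
punctuation stripping and uppercasing), grouping related ICD-style codes.
Days-before-index are grouped into seven buckets — 0, 1–29, 30–89, 90–179,
180–359, 360–719, 720+ — giving a coarse, non-linear representation of
visit timing. Patient-level random splits are 95:5 (pretraining dev/test)
and 9:1 (fine-tuning dev/test, with the dev portion further split 9:1
train/val); no patient appears in two splits.

Tokenized sequences are fixed at 512 positions: `[CLS]`, four demographic
tokens (age decade, sex, race, payor, taken from the index visit, time
bucket 0), then visit features oldest→newest, each carrying a code id, a
code-type id (principal / auxiliary / external-cause / procedure /
demographic / special) and a time-bucket id. Over-long inputs drop their
oldest visit features first — never `[CLS]`, demographics, or the newest
visit while it fits; padding is a contiguous suffix excluded from
attention. Codes rarer than `min_count` map to `[UNK]` rather than being
dropped, preserving sequence structure.

## Model

Each input position is the elementwise **sum** of three learned
d-dimensional embeddings (code + type + time bucket), followed by layer
normalisation. The encoder is a standard bidirectional multi-head
self-attention stack (post-LN residual blocks, GELU feed-forward); a
pooler (dense + tanh on the `[CLS]` position) summarises the trajectory.
Three heads: a linear decoder over the code vocabulary for masked-feature
recovery, a feed-forward next-visit category classifier, and a dense +
sigmoid binary risk head.

The network is written in numpy with explicit forward caches and
hand-written backward passes, verified against finite differences. This
keeps the implementation dependency-light, bit-deterministic given a seed,
and differentiable with respect to the summed input embeddings — exactly
what integrated gradients needs. The desk default is d_model 64 (tests use
32), 2 layers, 4 heads; a 780-dimensional production-style configuration
is expressible but not exercised. Dropout defaults to 0 at desk scale.
Initialisation is truncated normal (σ = 0.02, clipped at 2σ) from a fixed
seed. Whether normalisation follows the embedding sum is not a settled
convention; we apply LN after the sum, the common choice in this
architecture family.

## Pretraining

Two objectives are computed on every batch and their cross-entropies
summed:

* **Masked-feature modeling** — visit-feature positions (diagnosis,
  external-cause, procedure tokens; never `[CLS]`, demographics or
  padding) are selected i.i.d. with probability 0.15; selected positions
  are replaced by `[MASK]` with probability 0.8, by a uniformly random
  non-special code with probability 0.1, and left unchanged with
  probability 0.1. The decoder predicts the original codes at selected
  positions.
* **Next-visit category prediction** — for a trajectory with v ≥ 2 visits,
  every feature token of visit v is replaced by `[MASK]` and the pooled
  output predicts the clinical category of visit v's principal diagnosis.
  Temporal buckets are recomputed relative to visit v's date so the
  inputs' own buckets do not reveal the target visit's timing.

Demographic tokens are not eligible for corruption: they are static
context, not forecastable visit content (a judgement call; the alternative
is defensible).

## Fine-tuning and imbalance handling

Fine-tuning optimizes weighted binary cross-entropy on the binary head,
initialised either from pretrained parameters or from scratch (identical
code path; the difference is the starting point — this is the
pretraining-ablation comparison). Rare outcomes (~1% prevalence) are
handled by class-balanced weighted random sampling (selection
probabilities proportional to class weights) combined with a positive
class weight in the loss. The loss weight defaults to #neg/#pos; at ~1%
prevalence that weight approaches 100 and, stacked on an already-balanced
sampler, it double-compensates and destabilises training, so the planted-
signal and pretraining-benefit experiments set `pos_weight=1.0` with
balanced sampling. Optimization is AdamW (decoupled decay
on matrices only) with linear warmup then linear decay; early stopping
monitors validation AUROC with patience 3 evaluations and restores the
best parameters. Hyperparameters can be chosen by seeded random search
(`random_search`) over a finite grid; the shipped experiment
configurations use fixed, hand-chosen values.

## Evaluation

AUROC is the Mann–Whitney statistic (ties get half credit); AUPRC uses the
step-wise average-precision convention, appropriate for rare outcomes.
Confidence intervals are percentile bootstrap over patient-level resamples
(the production analyses use 10,000 resamples; pipeline configs and tests
use 500–1,000 for CPU budget — the machinery is identical). Paired model
comparisons apply identical resample indices to both models and report
two-sided sign-fraction p-values floored at 1/n_resamples. Top-k%
operating points flag ⌈k%·n⌉ highest scores with stable (score desc,
patient id) tie-breaking and report threshold, sensitivity, specificity,
PPV and NPV. Isotonic calibration (pool-adjacent-violators) is fit on the
validation split and applied to test predictions; out-of-range scores
clamp to boundary values. The lag analysis regresses calibrated case
probabilities on days between prediction and event (OLS), reporting the
slope per 100 days plus the median/IQR lag and a histogram export.

The comparator baseline is logistic regression on one-hot demographics
plus five any-prior-diagnosis indicators (psychiatric, substance use,
injury, pregnancy, homelessness), fit by maximum likelihood with a small
ridge penalty guarding against separation.

## Interpretation

Integrated gradients attributes the binary output to input positions by a
midpoint-Riemann path integral of the input-embedding gradient from a
baseline to the input. The baseline is the embedded all-`[PAD]` sequence
retaining `[CLS]` and the input's attention mask — the model's native
"absence" input. The completeness residual |Σ attributions − (f(x) −
f(baseline))| is reported per trajectory and shrinks as steps grow;
attribution is computed on the raw sigmoid output (calibration is monotone
so rankings are unaffected). Cohort summaries take the top-2 features per
trajectory by attribution magnitude (stable tie-break) and export category
pair counts for a chord-diagram view. Code embeddings are projected to 2-D
with seeded t-SNE after an occurrence filter. Representative-trajectory
exports choose k-medoid exemplars of cases (pooled-CLS space), top-scored
negatives, or bottom-scored positives; 30% of features are resampled from
the cohort's per-type feature pools and codes below an occurrence floor
are dropped, so no export is a verbatim record.

## Synthetic claims simulator

The simulator emulates the structure of statewide discharge data without
any clinical realism in code semantics:

* **Visit timing**: per-patient homogeneous Poisson process over
  2016–2019 (`visit_rate` = 5.5 mean visits, zero-truncated), matching a
  median of ~5 visits (IQR ~4–7) and producing gaps spanning all seven
  temporal buckets.
* **Codes**: ICD-like letter+2-digit diagnosis codes partitioned by a
  CCSR-style category map into five named predictor groups (psychiatric,
  substance use, injury, pregnancy, homelessness), a small outcome group,
  and neutral categories. Categories follow a sticky first-order Markov
  chain across visits — the sequential structure the next-visit objective
  must learn. Auxiliary counts are negative-binomial (median ~7 total
  codes per visit); 40% of raw codes carry decimal extensions to exercise
  truncation.
* **Outcome**: a discrete-time logistic hazard over twelve ~30-day
  post-index intervals whose logit rises by `risk_effect` per planted
  risk-code exposure accrued before the index, plus small age/sex effects
  (scalable via `strata_effects`) and a recurrence bonus for prior
  outcomes. The intercept is calibrated by root finding so the *observed*
  post-index outcome prevalence matches the target — accounting for the
  fact that a simulated outcome visit still inside the index year becomes
  the patient's new index visit and is absorbed rather than observed.
* **Demographics**: categorical draws with marginals loosely matching
  adult statewide ED/inpatient populations; a 10% latent high-risk class
  up-weights the predictor categories, creating exposure heterogeneity.

What the simulator does **not** reproduce: real comorbidity structure,
facility effects, coding drift, informative censoring, or any ICD
semantics. Passing tests therefore demonstrate that the machinery recovers
planted structure under the stated generative assumptions — not clinical
performance on real data.

## Problem sizes and numerical choices

The shipped experiments use a 20,000-patient simulated cohort (~13,000
fine-tuning trajectories at ~1.1% outcome prevalence), a d_model 32
encoder, sequence length 96 (64 for the pretraining-benefit comparison;
tokenization itself defaults to 512 and is asserted at 512), 300–400
training steps at batch 32, and 500–1,000 bootstrap resamples. These sizes
were chosen so the full workflow replays in minutes on a single CPU while
leaving the planted signal comfortably detectable: the fine-tuned model
reaches held-out AUROC ≈ 0.74–0.81 across seeds with 95% bootstrap CIs
excluding 0.5, and planted risk codes out-attribute neutral codes under
integrated gradients (one-sided Mann–Whitney p < 0.01).

Ties: same-date visits and index ties resolve by stable input row order;
top-k ties by (score desc, patient id). Degenerate inputs (single-class
calibration sets, groups without positives, single-class sampler labels)
raise or flag explicitly rather than propagating NaNs. Bootstrap resamples
on which a metric is undefined are skipped and counted, with failure above
1%. All randomness flows through numpy Generators seeded from explicit
config fields; CLI stage seeds derive from one global seed via
`(seed·1000003 + crc32(stage)) mod 2^31`.

## Known limitations

* The numpy encoder is single-threaded and CPU-bound; it is not intended
  for production-scale vocabularies or millions of trajectories.
* The simulator's hazard depends on exposure *counts* only; it cannot
  express interactions, protective codes, or time-decaying risk, so
  calibration-curve shapes on synthetic data are not informative about
  real data.
* The lag analysis inherits the simulator's event-time distribution,
  which is right-shifted relative to real cohorts because events inside
  the index year are absorbed into the index.
* Isotonic calibration is fit on the (small) validation split; with few
  positives the fitted map is step-y and the calibrated probabilities
  coarse.
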