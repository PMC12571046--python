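# Methods

This note documents the models and procedures implemented in `motr`, the
assumptions they make, and the numerical choices behind them.

## From trajectories to reading measures

A mouse-tracking-for-reading trial records the cursor at a nominal 20 Hz
(50 ms between samples) while the participant unblurs text by moving the
mouse. Processing proceeds in three steps.

**Word assignment.** Every sample is assigned to the word whose bounding
box is nearest in Euclidean distance (zero inside a box). Distance to the
box rather than to the word centre makes the assignment robust to word
length, which differs systematically between condition words here (the
long-form modifying adjective is one character longer than the short-form
predicative one). Exact ties go to the word with the smaller index —
leftmost in reading order — deterministically.

**Attentional associations.** Maximal runs of consecutive samples on the
same word are merged into *associations*, the fixation analogue. An
association lasts from its first sample to the onset of the next
association; the final association of a trial is credited one nominal
sample period (50 ms), which is unbiased relative to dropping the final
dwell. Gaps in sampling are credited to the association preceding them.

**Filtering.** Associations shorter than 160 ms or longer than 4000 ms are
excluded; the boundaries themselves are kept (strict inequalities).
Filtering happens after merging; by default, associations that become
adjacent on the same word after an exclusion are re-merged (durations
summed) and re-checked against the maximum only. The re-merge is a
package decision — fixation-exclusion practice varies on this point — and
can be disabled via `FilterPolicy(remerge_after_filter=False)` for
sensitivity analyses.

**Measures.** At word or region granularity (region is the analysis
default; a region's associations are the merged runs of its words), five
measures are computed per unit and trial:

* *gaze duration* — dwell in the first pass, i.e. until the first
  association off the unit in either direction;
* *go-past time* — all dwell from the first encounter until the first
  association strictly to the right, including regressive revisits;
  missing (right-censored, not truncated) if the unit is never passed;
* *total duration* — all dwell on the unit;
* *FPReg* — 1 if the association ending the first pass lies to the left;
  missing if the trial ends during the first pass;
* *RegIn* — 1 if the unit is fixated again after having been exited
  rightward (unit → right of unit → unit); 0 if fixated but never
  regressed into; missing only for never-fixated units.

"Right" is word/region order, not raw x, so multi-line layouts degrade
gracefully. A brute-force oracle that walks the association list applying
these definitions literally is kept in the test suite; the pipeline must
match it exactly on randomized sequences.

**Participant exclusion.** Participants with comprehension accuracy
strictly below 0.8 are dropped; exactly 0.8 is retained. Every stage logs
counts in and out so exclusion audits are testable.

## Design and synthetic data

The study design crosses grammaticality (match/mismatch), head-noun gender
(feminine/masculine) and agreeing element (modifying adjective,
predicative adjective, verb); agreement type (internal = modifying
adjective) and lexical category (verb vs. adjective) are functions of the
element, giving 12 cells. Defaults follow the study layout: 24 target
items (8 per element), 48 fillers (half grammatical), 4 practice items, 3
lists, 42 comprehension questions, 64 participants. List rotation ensures
each participant sees each item in exactly one grammaticality condition,
with gender counterbalanced so every participant contributes two trials
per design cell; across lists every item occurs in both grammaticality
conditions.

The measure generator draws directly from the analysis model below, so
simulated data carry exact ground truth. The trajectory generator renders
target region dwell times as raw samples: the *saccadic* profile dwells
near each word's centre (lognormal-jittered) and jumps between words in
one inter-sample step, which recovers region times to within half a
sample period; the *smooth* profile moves at piecewise-constant velocity
and never halts, giving coarser recovery. Regressions are inserted as
discrete events — after the critical region's first pass the cursor
returns to an earlier region (region 2 by default, under the agreement
controller) for a drawn revisit time — with probability given by a
Bernoulli model whose grammaticality coefficient makes mismatch trials
regress more. Effect-size defaults mimic agreement-mismatch reading
studies: a ~40 ms mismatch penalty on ~500 ms region totals
(`Gram = 0.10` log units at `beta0 = 6.2`), negative main effects of
agreement type and lexical category, small positive interactions, and a
regression-out base rate near 0.15. Layouts use a fixed-width character
metric (14 px/char, single line).

What the generator does *not* emulate: motor noise and overshoot,
mid-word landing-position effects, word-frequency or length effects on
dwell (beyond layout geometry), strategy mixtures within a participant,
and any dependence between trials. Passing round-trip and calibration
tests therefore certifies the pipeline's arithmetic and the estimator's
statistical calibration, not behavioural realism.

## The hierarchical model

For participant *i*, item *j* and contrast-coded predictors
*x₁ … x_P*:

    eta = (beta_0 + b_{0i} + c_{0j}) + sum_p (beta_p + b_{pi} + c_{pj}) x_p

Durations are modelled as `y ~ Lognormal(eta, sigma)` — identically, a
normal model on log y, a property asserted in the tests — and binary
regression indicators as `y ~ Bernoulli(logit^{-1}(eta))`. Random vectors
`b_i` and `c_j` are zero-mean multivariate normal with correlations
estimated within each grouping factor; by-item slopes exist only for
predictors that vary within an item (agreement type and lexical category
are between-item and get none). Rows with a missing response are dropped
per measure, never imputed; counts are logged.

**Contrast coding.** Comparisons are written as hypothesis weights over
the 12 cells (each row sums to zero and is scaled so that the weighted sum
of cell means *is* the averaged condition difference); the model matrix is
the Moore–Penrose generalized inverse of the hypothesis matrix, so each
coefficient is directly the named condition difference. Signs: Gram =
mismatch − match, Gen = masculine − feminine (arbitrary), AgrType =
internal − external, LexCat = verb − adjective, interactions are
differences of mismatch penalties, and the three-way rows are the gender
differences of the two-way rows. The Gram×Gen two-way term is omitted
from the default predictor set (the printed analyses this package mirrors
do the same) but available via `include_gram_gen=True`.

**Priors** (reading times / binary):

| parameter | RTs | binary |
|---|---|---|
| intercept | Normal(6, 1) on log-ms | Normal(0, 1) |
| slopes | Normal(0, 0.1) | Normal(0, 1) |
| sd(b), sd(c) | Exponential(2) | Exponential(2) |
| correlations | LKJ(2) | LKJ(2) |
| sigma | Exponential(2) | — |

Normal(6, 1) puts the prior predictive baseline near e⁶ ≈ 403 ms. The
lognormal is fitted on raw milliseconds with priors read on the log-ms
scale; no response scaling is applied.

**Sampler.** No probabilistic-programming backend is assumed: the
posterior is drawn by a blocked Gibbs sampler written for exactly this
model family.

* Fixed effects and each group's random-effect vectors have exact Gaussian
  full conditionals (batched Cholesky draws). For the Bernoulli family
  these conditionals are obtained by Pólya-Gamma augmentation; PG(1, c)
  variates are drawn from the truncated (120-term) infinite convolution of
  gammas with a moment-matched constant for the dropped tail, whose first
  moment is checked against `E[PG(1,c)] = tanh(c/2)/(2c)` in the tests.
* An exact Gaussian *translation move* shifts mass along the
  likelihood-invariant direction `(beta_p + delta, b_{pi} − delta)` for
  each grouping factor, eliminating the slow random-walk coupling between
  intercepts and random-intercept means.
* Scales: sigma and every random-effect sd are slice-sampled on the log
  scale. Each sd additionally gets an interweaved (ancillarity–
  sufficiency) update holding the whitened effects fixed — a change of one
  sd then rescales one effect column, making the conditional an explicit
  quadratic — which removes the classic stickiness of centred samplers at
  small variance components.
* Correlation matrices are parameterized by canonical partial correlations
  (C-vine), under which LKJ(η) factorises into independent scaled Beta
  densities with shape `η + (d−2−k)/2` at row k; this representation is
  verified against the known LKJ marginals in the tests. Coordinates are
  slice-sampled in a round-robin schedule (12 coordinates per scan by
  default) to bound per-iteration cost.

Inference defaults are 4 chains × 4000 iterations (2000 warm-up).
Convergence is flagged by split R-hat ≤ 1.01 and bulk ESS ≥ 400 for every
fixed effect (via arviz); Gibbs transitions have no divergence concept, so
the divergence count is reported as 0 for interface parity.

**Back-transformation.** Effects are reported in milliseconds or
probability by computing, per posterior draw, all 12 cell linear
predictors from the fixed effects, applying the inverse link cellwise, and
applying the effect's hypothesis-row weights to the transformed cell
values; the draws are then summarized (mean, 95% interval). A plug-in
variant at the posterior mean is available (`method="mean"`), but the
draw-level version is the default because it preserves the
"difference between conditions" reading and propagates uncertainty.

**Marginal mismatch costs.** The estimated-marginal-means style follow-up
computes, within each agreeing element and averaging over gender, the
mismatch − match difference on the response scale per draw, with a 95%
interval, the two-sided posterior tail probability of a sign flip
(primary), and a normal-approximation p-value offered only for
comparability with frequentist marginal-means software — the two summarize
different things and are labelled accordingly.

## Marginal likelihoods and Bayes factors

Two reduced models are compared: main effects plus Gram×AgrType only,
versus main effects plus Gram×LexCat only, identical otherwise. The Bayes
factor is the ratio of marginal likelihoods, estimated by iterative
optimal bridge sampling against a moment-matched normal proposal, with
the posterior sample split between proposal fitting and estimation and an
approximate relative-MSE Monte-Carlo standard error.

For the Gaussian families the bridge operates in a *collapsed* space:
given the variance parameters, the fixed and random effects integrate out
analytically (the marginal of log-responses is multivariate normal), so
the bridge runs over ~30–70 dimensions of scales and partial correlations.
This is dramatically more stable than bridging the full latent space —
two independently fitted chains agree to within ~0.05 log units — at the
cost of one N×N Cholesky per density evaluation. The Bernoulli family has
no such collapse; its evidence uses the full latent space and is reliable
only at moderate dimensionality (intercept-only random structures are
recommended for binary-measure comparisons and used in the examples; the
full-slopes latent bridge in several hundred dimensions is not trusted and
results are flagged through the convergence field).

Prior sensitivity is mapped by sweeping only the interaction
coefficient's prior sd; all other priors stay at their defaults. Labels
follow the conventional ladder (1–3 anecdotal, 3–10 moderate, >10
strong), with the >3 cut operative; values below 1 favour the
lexical-category model reciprocally.

## Power analysis

Counterfactual studies are simulated from a generative parameter set —
full generative draws including fresh random effects, not residual
resampling — at each (items × participants) grid point, refitted with
reduced sampler settings (2 chains × 500 iterations by default; a
deliberate deviation from the inference defaults, recorded in the
output), and power is the raw detection fraction; no smoothing. Detection
means the 95% credible interval excludes zero (a `p_below_alpha`
criterion is available for comparability). Item counts must divide over
the six element × grammaticality conditions. Per-replicate seeds are
derived from the master seed and returned, so any single replicate can be
re-run exactly. Note that with informative slope priors the
credible-interval criterion is *conservative* under a true zero effect:
the type-I rate sits at or slightly below the nominal 5%.

## Calibration of the whole stack

The package's strongest correctness check is simulate-and-refit
calibration (`calibration_study`): each replicate simulates a 24-item ×
32-participant study from the generative model, refits it with the
default priors, and records interval coverage per fixed effect. The
standard mode holds the ground truth at the study-condition generator
defaults and redraws random effects and noise each replicate, so coverage
estimates the intervals' frequentist calibration at realistic truths —
about 95%, and above it for coefficients shrunk toward zero (the
informative slope prior makes intervals conservative for small true
values; the visible flip side is shrinkage bias, e.g. a true 0.05
three-way coefficient is pulled toward zero by a few hundredths). The
acceptance suite runs 50 such replicates and requires 90–100% coverage
per effect and |bias| < 0.02 log units on the grammaticality coefficient.

A stricter `truth="prior"` mode redraws *all* parameters from the priors
each replicate (full simulation-based calibration, exactly 95% under
perfect sampling). It is the sharper diagnostic but also a harsher
regime than reading data ever present: Exponential(2) routinely draws
random-slope sds several times larger than any observed reading study,
and under such truths the weakly identified item-side directions (three
or four coefficients informed by eight items each) need far longer chains
than the defaults; with the reduced settings used in testing, their
empirical coverage sits a few points below nominal. A Geweke-style
joint-distribution test of the transition kernel (alternating Gibbs scans
with data re-simulation reproduces the prior's slope mean and sd to three
decimals) is part of the development record and localizes the gap to
finite-chain mixing, not the kernel.

## Problem sizes and reproducibility

Test and demonstration runs scale the study down — typically 24–32
participants, single or double chains with a few hundred post-warmup
draws for unit tests, 50 calibration replicates, 100 power replicates at
reduced settings, and 20-replicate power cells in the end-to-end script —
sizes chosen as the package's own benchmark configuration; the inference
defaults (4 × 4000) remain the recommendation for real analyses. All
randomness flows from explicit integer seeds through
`numpy.random.Generator`; per-participant substreams are derived by
counter so enlarging a simulated study never perturbs existing
participants, and the CLI writes byte-identical outputs given the same
seed and config.

## Known limitations

* The sampler is specialized to this model family (two crossed grouping
  factors, the priors above); it is not a general-purpose PPL.
* Binary-measure marginal likelihoods degrade with large random-effect
  structures (see above).
* The trajectory generator's regression model is a stand-in with the
  right rates, not a behavioural model of regressive reading.
* Correlation parameters mix more slowly than means and scales; their
  posteriors need the full inference settings, and with only 24 items the
  item-side correlations remain prior-dominated.
* Multi-line stimuli are accepted but "rightward" is index order, not
  geometry.
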