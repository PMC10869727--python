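# Methods

## The model

`mpisurv` trains a convolutional scorer f(x) on multi-slice grayscale
myocardial-perfusion studies under the proportional-hazards model

    h(t | x_i) = h0(t) · exp(f(x_i)),

where x_i is subject i's slice stack and f(x_i) is a unitless
log-relative-hazard ("risk score").  The training objective is the Cox log
partial likelihood

    log L = Σ_i δ_i [ f(x_i) − log Σ_{j ∈ R(t_i)} exp(f(x_j)) ],

with δ_i the event indicator and R(t_i) = {j : t_j ≥ t_i} the risk set.
The baseline hazard h0 cancels, so the network never estimates it.  During
training the likelihood is evaluated *within each mini-batch*: risk sets are
restricted to the batch, batches containing no event contribute no term and
are skipped for the parameter update.  The loss is the exact negation of the
library's `partial_log_likelihood`, so the trainer and the classical Cox
machinery share one objective; a linear scorer trained with whole-cohort
batches converges to the Newton–Raphson maximum-partial-likelihood estimate
(this reduction is exercised in the tests and the acceptance script).

Tied event times use Breslow's convention — the partial likelihood as
written above *is* Breslow's form — so comparisons against software
defaulting to Efron's correction will differ slightly on tied data.  Each
risk-set log-sum-exp subtracts the running maximum score for numerical
stability; the objective is invariant to adding a constant to all scores.

## Input representation and architecture

A study is an ordered stack of equal-sized 2D slices: two conditions (rest,
stress) × three cardiac axes (short, horizontal long, vertical long).  The
standard acquisition layout is 96 slices (24 + 12 + 12 per condition); a
reduced 8-slice layout (2 + 1 + 1) supports desk-scale experiments.
Intensities are min–max rescaled to [0, 1] per study at load time
(zero-range studies map to zeros with a warning), then standardized per
channel over the training cohort before entering the network.

The slices enter as *input channels* of a 2D convolutional encoder — the
tensor layout for a multi-slice stack is a genuine design choice; a 3D
convolution variant is out of scope.  The encoder is a ResNet-style stack:
a 3×3 stem, then residual stages of conv–BN–ReLU–conv–BN blocks with
identity (or strided 1×1 projection) shortcuts, global average pooling, and
a single linear score head.  Batch normalization is integral: at the small
learning rate used here an unnormalized network optimizes far too slowly to
be useful.  Three scales are provided — `tiny` (stages of 8/16/32 channels,
one block each; the profile exercised throughout the tests), `small`
(16/32/64, two blocks), and `resnet50_like` (64/128/256/512 with 3/4/6/3
blocks) — plus a `linear` scale for the tabular special case.  Three input
modes mirror the clinical-fusion variants: `image_only`, `clinical_only`
(a small fully connected network on the six covariates), and `combined`,
where the standardized clinical covariates join the pooled image features as
additional entry nodes before the head.

Optimization uses Adam with the standard protocol defaults: batch size 16,
learning rate 1e-4, 70 epochs, no early stopping (epoch count is
config-driven; the desk-scale profiles use ~10–12 epochs, which the tiny
encoder needs to converge on the phantom task).  All randomness —
initialization, shuffling, fold assignment — flows from the single
configured seed.  Inference is deterministic (normalization uses running
statistics).

Model selection uses k-fold cross-validation (default k = 5): one scorer
per fold, each evaluated on its held-out fold by the *truncated* Harrell
concordance at the configured horizons (1000/2000/3000 days), keeping the
scorer with the highest C-index across horizons ("max" selection; "mean" is
a config switch).  Whether a per-horizon "C-index" means truncated
concordance or a horizon AUC is ambiguous in common usage; this package
implements truncated concordance for selection and exposes horizon ROC/AUC
separately in the evaluator.

## Evaluation protocol

* **Concordance** — Harrell's C over comparable pairs (event subject i,
  t_i < t_j, or t_i ≤ t_j with j censored); score ties count ½.  With a
  horizon, pairs whose event time exceeds it are excluded.
* **Kaplan–Meier** — product-limit estimator reported at event times.
* **Log-rank** — k-group statistic with the hypergeometric variance, ties
  handled jointly, χ² with k−1 df, upper-tail p, no continuity correction.
* **Stratification** — empirical type-1 quantile thresholds (the ⌈nq⌉-th
  order statistic), so 388 distinct scores split exactly 194/194 at the
  median and 194/97/97 with cuts at (0.5, 0.75).  Tied scores at a cut are
  rejected by default (`stable_order` breaks them by sort order instead).
* **Horizon labels** — positive = event by the horizon; negative = followed
  beyond it event-free.  Subjects censored earlier are excluded by default;
  the `censored_as_negative` policy (treating censoring as event-free
  follow-up) is exposed explicitly rather than silently adopted.
* **ROC** — threshold sweep with trapezoidal AUC (equals the normalized
  Mann–Whitney U).  For a three-level stratification the ROC is the
  three-segment polyline through the "high only" and "high + intermediate"
  operating points; its AUC equals the threshold-sweep AUC of the ordinal
  stratum index, an identity the tests verify.
* **Subgroup hazard ratios** — per-subgroup single-covariate Cox fits of
  the score, coded either as a full-cohort z-score or as a top-quartile
  indicator (both codings are offered; neither is canonical).  Zero-event
  subgroups are reported "not estimable".
* **Event rates** — percentages round half away from zero to two decimals.

The Cox fitter is Newton–Raphson with step halving on the Breslow partial
likelihood, convergence at score-norm < 1e-9, standard errors from the
inverse observed information, 95% CIs at exp(β ∓ 1.959964·SE), and a
separation guard (|β| > 20 flags non-convergence instead of diverging
silently).  An optional ridge penalty (default 0) can rescue separated
data.  Risk-set sums use sorted suffix accumulation (O(n log n)); the
naive O(n²) enumeration is kept in the test suite as the oracle.

## The phantom generator

The synthetic cohort exists so every stage has ground truth.  Each subject
carries a latent defect severity s ∈ [0, 1] (uniform by default; a
two-point law is available) that drives both data channels:

* **Images.**  Short-axis slices render a Gaussian annulus ("myocardium")
  whose amplitude fades toward apex and base; long-axis slices render an
  open ring.  A wedge-shaped uptake deficit with angular extent and depth
  proportional to s is carved into the stress slices and attenuated by a
  reversibility factor (default 0.5, mimicking stress-induced ischemia;
  1.0 gives a fixed "infarct" defect) in the rest slices.  The wedge's
  angular position is randomized per subject so a learner cannot key on
  location.  Gaussian noise (σ = 0.05) and a light blur (σ = 0.7 px)
  follow, then min–max normalization.  A simple rest-minus-stress ring-mean
  statistic recovers s with Spearman ρ ≈ 0.98 at default noise, so the
  images demonstrably carry a learnable signal.
* **Outcomes.**  Event times are drawn by inverse transform from the
  cumulative hazard H0(t)·exp(β_true·s) (closed form for the exponential
  default and the optional Weibull), with administrative censoring at
  10 years minus a uniform 0–5-year staggered-entry jitter.

**Calibration.**  The default hazard pair (β_true = 4.0, baseline rate
4.9e-6/day) was solved against the event-rate structure of a
moderate-to-severe ischemia cohort: ~15% cumulative events by censoring,
with five-year incidence ≈ 3% in the lower severity half versus ≈ 25% in
the top quartile.  Under a 15% overall rate and uniform severity the
top-quartile five-year incidence cannot reach 40% however large β_true is,
so the preset matches the overall rate, the low-risk figure and the
direction of the gradient rather than every stratum value.  The
`paper_like` preset re-solves the baseline rate (by quadrature + bisection,
deterministic) for whatever effect size and severity law are configured, so
cohorts with different β_true — including the β = 0 null — share the same
marginal event rate; a null cohort inheriting the β = 4 baseline would be
nearly event-free and uninformative.

**What the phantom does not emulate:** SPECT physics (attenuation, scatter,
reconstruction artifacts), cardiac motion, anatomical variability beyond
the ring geometry, informative censoring, and covariate-outcome
confounding (clinical covariates are independent of severity unless the
correlation knob is turned).  Passing tests therefore certify the
*method* — objective, optimization, protocol arithmetic — not clinical
performance on real scans.

## Discriminability ceilings at desk scale

For exponential event times the probability that the higher-severity member
of a pair fails first is σ(β_true·|s_i − s_j|) (logistic σ), so the
concordance of the *true* severity — the ceiling for any image-based
scorer — is E[σ(β_true·|s_i − s_j|)].  With uniform severity this is
≈ 0.62 at β_true = 1.5 and ≈ 0.73 at β_true = 4.0; no severity law on
[0, 1] exceeds 0.66 at β_true = 1.5.  Desk-scale expectations for trained
models must be read against these ceilings: with the default generator the
tiny network reaches test C ≈ 0.70–0.80 (ceiling ≈ 0.75), while at
β_true = 1.5 even a perfect scorer sits near 0.6.  The null experiment
(β_true = 0) scores a larger held-out cohort (n = 1000, ~150 events) so
that the sampling width of a chance-level C (~0.025) is small compared
with the [0.45, 0.55] acceptance band; at n = 200 the band would be missed
by sampling noise alone roughly a third of the time.

## Problem sizes

Test-suite and acceptance-script runs use the reduced 8-slice layout at
32 px, the tiny encoder, cohorts of 300 training / 200–1000 test subjects,
and 12 training epochs — sizes chosen so a full run completes on one CPU in
minutes while leaving every qualitative property (signal recovery, null
behaviour, oracle equivalences) measurable.  The 96-slice layout, larger
scales and 70-epoch protocol are exercised for contracts (shapes, layout
validation) rather than trained to convergence.

## Known limitations

* Breslow ties only; no Efron or exact methods, no time-varying covariates,
  no stratified baselines, no baseline-hazard estimation.
* The batch-restricted likelihood is a stochastic approximation of the
  full-cohort objective; no cross-batch memory bank is kept.
* BatchNorm couples subjects within a batch during training; inference uses
  running statistics and is per-subject deterministic.
* KM curves carry no confidence bands; horizon AUC is unweighted (no
  inverse-probability-of-censoring weighting).
* The numpy engine is single-threaded BLAS-bound and sized for desk-scale
  profiles, not GPU-scale training.
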