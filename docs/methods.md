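# Methods

## The measurement problem

Emotional clarity — how readily a person can identify what they are feeling
— is usually self-reported. `emaclarity` implements two *passive* indicators
computed from how people answer ordinary momentary-affect items in
ecological momentary assessment (EMA) studies, where each prompt presents a
few negative-affect (NA) and positive-affect (PA) sliders (0–100) and the
app records per-item response times (RTs):

1. **Median RT** — per prompt and valence, the median RT over the valence's
   items, multiplied by −1 so that higher = clearer.
2. **Log absolute drift rate** — from a D-diffusion item response theory
   (IRT) model of the dichotomized responses and their RTs, the occasion's
   drift-level factor score θ̂ is turned into
   `ad = mean_i |θ̂ − b_i|`, the mean absolute distance from the item
   difficulties, then log-transformed. Under the distance–difficulty
   principle, large |θ − b| means fast, decisive answers: high clarity.

Around these indicators the package provides the supporting analyses a
study of such measures needs: multilevel reliability as a function of the
number of prompts, and covariate-adjusted between-person validity testing
against trait measures.

## D-diffusion IRT model

Each EMA occasion (prompt) is an exchangeable unit with latent drift level
θ and log boundary separation log α (response caution). For item *i* with
difficulty *b_i*, the response and RT follow a two-boundary Wiener process
with unit diffusion, drift ν = θ − b_i, boundary separation α, unbiased
start, and non-decision time Ter:

* P(endorse) = 1 / (1 + exp(−α(θ − b_i))) — the absorption probability of
  the unbiased Wiener process, which is the D-diffusion choice rule;
* RT − Ter follows the defective first-passage-time density, computed with
  the classical dual series: a short-time expansion in Gaussian images and
  a long-time eigenfunction expansion. With an unbiased start the even
  long-time terms vanish. The representation switches at normalized time
  τ = t/α² = 0.35, where the truncation error of either series
  (5 image terms / 4 odd eigenterms in the fitting kernel; slightly more in
  the reference implementation) is below 1e-10, keeping the density
  continuous across the switch to ~1e-10.

**Estimation.** Marginal maximum likelihood: (θ, log α) are integrated over
a bivariate normal N((0, μ_logα), Σ) with free SDs and correlation, using
Gauss–Hermite quadrature (default 15 nodes per dimension; fitting explores
on a 7-node grid and polishes at full resolution). Optimization is
quasi-Newton (L-BFGS-B) on transformed parameters (log SDs, atanh ρ), with
three jittered starts from moment-based initial values. The quadrature is
non-adaptive, so the total log likelihood retains a per-occasion error of
order 1e-4 relative to much finer grids; doubling the nodes moves the
log likelihood by less than 1e-3 *per occasion* at the optimum.

**Identification.** The likelihood depends on θ − b_i only, so the latent
mean and the difficulties are jointly unidentified; μ_θ is fixed at 0 with
all b_i free (items answered identically by everyone get b pinned at ±4
logits with a warning). Item boundary weights are fixed at 1 by default —
four items per valence carry little information about per-item boundaries.

**Non-decision time.** Two policies:

* `occasion_min` (default): plug-in Ter = 0.95 × the minimum observed RT in
  the occasion. Cheap and always feasible, but it absorbs part of the
  decision time, biasing α̂ and the population parameters toward smaller
  values. Adequate for *scoring* (the EAP ordering of occasions is
  essentially unchanged) but not for recovering generating parameters.
* `global`: a single Ter estimated as a free bounded parameter. The upper
  bound is min(1st percentile of all RTs, 0.999 × smallest observed RT) —
  any Ter above the smallest RT has zero likelihood, so the feasibility
  bound is binding, not cosmetic. This policy recovers generating
  parameters accurately when the data share a common Ter and is what the
  parameter-recovery checks use.

**Scoring.** EAP (posterior mean) θ̂ and α̂ per occasion on the fitted
quadrature grid. A hypothetical occasion with no usable items would score
at the prior means. The clarity indicator is log(max(ad, 1e-6)); the floor
handles the measure-zero event θ̂ = b_i for a single item.

**Model checking.** Posterior-predictive RT check: occasions are resampled,
latents drawn from each occasion's posterior over the grid, Wiener first
passages sampled at those latents, and per-item observed-vs-simulated
Kolmogorov–Smirnov distances and quantile tables reported. Plugging in EAP
point estimates instead (shrunken latents) visibly under-disperses the
simulated RTs and fails its own self-consistency check, which is why the
posterior-predictive form is used.

## Preprocessing rules

* RTs < 0.2 s or > 30 s are set to missing (screening for careless or
  distracted responding); negative RTs raise — they indicate corrupt input,
  not outliers. Milliseconds on disk, seconds in memory, converted at
  ingest only.
* Dichotomization: scale-midpoint rule codes response ≥ 50 as 1; the
  person-mean rule thresholds at the person's own mean per valence (ties
  coded 1 to mirror the at-or-above midpoint convention; single-observation
  persons are flagged).
* Per-occasion medians require ≥ 2 of 4 usable item RTs — a one-item
  "median" is not a median.
* Baseline speed: per-person median RT on the non-affect activity item.
  Processing speed: per symbol-search session, median RT of accurate trials
  when ≥ 14/20 are accurate; person score is the mean of valid sessions,
  sign-flipped so higher = faster. Sessions must have exactly 20 trials.
* Time of day: the first prompt of a day is *morning*, the last *scheduled*
  prompt (by the person's 5/6-prompt schedule, answered or not) is
  *evening*, everything between *midday*.

## Reliability

One-way random-intercept decomposition (REML via statsmodels MixedLM) of
each occasion-level indicator gives between-person variance σ²_b and
within-person variance σ²_w; ICC = σ²_b/(σ²_b+σ²_w) and the
Spearman–Brown-type curve

    reliability(n) = σ²_b / (σ²_b + σ²_w / n),  n = 2..70,

from which the smallest n reaching 0.70 is read off. On balanced data REML
coincides with the ANOVA method-of-moments estimator (verified to 1e-6);
a negative between-variance is truncated at zero with a warning. Two-level
McDonald omega splits the item covariance into within (person-centered) and
between (person-means, within-attenuation removed) parts and fits each with
a one-factor minimum-residual model; between-level uniquenesses are floored
at the sampling noise of the person means (diag(S_w)/n̄) so that a null
between-person covariance yields ω_b ≈ 0 rather than a 0/0 artifact.

## Validity

Two-stage approximation to a multilevel SEM: (1) mixed-model person scores
— indicator ~ morning + evening + (1 | person), midday reference, person
score = fixed intercept + BLUP, i.e. the shrunken person mean at a midday
prompt; (2) partial Pearson correlations of person scores with traits given
person-level covariates (baseline speed, optionally processing speed), with
t-based p-values on n − 2 − k df and listwise deletion per pair. This
replaces single-stage latent-mean estimation with robust SEs; the
substitution trades exactness for testability and is exercised by the
calibration checks below rather than by reproducing any published
coefficient table. An emotional-intensity sensitivity variant adds the
centered occasion mean rating and its centered square at level 1 before
scoring (centering both keeps the reference occasion at average intensity).
Benjamini–Hochberg FDR is applied within hypothesis families — one family
per indicator × construct group (subjective well-being vs emotion
regulation). The power function for between-person correlations uses the
Fisher-z approximation with both rejection tails.

## Synthetic EMA generator

The generator emulates the study design the analyses assume: n persons ×
days × 5–6 prompts/day at 3-hour intervals (a per-person schedule, fixed
across days; ~30% of persons on the 5-prompt schedule), 4 NA + 4 PA items
(difficulties NA (−1, −0.3, 0.4, 1.1) logits, PA mirrored), a baseline
activity item, and 20-trial symbol-search sessions. Latent structure:

    θ_pt = u_p + κ_p δ_t,  δ_t ~ N(0,1);  log α_pt ~ N(log α_p, 0.15)

with u_p ~ N(0, 0.55²), κ_p lognormal(0, 0.55²), log α_p ~ N(log 2, 0.2²),
Ter_p ~ U(0.25, 0.45) s plus a lognormal baseline-speed offset shared with
the baseline item and correlated (ρ = 0.5 through a general-speed factor)
with symbol-search speed. The dispersions were set so the intraclass
correlation of the generated log absolute drift is ≈ 0.27, a typical
between-person share for occasion-level clarity indicators. κ_p is the
person's clarity scale: it widens the occasion distribution of |θ − b|,
so high-κ persons answer faster and more decisively.

RTs are Ter + Wiener first passages. The bulk generator samples first
passages by inverse-CDF on a fixed normalized-time grid (the conditional
FPT distribution depends on the parameters only through αν, so one
512-point grid serves every trial); a deliberately independent
Euler–Maruyama random-walk simulator (step 1e-4 s, numba) is kept as the
oracle that the series density and the fast sampler are tested against.
Sliders are round(100·clip(p + N(0, 0.08), 0, 1)) where p is the latent
endorsement propensity, so midpoint dichotomization recovers the latent
binary choice with high probability. Artifact injection drops whole
prompts (default rate 0.08, giving ~92% median completion) and replaces
item RTs with sub-0.2 s or 30–60 s draws (rates 0.01/0.003, ~1.3% of
observations), with provenance flags retained. Trait variables are built
from the standardized person mean of the latent log absolute drift at
exact target correlations (defaults mirror the magnitudes typical for
clarity–well-being associations, e.g. −0.27 for depression).

What the generator does **not** emulate: circadian RT trends beyond the
3-slot coding, autocorrelated affect dynamics, app/device latency,
response styles, or any direct slider–RT coupling beyond the diffusion
model of the dichotomized response. Passing recovery and calibration tests
therefore shows the estimators work under the model's own assumptions —
not that real EMA data satisfy them.

## Calibration design and problem sizes

* Parameter recovery: one MML fit on 2000 occasions × 4 items at known
  parameters (b as above, sd_θ = 1, μ_logα = log 2, Ter = 0.35, global-Ter
  policy). Checked: item-difficulty RMSE < 0.15, |ŝd_θ − 1| < 0.1, EAP–truth
  correlation > 0.6.
* Type-I error: 500 replicates of a 50-person × 20-occasion null study
  (trait correlations all zero), each run through RT filtering, indicator
  construction, EAP scoring, mixed-model person scoring and the adjusted
  validity grid; the pooled rejection rate at α = .05 must sit within 3
  binomial SEs of .05. Within replicates, EAP scoring uses the known
  generating parameters — the MML fit is exercised by the recovery check,
  and refitting 500 times would add cost without changing what the check
  tests (the calibration of the scoring-and-correlation stages).
* Coverage: 200 person-level replicates at n = 196 with baseline-speed
  confounding of both indicator and trait; 95% Fisher-z CIs of the adjusted
  correlation must cover the generating −0.27 in ≥ 90% of replicates.

## Numerical choices

* Series truncation 1e-10; density floored at 1e-300 before logs.
* Quadrature 15×15 (scoring at 11 nodes inside the replicated calibration).
* Optimizer convergence: L-BFGS-B success or max |gradient| < 1e-3;
  non-convergence flags the result and is never silent.
* log absolute drift floor 1e-6; covariance smoothing by eigenvalue
  clipping at 1e-10 for non-PSD level matrices.
* Partial correlations with zero residual variance after adjustment return
  r = 0, p = 1 with a warning (a trait exactly explained by the covariates
  has no testable residual association); constant inputs raise instead.

## Known limitations

* The occasion-min Ter plug-in biases boundary/population estimates
  downward; use the global policy when generating-parameter scale matters.
* The two-stage validity procedure approximates latent-mean SEM; with few
  occasions per person, shrinkage attenuates between-person correlations
  relative to the latent estimand.
* One model fit per valence pools occasions as exchangeable; person-level
  clustering enters only downstream (reliability/validity stages), not the
  diffusion likelihood.
* The reliability arithmetic from rounded reference variance components
  reproduces the prompts-needed value of 7 for drift indicators, but the
  analogous RT-row components (0.70/1.95) imply ≥ 7 prompts, which cannot
  be reconciled with the reported value of 5 for that indicator — rounded
  components cannot reconstruct it, and no attempt is made to guess the
  unrounded ones.
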