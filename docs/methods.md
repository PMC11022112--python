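# Methods

## The scientific question and the model

Trauma-exposed people with probable PTSD (pPTSD) report emotional numbing
and hyperreactivity at once. One resolution is that their transition from a
neutral to a negative emotional state is *faster* — not larger — than in
trauma-exposed controls (TEC). The package models continuous
visual-analog-scale (VAS, 0–1) valence ratings of images with normative
valence `x` (1–9 scale, most negative ≈ 1.33 to neutral = 5) as a
5-parameter logistic (5-PL) curve per participant:

    f(x) = d + (a − d) / (1 + (x/c)^b)^g

with lower asymptote `a` (rating of the most negative images), Hill slope
`b` (speed of the neutral-to-negative transition — the quantity of
interest), inflection point `c`, upper asymptote `d` (rating of neutral
images), and asymmetry `g`. A hierarchical Bayesian model ties participant
parameters to group-level means; groups are compared by subtracting the
pPTSD posterior from the TEC posterior and checking whether 0 lies outside
the 89% highest-posterior-density (HPD) interval ("robust" difference). A
linear model `f(x) = b·x + a` is the comparison baseline, judged by
PSIS-LOO. An extension replaces the participant slope by
`B_i = numbing_z_i · EN + b_i` (fixed slope, random intercept) to test
whether emotional numbing (PCL-5 items 12–14, z-scored) is associated with
the transition speed; further variants add z-scored age and a
numbing × age interaction.

## Priors

Participant level: `a ~ Beta(α₁, α₂)`; `b ~ N(μ_b, 1) [0.5, ∞)`;
`c ~ N(μ_c, 1) [0.5, 5]`; `d ~ N(μ_d, 1) [0.5, ∞)`; `g ~ N(μ_g, 1)
[0.8, ∞)`. Group level: `α₁ ~ N(2, 1) [1, ∞)`; `α₂ ~ N(10, 1)`;
`μ_b ~ N(2, 1) [1, ∞)`; `μ_c ~ N(2, 1) [0.5, ∞)`; `μ_d ~ N(2, 1) [0, ∞)`;
`μ_g ~ N(4, 1) [1, ∞)`. Linear model: `a ~ N(0, 0.2) [0, ∞)`,
`b ~ N(0, 0.5) [0, ∞)` at the group level, with the same
participant-around-group-mean structure (unit SD) as the 5-PL so the LOO
comparison is like-for-like. `EN`, `AGE`, `INT ~ N(0, 1)`. All constants
live in `valtrans.model.PRIOR_CONSTANTS` and can be overridden through the
`priors` config block.

Notes on deliberate asymmetries, kept exactly as specified: the
participant-level lower bounds for `d` (0.5) and `g` (0.8) differ from the
group-level bounds for `μ_d` (0) and `μ_g` (1); `α₂`'s prior is an
untruncated Normal(10, 1) with a hard positivity guard in the log density
(prior mass below 0 is ≈ 7.6e−24, so the guard is effectively never
active); `d` has no upper bound even though ratings live in [0, 1].

The observation model is unstated in the source description; we use
`y ~ Normal(f(x), σ)` with `σ ~ HalfNormal(0.2)` shared across
participants — the minimal continuous-response likelihood on the VAS scale.
Participant-level SDs are fixed at 1 as the printed notation implies, with
one exception: the EN-family models estimate the between-participant slope
SD (`σ_b ~ HalfNormal(1)`, flag `estimate_slope_sd`). With the SD fixed at
1 the EN coefficient's posterior SD is `1/√(n+1)` regardless of the true
residual scatter (≈ 0.07 at 200 participants), which makes covariate
recovery impossible at desk-scale sample sizes; estimating the residual
scatter is standard for such random-intercept regressions and restores the
expected `sd_resid/√n` behaviour. The flag accepts either choice.

## Inference

No probabilistic-programming framework is part of the package's
dependency set; the models are few and fixed, so the package implements
the No-U-Turn Sampler directly with analytic gradients of the
unconstrained-space log posterior (lower-bounded parameters via
`L + exp(t)`; `a` and `c` via logistic maps; Jacobians included). A
compiled (numba) kernel and a pure numpy/scipy reference implementation of
each density are asserted equal in the test suite, and gradients are
checked against central finite differences.

The sampler follows the standard design: multinomial sampling over the
leapfrog trajectory with biased progressive selection, doubling until the
generalized U-turn criterion or a divergence (energy error > 1000),
dual-averaging step-size adaptation to a target acceptance statistic
(default 0.8), and Stan-style expanding adaptation windows. The inverse
mass matrix is block-diagonal: one dense block per participant's five
curve parameters (their posterior rides a strong local ridge — inflection
vs asymmetry vs slope trade-offs), one dense block for the group-level
scalars, diagonal elsewhere, with an optional low-rank correction from the
leading principal components of the block-whitened tuning draws to capture
collective cross-participant modes. Equal-sized blocks are batched, so the
metric costs a few einsums per leapfrog step. Sampler defaults mirror the
published run: 1000 draws, 1000 tuning steps, 4 chains, no thinning.

Convergence is judged by split-chain rank-normalized R-hat (< 1.01) and
bulk effective sample size (> 1000), computed by arviz; `fit` warns when a
fit misses that bar and when post-warmup divergences exceed 1% of draws.

Known geometry limitation: with few participants the asymmetry `g` is
weakly identified per participant, and a *curved* collective mode — all
participants' `(c, g)` sliding along their shared ridge together with
`μ_c` and `μ_g` — dominates the autocorrelation time of those two
hyperparameters. No linear metric removes a curved ridge; the block +
low-rank metric shortens it but the hypermean ESS per draw remains the
binding constraint on convergence at small n (a metric built from an
independent long pilot posterior caps their efficiency near 11% of
draws, so at 4 × 1000 draws their bulk ESS tops out in the hundreds and
their split R-hat hovers around 1.01–1.03). The effect weakens as the
number of participants or the true asymmetry grows; at the study's
sample size it would not bind.

## Group comparison and HPD

The contrast is literal: TEC draws minus pPTSD draws, paired by flattened
(chain, draw) index; the fits are independent, so pairing is immaterial
(asserted in tests). Unequal draw counts are reconciled by seeded
subsampling without replacement. The HPD is the shortest contiguous window
of the sorted draws containing ⌈mass·n⌉ of them, ties broken toward the
lowest start; for symmetric unimodal posteriors it matches the central
interval. The interval's *width* converges fast, while the endpoint
*positions* of any shortest-window estimator jitter at O(n^−1/3)
(SD ≈ 0.013 at 10⁶ standard-normal draws); tests are calibrated
accordingly.

## Model comparison

PSIS-LOO (expected log pointwise predictive density) via `arviz.loo` from
the stored pointwise log-likelihood draws; observations with Pareto
k > 0.7 are reported, not refit. Tables carry rank, loo, p_loo, d_loo,
weight, se; weights use stacking by default (pseudo-BMA and BB-pseudo-BMA
available — the tie case `compare(m, m)` yields 0.5/0.5 under pseudo-BMA).
Comparisons are run per group, driven by the screening labels.

## Screening

PCL-5: total 0–80; probable PTSD requires total > 33 *and* DSM-5 cluster
endorsement (item ≥ 2 counts as endorsed): ≥1 of items 1–5 (intrusion),
≥1 of 6–7 (avoidance), ≥2 of 8–14 (cognition/mood), ≥2 of 15–20
(arousal). Emotional numbing is items 12–14 (0–12). The z-transform uses
the population-SD convention (divisor n; `ddof` configurable).

Rating quality control: norms (1–9) are mapped onto the VAS by
`m → (m−1)/8`, `s → s/8` (order-preserving affine map; the 3-SD rule is
equivariant under it); a participant deviating more than 3 rescaled SDs
from the rescaled norm mean on strictly more than 2 images is excluded.
Positive images (norm mean > 5) are shown to reduce negativity bias and
dropped before modelling.

## Synthetic data

The generator emulates the study design: 35 image norms evenly spaced
(with small jitter, endpoints exact) from 1.33 to 5.0 plus 5 positive
fillers in [5.63, 7.09], norm SDs uniform on [0.8, 1.6]; two groups of
participants with PCL-5 vectors *constructed* to satisfy or fail the
diagnosis rule exactly (group totals ≈ 46.5/17.8, numbing ≈ 7.94/2.95,
ages ≈ 36.1/41.5, matching the study's sample description); curve
parameters drawn from the model's own truncated population distributions
with true group slope means 1.2 (TEC) and 1.45 (pPTSD); the participant
slope is `B_i = 0.1 · numbing_z_i + b_i` by default, so the groups also
differ through their numbing distributions — as the study's account
implies; ratings are `clamp(f(x) + N(0, 0.05), 0, 1)` (mild boundary
censoring, negligible at that noise level). Ground truth is returned
separately and never read by the inference stages.

Between-participant SDs: `b`, `c` and `g` default to the model-matched
values (`sd_b = 1.0`; `sd_c`, `sd_g` configurable, defaults 0.3) — for the
slope the matched value is essential, because the group-level `μ_b`
estimand equals the generating `μ_b` only when the generating population
is the model's own truncated normal; with a much tighter population the
truncated-mean inversion `E[b] = μ + φ/Φ` places the estimand near or
below the hyperprior bound and the contrast collapses. `d` cannot be
matched: a unit SD would put upper asymptotes far above the VAS range, so
`sd_d = 0.04` around 0.58. A tight `d` population just above its
truncation bound (0.5) makes `μ_d` pile at its own bound (0) — the
truncated-normal location likelihood is maximized far below the bound for
observations hugging it — so `μ_d` is reported but not interpretable as a
mean rating; the group *difference* in `d` remains well-defined and null.

The default true asymmetry is `μ_g = 3.5` (SD 0.3): the study's prior for
`μ_g` centres on 4 — the only available evidence about the magnitude of
asymmetry in the real ratings — and simulations here confirm that clearly
asymmetric curves are what make `g` (and with it the `c`–`g` geometry)
identifiable at desk-scale sample sizes.

What the generator does *not* emulate: trauma-specific image content,
arousal ratings, reaction times, attention-check behaviour, item-level
PCL-5 responses beyond the constraints above (items are filled by a
randomized constructive procedure, not an IRT model), and any
group-by-image interaction on the positive fillers. Passing tests
therefore demonstrate correct recovery under the model's own assumptions,
not robustness to the many ways real rating data violate them.

## Attenuation of the numbing coefficient under rating noise

A finding from the recovery simulations worth stating on its own: at the
study's rating-noise level (SD 0.05) the EN coefficient is systematically
*attenuated* — synthetic data generated with a true coefficient of 0.10
typically yield posteriors centred near 0.04–0.06, while at noise SD 0.005
the fit recovers 0.10 essentially exactly. The mechanism is per-participant
identifiability, not estimation error: with noisy ratings, the likelihood
cannot fully separate a numbing-linked change in the Hill slope from a
compensating change in the asymmetry or inflection parameters, so part of
the association is re-attributed to them. Because this ambiguity lives at
the level of each participant's 35-point curve, it does **not** shrink as
participants are added. The association's *existence* (89% HPD excluding
zero) is detected reliably; its magnitude should be read as a lower bound.
The same caveat applies, in principle, to magnitudes estimated from real
data with this model family.

## Problem sizes used in the checks

The automated checks run at deliberately reduced scale, chosen by power
analysis rather than by mimicking the study's n≈1380; the 35-image
stimulus design is kept everywhere, because fewer images soften the
slope/inflection/asymmetry likelihood ridge and degrade every downstream
estimate. The convergence check fits 40 participants per group at the
full published sampler settings. The group-contrast check uses 250 per
group (effect, 5 seeds) and 20 per group (null, 10 seeds) at reduced
draws: the naive power calculation (μ_b difference posterior SD ≈ √(2/n)
under the unit participant-level SD) is optimistic here, because near the
hyperprior's truncation bound the group-mean estimand amplifies
dataset-level sampling noise, so the effect run needs the larger n; the
null false-positive rate is the ~11% HPD miscoverage by construction at
any n. The numbing-association
check uses 100 per group with residual slope SD 0.25 (the expected
coefficient SE ≈ 0.25/√200 makes a 0.1 effect detectable, subject to the
attenuation above); model comparison runs at 20 per group. The pipeline
smoke test uses toy sizes throughout.
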