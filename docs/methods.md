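# Methods

## Performance model

A 2IFC trial is correct with probability

ψ(x) = γ + (1 − γ − λ) · F(x; α, β),  F(x; α, β) = 1/(1 + exp(−β(x − α))),

where `x` is expression intensity in percent (`100 − dilution`). The model
assumes stationarity (no learning, fatigue or sequential dependence),
independence across trials, and a stimulus-independent guess rate. Fitting
is done in intensity space so performance increases with `x` and β > 0
always; every user-facing threshold is reported on the dilution scale
(`100 − x`), where larger = more sensitive. The conversion lives in one
place (`intensity_from_dilution` / `threshold_from_params`) and is tested
in both directions.

### Parameters

| parameter | units | default | notes |
|---|---|---|---|
| α | % intensity | free | threshold location; ψ(α) = 0.75 under the defaults |
| β | per % intensity | free | logistic slope; 0.2–0.4 is typical for morph continua at these trial counts |
| γ | probability | 0.5 | 2IFC chance; fixed, not estimated |
| λ | probability | 0.0 | lapse rate; fixed, configurable — with several hundred trials per level and 7 levels, freeing λ mostly trades bias for variance |
| criterion | probability | 0.75 | halfway between the asymptotes under the defaults, so the threshold is exactly `100 − α` |

With γ = 0.5, λ = 0 the function runs from 50 % to 100 % and crosses 75 %
at α; ψ evaluated at the returned threshold reproduces the criterion to
numerical precision (a tested identity).

## Maximum-likelihood fitting

The exact binomial negative log-likelihood over levels is minimised by
L-BFGS-B with the analytic gradient, from a small multi-start grid
(default 7 starts): α candidates at the interpolated mid-performance
crossing plus the range anchors of the presented levels, β candidates
log-spaced over 0.05–1.0. Box constraints are α ∈ [−50, 150] %
(well outside any presentable level) and β ∈ [10⁻³, 10].

Numerical choices:

- ψ is clipped to [10⁻¹⁰, 1 − 10⁻¹⁰] inside logarithms so λ = 0 with an
  error at near-ceiling levels stays finite; gradients do not propagate
  through the clip (flat where clipped).
- Ties across starts resolve to the lowest NLL found; fitting is
  invariant to the order of levels because data are sorted at
  construction.
- A fit is declared **unfittable** (flag, not exception) when fewer than
  2 levels carry trials, when the observed proportion correct never
  reaches the criterion at any level (the curve cannot be pinned to the
  criterion — the situation that arises when every offered dilution is
  still too strong), or when the optimum sits on a box bound. Threshold
  extraction refuses unfittable fits.
- Binned counts are normally integers but nonnegative reals are accepted,
  so noiseless expected-count data can be fit in generate-and-refit
  checks without rounding error.

A parametric-bootstrap percentile CI for the threshold
(`bootstrap_threshold_ci`) supports coverage checking.

## Model comparison (1PF vs 2PF)

The null model (1PF) shares one (α, β) across both conditions (summed
log-likelihood); the alternative (2PF) fits each condition separately.
Both use the same fixed γ, λ for observed and simulated fits. The test:

1. Fit 2PF and 1PF to the observed pair; `LR = exp(ll₁ − ll₂)`,
   `TLR = −2(ll₁ − ll₂)`. If optimisation noise makes ll₁ exceed ll₂,
   the free fits are retried with a larger start grid before an
   internal-consistency error is raised.
2. For each of B replicates (default 10,000), draw binomial counts for
   *both* conditions from the fitted 1PF at each condition's observed
   levels and trial counts, refit both models, and record the simulated
   LR. The null parameters are the natural generating source: under H₀
   both conditions share one function, and the joint fit is its ML
   estimate.
3. `p = #{LR_sim < LR_obs} / B`, strict inequality (ties favour the
   null), no continuity correction — so 499/10,000 gives p = .0499 and
   500/10,000 gives exactly .05. p = 0 is possible and is rendered as
   "p < 1/B" in text output.

Bootstrap refits use a damped Fisher-scoring iteration started at the
generating (null) parameters — the expected-information direction is a
descent direction, and a halving line search keeps it monotone — with
fallback to the multi-start quasi-Newton path whenever scoring fails to
converge or the nesting inequality ll₁ ≤ ll₂ is violated. A replicate
that still fails after jittered restarts is redrawn (counted; > 1 %
redraws warns). The unfittable screening rule applies to observed data
only, not to simulated replicates: redrawing replicates that dip below
criterion would bias the null distribution.

Calibration is verified empirically: over 200 truly-null pairs (240
trials/level, 7 levels) the rejection rate at nominal .05 falls within
[0.02, 0.10], and the median p is ≈ 0.5.

## Synthetic observers

The generator emulates the canonical study designs:

- **Schedule**: 7 dilution levels × 6 faces × 40 repeats = 1,680 trials,
  240 per level; complete shuffled passes over the level × face set (no
  pair shown n+1 times before all shown n times); test-first probability
  exactly 0.5. Emotions are simulated as separate blocks.
- **exp1 preset**: 11 observers; true happy thresholds ~ N(92, 1.89²) and
  fear ~ N(86, 4.08²) on the dilution scale (between-subject SD taken as
  SE·√n from the group values 92 ± 0.57 and 86 ± 1.23), common slope
  β = 0.3. Presented levels are tailored per observer: seven 2 %-ladder
  dilutions at offsets (−12 … +6) around the true threshold, shifted as a
  block to stay within [2, 98] — four easier and three harder than
  threshold, spanning ≈ 99 % down to ≈ 53 % correct.
- Other presets: `retest` (2 sessions), `faces` (additive per-face
  threshold offsets, SD 2 dilution points, centred — slopes shared, the
  simplest mechanism for face heterogeneity), `durations`/`sizes`
  (metadata variants with modest threshold shifts at short durations /
  small images), `software` (9 observers, 1 %-step ladder, happy 93 ± 0.91,
  fear 86 ± 1.21).
- At dilution 100 the test and comparison stimuli are identical, so the
  simulator returns exactly chance (0.5) rather than the model value
  γ + (1−γ−λ)F(0): discrimination is undefined for identical stimuli.
- One RNG stream per participant (derived from the master seed and the
  participant index), so adding participants never perturbs existing
  ones; everything is bit-reproducible for a fixed seed.

What the generator does **not** emulate: reaction times, lapses/attention
drift (λ = 0 truth), learning across sessions, interleaved emotions,
stimulus-specific difficulty beyond additive face offsets, and any image
properties. Passing tests therefore demonstrate the statistical pipeline
is correct and calibrated for the assumed response model — not that real
observers satisfy that model.

## Group analysis

The group curve averages each participant's *fitted* percent correct at
a fixed dilution set (68, 80, 86, 90, 94, 96, 98) — not pooled raw
trials — so observers measured on different tailored ladders share an
axis; error bars are across-participant SEM (SD/√n, ddof = 1). The group
comparison is a two-sided paired t test on unrounded dilution thresholds
with df = n − 1 and effect size r = √(t²/(t² + df)) (this form reproduces
the conventional printed effect sizes for these designs). Zero-variance
differences are defined explicitly (t = 0, p = 1, r = 0 for identical
vectors). Participants unfittable in either compared condition are
excluded from group statistics with enumerated reasons.

## Problem sizes

Defaults follow the measured designs (B = 10,000 bootstrap simulations;
240 trials per level). The test suite exercises the same code at reduced
Monte-Carlo scale chosen for desk turnaround: 200–500 inner simulations
per test, 6–20 outer replicates for power/recovery checks, and 200 outer
nulls × 500 inner simulations for type-I calibration. The acceptance
script uses 20 independent studies of 11 observers for group recovery and
≥ 10,000 trials for the chance-floor and interval-balance checks.

## Design choices and limitations

- The package is organised around scikit-learn-style estimators
  (`PsychometricCurve`, `PsychometricLRTest`) with functional wrappers;
  fitted attributes carry trailing underscores and `get_params`/`clone`
  work as usual.
- Only the logistic form is provided (no Weibull/Gumbel), γ and λ are
  never estimated, and the comparison is limited to two conditions with
  both threshold and slope shared under the null; threshold-only
  constrained variants and asymptotic χ² p values are out of scope.
- The bootstrap p value is exact only up to Monte-Carlo error ~√(p(1−p)/B);
  at B = 10,000 the .05 boundary has SE ≈ 0.002.
- Thresholds are printed to 1 decimal place in reports; internal values
  are never rounded before statistics.
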