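# Methods

This note records the statistical models implemented in `lifemet`, the
design choices made where several readings were defensible, what the
synthetic-cohort generator does and does not emulate, and the numerical
conventions that affect results.

## Healthy Lifestyle Score

The score awards one point per component: aMED ≥ 5 (the alcohol-free 0–8
alternate Mediterranean diet score; the fixed threshold corresponds to the
top ~40% of a typical distribution, and an empirical-quantile threshold is
available as an option), alcohol in [5, 15] g/day for women and [5, 30]
g/day for men, leisure-time moderate-or-vigorous activity ≥ 600
MET-min/week, BMI in [18.5, 25.0) kg/m², and never smoking.  All interval
rules are closed except the BMI upper bound, which is half-open so that
values between 24.9 and 25 do not fall into a gap.  aMED items score 1 at
or above the cohort median (healthy items) or strictly below it
(red/processed meat); values exactly at the median count as meeting the
healthy cut-off.  Participants outside the sex-specific energy-intake
ranges (500–3500 kcal/day women, 800–4000 kcal/day men, inclusive) are
excluded upstream of scoring.

Sensitivity variants: (a) the alcohol item is kept inside the aMED (0–9);
its rule is the same sex-specific moderate range as the HLS alcohol
component, a choice this package makes because the source instrument's
alcohol cut-offs differ across publications; (b) the alcohol component is
dropped from both scores (total 0–4); (c) non-drinkers (exactly 0 g/day)
also receive the alcohol point.

## Fasting adjustment and weighted quantiles

Each metabolite is regressed on fasting hours (OLS with intercept,
unweighted — the adjustment is a measurement correction, not a population
estimate; a weighted switch exists) and replaced by residual + sample
mean.  The operation preserves column means, removes the fasting
correlation to numerical precision, and is idempotent.

Weighted quantiles use a step-function inversion of cumulative weights:
sorted point k with weight w_k occupies the flat interval
[C_{k−1}, C_{k−1} + max(w_k − 1, 0)]/(S − 1) and the quantile function
interpolates linearly between intervals.  This reduces exactly to the
linear-interpolation (type-7) convention at equal weights and exactly to
row duplication for integer weights — the two properties the rest of the
package relies on.  The p90 − p10 span from these quantiles is the
contrast unit for metabolite rate differences.

## Survey-weighted regression

The cohort's sampling design is emulated as independent per-participant
weights (lognormal, normalised to mean 1) without strata or PSUs, so all
variances are weight-aware sandwich estimators,
(X′WX)⁻¹ [Σ w_i² s_i s_i′] (X′WX)⁻¹, consistent under independent weighted
sampling; no finite-population or linearisation corrections are applied.
Estimates are invariant to rescaling all weights.  Two-sided p-values use
the normal reference for sandwich z statistics (large-sample), not t.
q-values are computed with the null-proportion tuning parameter λ = 0,
under which π₀ = 1 and the q-values coincide with Benjamini–Hochberg
step-up adjusted p-values; the screen selects at q ≤ 0.025.  Screening
operates on the fasting-adjusted concentration scale with an optional
z-score switch.

## Additive hazards (Lin–Ying)

The reported rate differences come from the constant-coefficient special
case of the additive hazards model, because a single RD per exposure is
the estimand; the nonparametric cumulative-coefficient estimator is
available as a diagnostic through lifelines.  With time-fixed covariates
the estimating equation reduces to reverse cumulative sums over the sorted
follow-up times, making one fit O(n log n + n p²) — cheap enough for
bootstrap and jackknife loops.  Ties are handled exactly (the risk set at
a tied time contains all tied subjects); an earlier jitter-based ordering
was abandoned because it biases within-tie risk sets.  All subjects enter
at baseline (no left truncation), and survey weights enter both the
estimating equation and the sandwich variance.  With a single binary
covariate and no censoring the estimator converges to the crude difference
in events per person-time between groups but does not equal it at finite
samples — the nonparametric baseline keeps risk-set centring in the
equation.

## BKMR-P

The probit kernel machine model places a Gaussian-process surface h over
the standardized metabolite mixture, K_ij = exp(−Σ_m r_m (z_im − z_jm)²),
with spike-slab selection δ_m ~ Bernoulli(π) and, given inclusion, a
Gamma(2, 0.05) slab on r_m (hard numerical cap at 10).  The slab's shape
matters more than usual here: as r_m → 0 an active component degenerates
into a shared intercept, and as r_m grows the kernel tends to the identity
so the component becomes a pure variance inflation — and because the
probit latent scale is unidentified, variance inflation is invisible to
the likelihood.  A flat slab therefore pins every inclusion probability at
its prior; the Gamma(2,·) slab concentrates prior mass where a component
must express itself as correlation structure that the outcome's sign
pattern can judge.  π defaults to 0.25, reflecting the sparse-mixture
setting in which the method is used.

Sampling follows the marginalised construction: h is integrated out, so
z* ~ N(Xβ, I + λK) truncated coordinate-wise by the outcome.  The sampler
alternates a log-random-walk Metropolis step on λ (Gamma(1, 1) prior), one
Metropolis birth/death/jitter move per iteration on a randomly chosen
(δ_m, r_m) pair (birth proposals mix a Gamma(2, 0.05) draw with a
Uniform(0, 10) draw so death moves stay reversible from any active r), a
numba-compiled coordinate Gibbs scan of the truncated latents (inverse-CDF
sampling in tail-safe form with an AS241 normal quantile), and a conjugate
GLS draw of β (flat prior).  The current kernel matrix is cached and
updated multiplicatively per component move; the precision matrix is
refreshed at most once per iteration.  Chains are bit-reproducible given
the seed.  h is drawn from its Gaussian conditional only for response
summaries (overall-mixture contrasts and univariate curves).  With no
active component the model reduces exactly to Albert–Chib Bayesian probit
on the confounders, which the tests verify against a maximum-likelihood
probit fit.

Person-time handling: the binary incident indicator over the
administratively censored window is modelled directly.  Follow-up time
must *not* be entered as a covariate — under administrative censoring the
event time is part of the outcome, and conditioning on it quasi-separates
the probit fit (verified empirically: every PIP collapses).  A case-base
style risk-time subsampling variant was considered as an alternative
reading of time-to-event adaptation and is left out of scope; with ~10%
uniform dropout the indicator misclassification is small.

Exchangeability of metabolite columns holds in distribution (the kernel
and priors are symmetric), not path-wise under a shared RNG stream.

## Mediation and decomposition

Percent explained is (1 − RD_adj/RD_ref) × 100, unclamped, with BCa
bootstrap intervals from participant-level resampling carrying weights;
acceleration uses the participant jackknife, or a grouped delete-block
jackknife (default 50 blocks in the pipeline) when n makes the full
jackknife expensive.  With zero bias correction and acceleration the
interval reduces exactly to the percentile interval.

Natural indirect effects use the product of coefficients: α from the
weighted linear model of the mediator on the HLS (adjusted for covariates
and the other relevant metabolites) and θ from the additive-hazards
outcome model containing all relevant metabolites.  The joint covariance
of (α, θ) is block-diagonal across the two fits (fits on the same data
treated as independent blocks — the convention of the product-of-
coefficients literature, and a documented limitation).  The relative
mediated effect divides each NIE by the HLS rate difference of the
*reference* model (no metabolites): with independent mediators this makes
the relative effects sum to the group percent explained, which is the
consistency property the package checks.  Dividing instead by the
partially adjusted RD (the other reading of "before adding the specific
metabolite") breaks that additivity even in truth — with three equal
mediators each carrying 1/6 of the total effect, the per-mediator ratio
would be 1/4 each and the sum 75% against a group percent of 50%.

No exposure–mediator interactions are modelled, matching the
product-of-coefficients estimand.

## Synthetic-cohort generator

The generator emulates a population-based cohort of ~1016 adults:
lifestyle components drawn with mild positive dependence through one
latent healthy-behaviour factor and calibrated so the integer HLS spans
0–5 with median 2; 49 standardized metabolites in 7 biological groups
(17 lipoprotein, 12 amino acid, 6 fatty acid, 2 fluid balance, 6 energy,
5 bacterial co-metabolism, 1 phosphoethanolamine) with block
compound-symmetric correlation (ρ = 0.3 by default) and a mean shift per
HLS point; fasting times uniform on 0–17 h with a small linear leakage
into the raw metabolite columns; survey weights lognormal with mean 1;
~9% prevalent diabetes (rarer at high HLS) and ~10% lost to follow-up.

Event times are exponential given a constant additive hazard
λ_i = max(0, a₀ + a₁·HLS_i + Σ_m c_m M_im), administratively censored at
14 years.  The intercept is calibrated analytically so the mean generated
hazard equals the target incidence (40/10,000 person-years by default)
given the drawn HLS and metabolites.  Hazards are clipped at zero per
participant; configurations in which more than 5% of participants would
clip are rejected, because clipping distorts the analytic ground truth:
the NIE through metabolite m is β_m·c_m, the total RD is a₁ + Σ β_m c_m,
and the true percent explained is their ratio × 100.

Presets: `null` (all effects zero), `hls_only` (a₁ = −9/10,000 PY per
point), `mediated` (total RD −8/10,000 PY per point, half transmitted
through three planted mediators — a bacterial co-metabolism analogue, a
medium-HDL analogue, and a small-LDL analogue with the opposite signs —
with ρ = 0 so the mediators are independent, the regime in which the
consistency property holds), and `mixture_sparse` (n = 400, 20
metabolites, 3 active).  The sparse preset emulates an *enriched
high-risk* subcohort: cumulative 14-year incidence near 40% (comparable to
progression in impaired-glucose-tolerance cohorts) with |c_m| = 0.011 per
SD for the actives — the strongest signal the hazard-positivity rejection
rule permits with seed-to-seed margin.  At the population-typical
40/10,000 PY rate, a 400-participant cohort carries ~20 events and no
selection method can flag three metabolites reliably; the enrichment is
what makes the desk-scale scenario informative rather than vacuous.

What the generator does not emulate: NMR spectra or lipoprotein
deconvolution (metabolites are generated at the concentration level),
geographic or clustered sampling structure, strata/PSUs (hence no
linearised survey variance), competing risks, or time-varying covariates.
Passing recovery tests on these cohorts therefore demonstrates correctness
of the estimators under independent weighted sampling and additive-hazard
truth, not robustness to design features the generator omits.

## Problem sizes used in the test suite

Recovery tests run at the scale at which each property is informative:
Lin–Ying recovery at n = 20,000 over 100 seeds; kernel-machine selection
at the sparse preset's n = 400 with 4,000 iterations over 10 seeds;
mediation coverage and consistency at n = 6,000 over 20 runs with B = 500
bootstrap replicates and a 50-block jackknife (the default 1,016-
participant scale yields ~30 events, at which a ratio of rate differences
is too noisy for a meaningful recovery assertion — as the wide intervals
of such decompositions in comparably sized real cohorts attest).

## Known limitations

* The percent-explained decomposition is a ratio of estimated rate
  differences; at realistic event counts its sampling distribution is
  heavy-tailed and the BCa intervals are wide and can be unstable in
  bootstrap resamples with very few events.
* PIPs depend on the slab and inclusion priors; the defaults are tuned for
  sparse mixtures of ~20–50 standardized exposures at a few hundred
  subjects, and should be revisited for other regimes.
* Cross-fit covariance between mediator and outcome models is ignored in
  the NIE resampling intervals.
* The survey machinery assumes independent weights; clustered or
  stratified designs need design-based variance estimation that this
  package deliberately does not implement.
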