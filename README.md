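# lifemet

Healthy-lifestyle scores, plasma NMR metabolomics and incident type 2
diabetes: a tested implementation of the full analysis chain linking a
composite lifestyle measure to metabolite profiles and long-term diabetes
risk, together with a synthetic-cohort generator whose ground truth makes
every stage testable without access to restricted cohort data.

## Who this is for

Epidemiologists and biostatisticians analysing prospective cohorts with a
baseline metabolomic panel: the package covers score construction,
metabolome-wide screening under survey weights, absolute- and
relative-scale survival modelling, Bayesian joint selection of correlated
metabolites, and the mediation arithmetic that turns those fits into a
statement of how much of a lifestyle effect the metabolome explains.

## The models

**Healthy Lifestyle Score (HLS).** Five binary adherence components —
diet (alternate Mediterranean diet score aMED ≥ 5 on the 0–8 alcohol-free
scale), moderate alcohol (5–15 g/day women, 5–30 g/day men), leisure-time
physical activity (≥ 600 MET-min/week), BMI in [18.5, 25) kg/m², never
smoking — summed to 0–5 and categorised low (0–1), medium (2), high (3–5).

**Metabolome-wide screen.** Per metabolite, a survey-weighted linear model
of the fasting-adjusted concentration on the HLS with weight-aware
sandwich variance; false-discovery control at q ≤ 0.025 with q-values at
λ = 0 (equivalently Benjamini–Hochberg adjusted p-values).

**Survival models.** Rate ratios from weighted Poisson regression with a
log person-years offset, RR = exp(β); rate differences from the Lin–Ying
additive hazards model λ_i(t) = λ0(t) + β′Z_i, whose constant coefficients
solve a closed-form estimating equation and are reported per 10,000
person-years, rescaled to the p90 − p10 span of each metabolite.

**BKMR-P.** Probit Bayesian kernel machine regression: the incident-event
indicator follows a probit model whose latent mean carries a Gaussian-
process surface over the metabolite mixture with kernel
K_ij = exp(−Σ_m r_m (z_im − z_jm)²) and spike-slab selection on each
relevance r_m; posterior inclusion probabilities (PIPs) above 0.20 flag
relevant metabolites.

**Mediation.** Percent explained = (1 − RD_adjusted/RD_reference) × 100
with BCa bootstrap intervals; per-mediator natural indirect effects by the
product of coefficients (HLS→metabolite × metabolite→hazard) with
multivariate-normal resampling intervals; and the consistency check that
summed relative indirect effects match the group decomposition when
mediators are independent.

## Worked example

```python
import numpy as np
from lifemet import (CovariateSpec, generate_cohort, scenario_presets,
                     fasting_adjust, MetaboliteMatrix)
from lifemet.additive_hazard import hls_rd
from lifemet.mediation import decompose_by_group

cfg = scenario_presets("mediated", seed=7, n_participants=6000)  # true percent = 50
part, mat, outc, truth = generate_cohort(cfg)
keep = ((outc.prevalent_diabetes == 0) & (outc.lost_to_follow_up == 0)).to_numpy()
part, outc = part.loc[keep].reset_index(drop=True), outc.loc[keep].reset_index(drop=True)
adj = fasting_adjust(
    MetaboliteMatrix(values=mat.values.loc[keep].reset_index(drop=True),
                     groups=mat.groups),
    part["fasting_hours"].to_numpy())

spec = CovariateSpec("M2")
res, rds = hls_rd(outc.follow_up_years, outc.incident_diabetes,
                  part.hls_total, part, spec, part.weight)
print(f"RD per HLS point: {rds[0].rd:.2f} "
      f"({rds[0].ci[0]:.2f}, {rds[0].ci[1]:.2f}) per 10,000 PY")

mediators = [m for m, t in zip(adj.names, truth.true_hazard_coefs) if t != 0]
grp = decompose_by_group(outc.follow_up_years, outc.incident_diabetes,
                         part.hls_total, {"relevant": adj.values[mediators]},
                         part, spec, part.weight, B=500, seed=1, jackknife=50)[0]
print(f"percent explained by planted mediators: {grp.percent_explained:.1f}% "
      f"(95% BCa {grp.ci[0]:.1f}, {grp.ci[1]:.1f})")
```

Output for this seed:

```
RD per HLS point: -6.78 (-10.83, -2.73) per 10,000 PY
percent explained by planted mediators: 57.9% (95% BCa 22.5, 127.1)
```

The adjusted rate difference says each additional healthy-lifestyle point
avoids about 7 diabetes cases per 10,000 person-years in this synthetic
cohort (the generating value is 8).  Adjusting for the three planted
mediators attenuates the HLS coefficient by a little over half, consistent
with the generating truth of 50%; even at 6,000 participants the BCa
interval is wide, because a ratio of two noisy rate differences is poorly
determined — at the default 1,016-participant scale (~30 events) the same
interval spans hundreds of percentage points, matching the behaviour of
such decompositions in real cohorts of this size.

A command-line interface mirrors the library
(`lifemet synth | hls | screen | survival | bkmr | mediate | run-all`); see
`lifemet --help`.

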