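# Methods

## The model

`msmpub` analyses the fate of clinical research studies after ethics
approval with a progressive four-state Markov model on the time scale
*years since approval*:

```
Approved ──→ Completed ────→ Published
    └──────→ Discontinued ──→ Published
```

Published is absorbing; no state can be revisited. Each of the four
transitions *h* has intensity

    λ_h(t | x) = λ0_h(t) · exp(xᵀ β_h),

with a right-continuous step-function baseline λ0_h on a grid of cutpoints
shared across transitions, and per-transition log hazard ratios β_h for the
eight encoded covariates (log planned sample size; RCT; commercial /
unstated funding vs non-commercial; industry involvement; primary outcome;
national / international multi-centre vs single-centre). All four
transitions run on the same clock-forward time scale, so the publication
intensity after completion depends on time since approval, not on the
sojourn time in Completed. A semi-Markov (sojourn-clock) variant would be a
natural extension but is not implemented.

Default cutpoints are {2, 4, 7, 9} years: publication activity is
concentrated roughly four to seven years after approval and has largely
ceased beyond nine, so these knots give the baseline enough freedom where
the hazard actually moves. They are fully configurable.

## Observation scheme and likelihood

Source data carry calendar years only. An event recorded in year *y* is
interval-censored to `[y − approval, y − approval + 1)`. For most studies
the intermediate year (completion / discontinuation) is unknown
altogether; it is then bounded by `[0, U)` with *U* the end of follow-up,
tightened to the right edge of the publication interval for published
studies, because a study cannot be published before it ends. Each study
reduces to one of these contribution patterns (writing S₁ for survival in
Approved, Λ for cumulative intensities, m for the intermediate transition
and q for its publication transition):

* still Approved at censoring time c (survey answer "ongoing"):
  `S₁(0, c)`;
* intermediate in [a, b), unpublished at c:
  `∫ₐᵇ S₁(0,s) λ_m(s) exp(−Λ_q(s, max(s, c))) ds`;
* intermediate in [a, b), published in [p, p+1):
  `∫ₐᵇ S₁(0,s) λ_m(s) [exp(−Λ_q(s, max(s,p))) − exp(−Λ_q(s, p+1))] ds`;
* status unknown, no publication found (no survey response): the sum of
  the still-Approved contribution and the two unpublished-after-exit
  integrals over [0, c] — i.e. exactly P(no publication by c | x).

The last pattern deserves a note, because it was a genuinely open design
choice. The simplest treatment censors non-responders in the Approved
state, but most of them have in fact completed or been discontinued
unobserved, and simulation shows that censoring them in Approved biases
the covariate effects (the effect is visible at n = 800 with a 9%
non-response rate). The mixture contribution above uses exactly what was
observed — the absence of a publication — and restores approximate
unbiasedness, so it is the default (`derive_observation_case(...,
unclear="unknown_state")`); the censor-in-Approved variant remains
available as `unclear="censor_approved"`.

Because the baselines are step functions, every integral is a sum of
closed-form pieces: splitting [a, b) at the cutpoints and at the relevant
absorbing bound makes each integrand `const · exp(κ(s−u))`, integrable as
`Δ · φ(κΔ)` with `φ(z) = (e^z − 1)/z` (series-expanded near 0). The
survival mass down to the left end of each integration range is factored
out analytically, so contributions are evaluated stably in log space. A
fully exact-time variant (point contributions instead of integrals) is
supported for model checking.

The analytic score (gradient in all log-baselines and βs) is implemented
alongside the likelihood, including the posterior-weighted mixture for the
unknown-state pattern, and is verified against finite differences and
against an adaptive-quadrature likelihood oracle in the test suite.

## Estimation

Parameters enter on the log scale, so positivity is automatic and the
problem is smooth and effectively unconstrained; we maximize with L-BFGS-B
(box ±20 on the log scale purely as a numerical safeguard — a baseline
interval with no events legitimately runs to the lower box) followed by a
safeguarded Newton polish on the analytic score (relative function
tolerance 1e−10, polish gradient tolerance 1e−8, at most 2000 + 30
iterations). Convergence is judged on the *projected* gradient, so a rate
pinned at the box with outward-pointing gradient does not mask
convergence. Initial values are crude event/exposure rates with intervals
taken at midpoints; β starts at 0. The fit is deterministic.

Standard errors are Wald, from the inverse of a central-difference
observed information built on the analytic score (step 1e−5 · max(1,|θ|));
95% CIs are exp(β ± z₀.₉₇₅·SE). Dummy covariate levels with zero (or all)
events on a transition are non-identifiable — the log-HR would diverge —
and are detected up front, frozen out of the optimization, and reported as
`--` in the hazard-ratio tables. Baseline intervals with zero crude
exposure are likewise frozen. If the observed information is not positive
definite at the reported optimum (possible when a transition is nearly
non-identifiable in a small cohort), the affected standard errors are
reported as NA rather than as spuriously tight intervals.

Transition-probability matrices P(s, t | x) are computed as products of
exact matrix exponentials of the 4×4 generator over constant-intensity
pieces; rows sum to 1 to 1e−10 and Published is absorbing.

## Two-state analysis

The simplified Approved → Published analysis treats time from approval to
first publication (integer years; events in the approval year are placed
at mid-year, 0.5, to keep durations positive) as right-censored survival
data. The Kaplan-Meier complement estimates the cumulative publication
probability, with Greenwood pointwise variance recomputed from the event
table. The median CI inverts the test (Ŝ(t) − ½)²/Var Ŝ(t) ≤ χ²₁(0.95) on
the plain survival scale (a log(−log) transform is available by option);
the interval is the span of event times in the acceptance region, reported
as unbounded above when the region includes the largest event time — the
shape this produces under heavy late censoring, [finite, ∞), is exactly
what staggered cohort horizons with a median near the end of follow-up
give. Cox regression uses the Efron tie correction by default (yearly data
produce many ties; Breslow is available by option), with all eight
covariates entered simultaneously. Multicollinearity is checked with VIFs
computed as the diagonal of the inverse correlation matrix of the
coefficient covariance. The median time among *published* studies only is
computed as a labelled descriptive statistic; it conditions on the future
and is not an estimator of time to publication.

## Timing-free sensitivity analysis

Per-transition logistic regressions ignore time entirely: outcome =
transition achieved during follow-up, risk sets following the state graph
(everyone for the two initial transitions, completed studies for
completion → publication, discontinued studies for discontinuation →
publication; ongoing/unclear studies count as non-events for the initial
transitions, mirroring the occupancy bookkeeping). Separation — a zero
cell between a dummy level and the outcome, or a diverging coefficient —
is flagged and reported NA, not corrected; with fewer events than
parameters the whole table is reported NA. With long follow-up the odds
ratio systematically overshoots the hazard ratio, which is demonstrated as
a property check rather than assumed.

## Synthetic cohorts

The generator (`msmpub.simulate`) emulates the observation scheme of a
three-year REC approval cohort: covariate marginals (43.9% RCT;
44.3/26.9/28.8% commercial/non-commercial/unstated funding; 42.4/34.1/23.5%
single/multi-national/multi-international; 59.8% primary outcome; 43.2%
industry involvement; log-normal planned sample size with median 120 and
log-sd 1.53, chosen to match a mean of roughly 390 alongside the median);
equal-probability approval years 2000–2002 with follow-up horizons 11/9/8
years; continuous-time trajectories by inversion sampling of the
piecewise-constant total exit hazard with a multinomial cause split, then
a publication time on the same clock; and the retrospective observation
scheme — years floored to calendar years, intermediate event year retained
with probability 0.23 (completed) / 0.13 (discontinued), survey response
0.91 with non-responding unpublished studies becoming "unclear", and
publication years always retained (publications are found by search, not
by survey). Masking draws are independent of the event history, so
missingness is non-informative by construction.

True covariate effects default to an illustrative set of per-transition
hazard ratios typical of publication-bias cohorts (funding source slowing
completion and publication, industry involvement accelerating completion,
small and randomized studies discontinuing more, with much weaker and
partly opposite effects elsewhere). Baseline log intensities were
calibrated once by simulation so that, under those effects and marginals,
about 71% of studies complete, 16% discontinue and 49% publish within
their horizons (63% of completed, 25% of discontinued), and then frozen
into the defaults; they are not re-tuned. Covariates are drawn
independently (only marginals are emulated); an optional mode couples
industry involvement to commercial funding. The generator makes no attempt
to reproduce a particular real cohort's correlation structure, secular
trends, or the publication-search process itself, so passing tests
demonstrate internal statistical correctness of the pipeline, not fidelity
to any specific dataset.

## Verification strategy and problem sizes

The experiments in `msmpub.evaluation` (run by `scripts/acceptance.py` and
the acceptance tests) use these sizes, chosen to make Monte-Carlo noise
small at interactive runtimes: occupancy arithmetic on the published
transition counts (n = 806); likelihood-vs-quadrature comparison on 50
randomized case/model pairs covering all contribution patterns;
closed-form exponential limit at n = 500; factorization against
independent per-transition Poisson-offset GLM fits at n = 400; parameter
recovery over 100 cohorts of n = 800 under the default observation scheme;
Brookmeyer-Crowley coverage over 200 censored exponential cohorts of
n = 300, plus one n = 800 heavy-late-censoring cohort (yearly exponential
events at rate 0.0648, staggered administrative censoring at 8/9/11 years,
so the survival curve only grazes ½ near the end of follow-up) for the
one-sided interval shape; a brute-force Efron partial-likelihood grid
oracle on 8 observations; and 20 replicates of the OR-vs-HR comparison at
n = 500 with a true hazard ratio of 2.

## Known limitations

* **Sparse-transition small-sample bias.** Discontinued → Published
  carries only ~26 events per n = 800 cohort against 8 covariates. The
  recovery study shows the classic away-from-zero maximum-likelihood bias
  there: the mean bias of its largest coefficients (log sample size, RCT,
  industry) is a few hundredths to ~0.2 on the log scale — beyond 3
  Monte-Carlo SEs at 100 replicates — while Wald coverage remains nominal
  (0.93–0.96 per transition) and all coefficients of the three
  well-populated transitions are unbiased within Monte-Carlo error.
  Estimates on very sparse transitions should be read with the same
  caution their wide intervals already suggest.
* The Markov clock-forward assumption makes the publication hazard depend
  on time since approval rather than time since completion.
* No time-dependent covariates, frailties, non-parametric (NPMLE)
  interval-censored estimation, or discrete-time grouped-data model.
* Yearly granularity is taken at face value: within-year orderings are
  not modelled beyond the logical constraint that publication cannot
  precede study end.
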