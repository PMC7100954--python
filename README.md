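# msmpub

Multi-state event-history analysis of the time from ethics approval to
publication of clinical research studies.

## The problem

Roughly half of the clinical studies approved by research ethics
committees are never published, and those that are take years to appear.
Asking only "how long from approval to publication?" hides where the time
goes: conducting the study (approval → completion, or early
discontinuation) versus analysing, writing and publishing it (completion /
discontinuation → publication). `msmpub` implements a four-state
progressive model that separates these phases,

```
Approved ──→ Completed ────→ Published
    └──────→ Discontinued ──→ Published
```

with transition intensities λ_h(t|x) = λ0_h(t)·exp(xᵀβ_h): piecewise-
constant baselines on a shared grid of cutpoints and per-transition
proportional covariate effects (hazard ratios exp(β)). The defining
difficulty of this kind of retrospective registry cohort is heavy interval
censoring — events are recorded to the calendar year at best, and for most
studies the year of completion or discontinuation is unknown entirely. The
package evaluates the full likelihood of such data *analytically* (every
integral closes over the step-function baselines) together with its exact
score, so maximum-likelihood fits with Wald confidence intervals are fast
and reproducible.

Around that core it provides:

* the simplified two-state Approved → Published analysis: Kaplan-Meier
  complement CDF, Brookmeyer-Crowley confidence interval for the median
  time to publication, Cox regression with Efron ties, and VIF
  multicollinearity checks;
* a timing-free sensitivity analysis (per-transition logistic
  regressions on transition achievement);
* a synthetic cohort generator reproducing the observation scheme
  (yearly granularity, ~23%/13% availability of intermediate event years,
  91% survey response, staggered follow-up horizons), so the whole
  pipeline is testable without access to any confidential registry data;
* a CLI (`msmpub`) orchestrating simulate / describe / fit2 / fit4 /
  sensitivity runs with config files and run manifests.

It is aimed at biostatisticians and meta-researchers studying publication
dynamics or, more generally, progressive multi-state processes observed
through interval-censored panel-style records.

## Worked example

```python
import numpy as np
from msmpub import (
    SimulationScenario, simulate_cohort, impute_sample_size,
    derive_observation_case, count_state_occupancy, fit_msm,
    format_hazard_ratio_table, to_survival_sample, km_fit,
    median_ci_brookmeyer_crowley,
)

scenario = SimulationScenario(n_studies=806, seed=42)
records, _ = simulate_cohort(scenario)
records, median_size, n_imputed = impute_sample_size(records)

print(count_state_occupancy(records).format())

sample = to_survival_sample(records)
ci = median_ci_brookmeyer_crowley(km_fit(sample))
print(f"Median time to publication: {ci.median:g} years "
      f"[{ci.lower:g}, {'inf' if np.isinf(ci.upper) else ci.upper}]")

cases = [derive_observation_case(r) for r in records]
fit = fit_msm(cases)
print(format_hazard_ratio_table(fit).split("\n\n")[0])
```

prints

```
State occupancy
---------------
Studies analysed               806
  completed                    540
  discontinued                 121
  ongoing                       98
  status unclear                47
Published after completion     355  (66% of completed)
Published after discontinu.     30  (25% of discontinued)
Published overall              385  (48% of analysed)
Median time to publication: nan years [8, inf]
Approved -> Completed (n = 540)
  Log sample size                                            0.937 [0.876, 1.003]
  RCT vs. other                                              1.168 [0.939, 1.453]
  Funding: Commercial vs. non-commercial                     0.548 [0.425, 0.707]
  Funding: Unstated vs. non-commercial                       0.662 [0.501, 0.874]
  Industry: Involved vs. not involved                        2.555 [2.055, 3.177]
  Primary outcome: Yes vs. no                                1.433 [1.158, 1.773]
  Collaboration: National multi-centre vs. single-centre     0.727 [0.575, 0.921]
  Collaboration: International multi-centre vs. single-centre 0.755 [0.573, 0.995]
```

Reading the output: just under half of this synthetic cohort is published
within follow-up, so the Kaplan-Meier curve only grazes 50% — the median
is not identified and its 95% confidence interval is one-sided, [8, ∞)
years. The hazard-ratio block for Approved → Completed shows, for example,
commercially funded studies completing at roughly half the rate of
non-commercially funded ones (HR 0.548) and industry involvement more than
doubling the completion rate (HR 2.555); both reflect the effects built
into the generating scenario. The same table is produced for the other
three transitions, with `--` marking covariate levels that are not
identifiable on a transition (no events carrying the level).

The same pipeline runs from the shell:

```bash
msmpub all --out run1 --seed 42        # simulate + describe + fit2 + fit4 + sensitivity
msmpub fit4 --config my.yaml --out run2
```

Outputs (CSV/JSON tables, a KM curve plot, a run manifest with the config
hash and seed) land in the output directory; identical config + seed gives
byte-identical numeric outputs.

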