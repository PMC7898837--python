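# relmediate

Causal mediation analysis within the relative-survival framework.

Population-based cancer registries show large survival gaps between groups
(for instance deprivation groups), but all-cause survival mixes two very
different mechanisms: mortality from the cancer itself and background
mortality from everything else. `relmediate` implements mediation analysis
on the *relative survival* scale, so that the part of a survival gap running
through a mediator such as stage at diagnosis can be isolated from
background-mortality differences — and translated into the number of deaths
an intervention on the mediator could postpone.

## The model

The all-cause mortality rate of patient *i* decomposes as

    h(t | X, Z) = h*(t | X, Z1) + λ(t | X, Z2)

where `h*` is the expected (background) rate taken from a population
lifetable stratified by `Z1` (age, sex, calendar year, group) and `λ` is the
excess rate attributable to the cancer. Equivalently
`S(t) = S*(t) · R(t)` with `R` the relative survival. `R` is modelled with a
flexible parametric (Royston–Parmar-type) survival model: a restricted cubic
spline in `ln t` on the log cumulative excess hazard, with covariate
effects, interactions and spline-based time-dependent effects. A multinomial
logistic model gives the mediator distribution `P(M = m | X, Z2)`.

Regression standardization over the study population produces the
counterfactual marginal quantities

    ξ(y, x; t) = (1/N) Σᵢ Σₘ R(t | X=y, Z2=zᵢ, M=m) · P(M=m | X=x, Z2=zᵢ)

from which the natural effects on the net scale follow:

    NDE = ξ(1,0) − ξ(0,0),  NIE = ξ(1,1) − ξ(1,0),
    TCE = NDE + NIE,        PM  = NIE / TCE.

All-cause analogues weight each term by expected survival `S*` (either set
to the contrast's exposure, or held at each patient's observed exposure so
that differences are cancer-attributable). Avoidable deaths among the
exposed scale the standardized all-cause death probability by a population
size `N*` and compare the observed regime with regimes that shift the
mediator distribution and/or relative survival to the unexposed group's.
Uncertainty comes from a parametric bootstrap: model coefficients are drawn
from multivariate normal distributions centred at the estimates with the
fitted covariances, and every estimand is recomputed per draw.

## Worked example

```python
import numpy as np
import relmediate as rm
from relmediate.synthetic import GeneratorConfig, generate

cfg = GeneratorConfig(n=20000, seed=0)          # registry-like synthetic data
frame, lifetable = generate(cfg)                # patients + stratified lifetable

spec = rm.default_relsurv_spec(frame, cfg.mediator_levels,
                               baseline_df=5, td_df=0, td_vars=(),
                               mediator_exposure_interaction=False)
rs = rm.fit_relsurv(frame, lifetable, spec, stratum_col="stratum")
mf = rm.fit_mediator(frame, rm.default_mediator_spec(frame, cfg.mediator_levels))

t = np.array([1.0, 3.0, 5.0])
net = rm.mediation_effects_net(rs, mf, frame, t)
print("TCE:", np.round(100 * net.estimates["TCE"], 2))
print("NIE:", np.round(100 * net.estimates["NIE"], 2))
print("PM :", np.round(100 * net.estimates["PM"], 1))
```

Output (percent of standardized net probability of death):

```
TCE: [3.07 4.75 5.2 ]
NIE: [1.07 1.8  2.05]
PM : [35.  37.9 39.4]
```

At 3 years the exposed group's standardized net probability of death is 4.74
percentage points higher than the unexposed group's, and 1.80 points (38%)
of that gap runs through the mediator's distribution. Avoidable deaths
follow the same pattern:

```python
exposed = rm.restrict(frame, lambda d: d["exposure"] == 1)
ad = rm.avoidable_deaths(rs, mf, lifetable, exposed, 1000.0, t, stratum_col="stratum")
print("AD scenario 1:", np.round(ad.ad_scenario1, 1))   # [29.2 41.4 41.8]
print("AD scenario 2:", np.round(ad.ad_scenario2, 1))   # [10.2 15.7 16.4]
```

Per 1,000 exposed patients, eliminating both the mediator-distribution and
relative-survival differences would postpone about 41 deaths by year 3;
about 16 of those come from the mediator shift alone.

A command-line interface mirrors the staged algorithm:

```bash
relmediate simulate --n 20000 --seed 0 --out sim/
relmediate fit       --config run.yaml
relmediate mediate   --config run.yaml
relmediate avoidable --config run.yaml
```

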