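# preevac

Modelling and simulation of crowd **pre-evacuation decision-making**: when,
after an alarm or visible smoke, does each pedestrian stop watching and start
escaping?

Pre-evacuation time — cognition plus reaction time before purposeful
movement — is a major, poorly predicted part of the required safe egress
time (RSET).  `preevac` implements a discrete-time survival model of that
decision for heterogeneous pedestrians, together with the tooling needed to
calibrate and exercise it: a synthetic questionnaire generator, a
maximum-likelihood fitter with natural-response correction, and a
multi-zone fire-scene simulator.  It is aimed at evacuation researchers and
safety engineers who need pre-evacuation behaviour as a *predicted* input
to egress models rather than a preset constant.

## The model

The pre-evacuation phase is split into decision periods *t*.  Pedestrian *i*
escapes in period *t* when the subjective–objective risk-utility difference
exceeds a personal escape-selection threshold; with Gaussian threshold noise
the per-period escape probability is the probit hazard

```
p_it = C + (1 − C) · Φ(η_it / σ)
η_it = α_t + Σ_k c_k·PRT_ik + c2·RCS_it + c3·DFD_it + c4·RNC_it
```

where PRT is the coded attribute vector (age grade, gender, education,
familiarity time, group size, residence distance, travel mode), RCS / DFD /
RNC are the standardized hazard intensity, distance-from-danger and
neighbourhood-reaction factors on four-level [0, 1] scales, and *C* is the
natural-response rate estimated from a control group (the baseline fraction
who respond regardless of the stimulus).  Period decisions are conditionally
independent, so the first escape follows the first-passage law
`P(t) = p_t · Π_{s<t}(1 − p_s)`, censored respondents carrying the survival
product.  Calibration maximises this likelihood by Newton iteration with
analytic derivatives; the package ships the calibrated coefficient set
(`default_coefficients()`), including the two period intercepts
(−3.212, −3.185) and the control-group rate 0.1981.

The estimator is exposed sklearn-style (`DiscreteTimeProbitHazard` with
`fit` / `predict_proba` / `get_params`); `fit_mle` wraps it for
respondent-level record tables.

## Worked example

```python
from preevac import (natural_response_estimate, default_coefficients,
                     default_distributions, sample_population,
                     simulate_survey, fit_mle)

est = natural_response_estimate(2973, 589)
print(f"natural response: {est.rate_percent:.2f}% (SE {est.se:.3f})")

pop = sample_population(default_distributions(4527, seed=0))
table = simulate_survey(pop, default_coefficients(), seed=0,
                        control_subjects=2973)
res = fit_mle(table, covariates=["gen", "age", "zone", "group", "time",
                                 "mode", "rcs", "dfd", "rnc"],
              natural_rate="from_controls")
print(res.summary())
```

prints

```
natural response: 19.81% (SE 0.007)
Escape-decision model fit
============================================================
                     B       S.E.          Z       Sig.   CI lower   CI upper
intercept_1    -2.9227     0.2613   -11.1847     0.0000    -3.4349    -2.4106
intercept_2    -2.9276     0.2614   -11.1991     0.0000    -3.4400    -2.4152
gen            -0.0017     0.0673    -0.0254     0.9798    -0.1337     0.1302
age            -0.0327     0.0319    -1.0221     0.3067    -0.0953     0.0300
...
rcs             0.9499     0.1330     7.1410     0.0000     0.6892     1.2106
converged: True after 9 iterations; log-likelihood -4499.9853
natural response rate: 18.26% (SE 0.007)
```

Reading: 589 of 2973 control subjects responding is a 19.81 % spontaneous
evacuation rate with binomial SE 0.007.  The fit recovers the strong context
effects (rcs/dfd/rnc near their generating value 1.0) while the attribute
effects — generated at |c| ≤ 0.015 — are statistically indistinguishable
from zero at n = 4527, which is exactly the resolution such a survey size
affords; recovery sharpens at larger n (see the test suite's 50,000-record
check).

The fire scene runs from the command line:

```
$ preevac simulate --n 400 --seed 1 --horizon 300 --out ev.csv --summary summ.json
400/400 escaped within the horizon; 63.0% within 20 s
```

with per-36 s interval counts in `summ.json`
(`{"t": 36.0, "escaped": 298, "waiting": 102}` …) and the spontaneous
first-period fraction (0.205 here, the natural-response share).  `generate`
and `fit` complete the CLI; all artifacts carry `*.meta.json` provenance
records and every run is bit-reproducible under its seed.

## Layout

```
src/preevac/
  population.py   attribute codings, sampling, questionnaire emulator
  risk.py         four-level standardization of RCS / DFD / RNC
  model.py        hazard, first-passage, likelihood, MLE, estimator class
  simulation.py   scenes, placement, smoke front, stepping, summaries
  cli.py          generate / fit / simulate / report verbs
docs/methods.md   model assumptions, defaults, numerical choices, limits
```
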