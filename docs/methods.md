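# Methods

## The model

`preevac` models the *pre-evacuation phase*: the interval between the onset of
an emergency (alarm, smoke, shouting) and the moment a pedestrian commits to
purposeful escape movement.  Pre-evacuation time is a large and poorly
predicted component of the required safe egress time (RSET), and it is driven
as much by who the pedestrian is as by what the hazard does.

The phase is discretised into decision periods ``t = 1..T``.  In each period
pedestrian *i* compares the difference between subjective and objective risk
utility, ``RE_it``, with a personal escape-selection threshold ``ECT_it``:
escape when ``RE_it >= ECT_it``, wait-and-see otherwise.  Only the difference
is identifiable from choice data, so the package parameterises the
deterministic part of the margin directly as a linear index

    eta_it = alpha_t + c11*Age_i + c12*Gen_i + c14*Time_i + c15*Group_i
           + c16*Zone_i + c17*Mode_i + c2*RCS_it + c3*DFD_it + c4*RNC_it

over the coded personal-risk-tolerance (PRT) attributes and the three
standardized context factors (risk strength RCS, distance from danger DFD,
neighbourhood reaction RNC), each on a four-level [0, 1] scale.  Gaussian
noise on the threshold gives the per-period probit hazard with
natural-response (control-group) correction

    p_it = C + (1 - C) * Phi(eta_it / sigma),

and conditional independence of period decisions gives the first-passage law

    P(T_i = t) = p_it * prod_{s<t} (1 - p_is),

with censor mass ``prod_{s<=T}(1 - p_is)`` for pedestrians who never escape
within the horizon.  The likelihood is the product of these terms over
pedestrians; censored pedestrians contribute their survival product by
default (``include_censored=False`` restricts the likelihood to observed
escapes, the literal published form).

### Identification and normalisation

* ``sigma`` is not identifiable separately from the coefficients in a probit;
  it is fixed at 1 internally (the scale of the threshold disturbance is
  absorbed into the coefficients).  The field is kept on `CoefficientSet` so
  rescaled sets remain representable.
* The subjective and objective utilities are not separately identifiable;
  `RiskUtility` carries them for interpretation, but only the difference and
  threshold enter any computation.
* The natural-response rate ``C`` is estimated from the control group (rate
  ``responses/subjects`` with binomial SE) and held fixed during the probit
  maximisation — the two-step scheme standard for natural-response probit
  analysis.  The reported SE for the shipped rate (0.007 for 589/2973)
  matches the binomial formula; the package treats it as such.

### Two intercepts

The calibrated model carries two intercepts (−3.212, −3.185).  They are used
in two consistent ways:

* In the survival route (`fit_mle`, the survey generator) they are
  *period-specific intercepts* ``alpha_t`` of the per-period hazard — one per
  decision stage, which is the reading consistent with the first-passage
  likelihood.
* `stage_probabilities` exposes the *cumulative shared-slope* (ordered
  probit) view: K ascending cut points split the response intensity into
  K + 1 ordered categories; K = 2 reproduces the calibrated structure and
  equal cut points collapse the middle category.

## Calibration

`fit_mle` expands respondent rows into person-period rows (a respondent
escaping at period *k* contributes *k* Bernoulli rows with a single success
at the last), builds a design of period dummies plus covariates, and runs
safeguarded Newton iteration with analytic gradient and Hessian from an
all-zero start.  Convergence requires score sup-norm below ``gtol`` (default
1e-8) within ``max_iter`` (default 500) iterations.  Standard errors, z
values, two-sided p values and 95% CIs come from the inverse observed
information; a rank-deficient design (e.g. a constant covariate) raises
`NonIdentifiableError` rather than returning a spurious fit.  Significance
screening is one-pass: fit, drop covariates with p above the threshold
(default 0.05), refit once — mirroring the published workflow that removed
education.  A Pearson-type chi-square over unique covariate patterns is
reported as a fit diagnostic; its value is data-dependent and is not a
reproduction target.  With ``C = 0`` and a single period the procedure is an
ordinary probit and agrees with an independent implementation (statsmodels)
to ~1e-12 in the tests.

## Synthetic questionnaires

The original 4527-questionnaire survey is not deposited, so
`population.simulate_survey` emulates it by inverting the fitted model:
attributes are drawn independently from per-field categorical marginals,
each respondent judges an independently drawn level-quantized context
vignette (uniform over the four scale values per factor), and the
first-escape period is drawn from the per-period hazards, natural response
included.  Control-group rows respond with probability ``C`` alone.

Defaults chosen where the source states nothing, fixed once:

* attribute marginals describe a mixed metropolitan day-time crowd
  (working-age majority, near-even gender split, transit-heavy mode mix);
* attributes are independent (no dependence structure is reported);
* context vignettes are uniform over the four levels, which keeps all three
  context coefficients identifiable;
* context coefficients c2–c4 are not published; the package default is 1.0
  each on the standardized scales, and every simulation output is
  conditional on that choice.

What passing recovery tests show — and do not show.  Parameter recovery at
n = 50,000 demonstrates that the estimator is consistent and its reported
SEs are honest *under the generator's assumptions* (independent attributes,
uniform vignettes, correctly specified hazard).  It does not validate the
published coefficient values against real behaviour, and the generator does
not emulate survey nonresponse, attribute dependence, or vignette design
effects.  Note the calibrated attribute effects are small (|c| ≤ 0.015);
at realistic sample sizes their estimated signs remain noisy, which is
visible in seed-to-seed variation of the sign-agreement summary.

## Risk standardization

Levels L1–L4 map bijectively to scales 1.00/0.75/0.50/0.25.  Distance bins
are half-open — [0, 20), [20, 40), [40, 60), [60, ∞) metres — so every
distance maps to one level.  The neighbourhood-reaction level is only
behaviourally labelled in the source; the package quantifies it as the
fraction of already-reacting agents within a configurable radius (default
10 m) cut at quartiles.  A continuous mode (``dfd = clip(1 − d/80)``,
``rnc = fraction``) is available but off by default.  The default scene
declares the fire at intensity "Level 4"; under the literal level table that
is the *weakest* scale (0.25).  The package keeps the literal coding as the
default and offers ``invert_fire_scale`` for the opposite reading; both are
exercised in tests.

## Fire-scene simulation

The default scene is a 100 m × 60 m three-hall layout (two 50 × 30 front
halls, one 100 × 30 rear hall), origins 1–3, exits at nodes 4 and 5, fire at
the centre of zone 3, smoke front circular at 0.3 m/s, walls not blocking
smoke.  Metric dimensions are package defaults — the reference layout
publishes topology, not sizes — and everything is configurable through a
JSON layout.  Demand splits 14.3 % / 28.6 % / 57.1 % across the origins with
largest-remainder rounding (ties broken by origin order).  Agents are placed
uniformly in their origin zone and do not move before deciding; post-decision
locomotion, congestion and exit choice are out of scope.

Each period every waiting agent recomputes its context (RCS fixed by the
event; DFD from its static position; RNC from neighbours that have already
reacted), evaluates the hazard and draws a Bernoulli decision; escape is
absorbing.  The decision period defaults to dt = 1 s with a 300-period
horizon; the 36 s reporting interval affects summaries only.  The
natural-response rate is applied at the first period only (a one-shot
spontaneous-response fraction); applying it as a per-second floor would
empty the scene within a few periods and does not describe a baseline
*rate of people*, which is what the control group measures.  An optional
awareness delay gates agents until the smoke front reaches their zone
(default off — the source narrative implies staged awareness but states no
rule).

Because c2–c4 and the layout's metric scale are package choices, the
simulator's headline fractions (e.g. the share escaping within 20 s) are
conditional quantities, reported by `summarize` but not treated as
reproductions of any published figure.  With the shipped defaults the
early-escape share is substantially higher than the published narrative's
20.1 %, which is expected: unit context coefficients make the standardized
context terms dominate the (small) attribute effects.

## Numerical choices

* Probit CDF via `scipy.special.ndtr`/`log_ndtr`; likelihoods use the
  log-CDF forms, so extreme indices degrade gracefully (an exactly
  impossible observation yields −inf with a logged diagnostic, not an
  exception).
* Probabilities are clipped at 1e-12 only inside gradient/Hessian weights.
* Newton steps fall back to gradient ascent if the Hessian is not negative
  definite at the current iterate; step halving guards the line search.
* First-passage mass is conserved to better than 1e-12 for arbitrary hazard
  sequences (verified against exhaustive 2^T enumeration).
* All randomness flows from one top-level seed through named
  `SeedSequence` substreams (population, placement, decisions), so runs are
  bit-reproducible.

## Problem sizes used in the shipped checks

Parameter recovery uses 50,000 respondents × 2 periods; simulator-vs-
analytic equivalence pools 200 replicates of 100 agents × 12 periods; the
probit-degeneration check uses 4,000 single-period respondents; the default
simulation example uses 800 agents × 300 s.  These sizes give the stated
statistical resolution (4-SE bands; 2-SE recovery) while keeping any single
check in the seconds-to-minutes range.

## Known limitations

* Ordinal attributes (and travel mode) enter as single numeric covariates,
  as calibrated; one-hot encoding is a possible extension, not the default.
* The RNC quantification and the attribute marginals are package
  constructions; conclusions that depend on them should be re-examined
  against real survey tables when available.
* No fire physics beyond the linear circular smoke front; no Bayesian or
  random-effects extensions.
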