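# Methods

## Model structure

The model is a one-cohort, expected-value accounting of two opposing
causal pathways of e-cigarette use, evaluated for a single base year and
followed to their long-run endpoints:

1. **Cessation benefit.** Adult current smokers (25–69, 5-year groups)
   who tried to quit in the past year and currently use e-cigarettes
   experience a different ≥6-month cessation probability than attempters
   who do not. Those who reach ≥6 months are carried through two further
   conditional persistence probabilities (1 year | 6 months, ≥6 years |
   1 year) to ≥7 years of continual abstinence, a horizon beyond which
   relapse is rare and excess mortality approaches never-smoker levels.
   Each long-term quitter gains an age-dependent number of life years.
2. **Initiation harm.** Never-smoking adolescents and young adults
   (12–29, single years) who have ever used e-cigarettes experience a
   higher one-year smoking-initiation probability than never-users.
   Initiators convert to current daily smoking at 35–39 with an
   age-of-initiation-dependent probability, and each eventual daily
   smoker loses an age-dependent number of life years.

Both pathways are pure multiplicative chains over age strata (see the
README for the formulas); counts are real-valued expectations, never
rounded internally. Net life years = benefit + harm, with harm ≤ 0 by
sign convention; negative net years are reported as years of life lost.

### Effect sizes on the odds scale

Published effects enter as odds ratios and are applied to baseline
probabilities on the odds scale, `p' = OR·p/(1−p+OR·p)`. A relative
risk from a trial is converted to an odds ratio at the trial's control
risk (`rr_to_or`), and the inverse conversion is provided. The
cessation baseline is a two-component mixture over pharmaceutical-aid
use during the quit attempt; the non-aid cessation probability is an
explicit parameter rather than a hard-coded constant, and the single
pooled odds ratio is applied to the aggregate mixture baseline (one
reference probability), the simplest reading of a user/non-user
contrast. Initiation deltas are computed per single year of age from
that age's baseline with one shared pooled odds ratio.

### The dilution penalty

With `h` the residual harm of e-cigarettes relative to cigarettes, the
benefit branch credits each additional quitter only `(1−h)` of the
age-specific life-year gain, and — when the dilution penalty is on
(default) — debits `h` of the gain for each *baseline* quitter in the
exposed group (`Q0`): quitters who would have quit without e-cigarettes
but continue to carry the residual exposure. This term is the only
accounting under which a benefit branch can be net-negative while the
additional-quitter count is positive, which matches the reported
behaviour of this model class; because the exact published accounting
is not printed anywhere public, the term is a boolean flag
(`include_dilution_penalty`) so the pure `(1−h)·ΔQ` reading can be run
unchanged.

## Uncertainty propagation

Every uncertain parameter is an `(mean, SE)` pair sampled independently
as `N(mean, SE)`; zero-SE parameters (census counts, fixed assumptions)
pass through exactly. Parameters published as 95% CIs get
`SE = (upper − lower)/(2·1.959964)`, consistent with the normal
sampling model; draws are on the natural scale, including odds ratios,
because the intervals being emulated are symmetric on that scale.

**Truncation.** Normal draws can leave a parameter's domain. The
default `clip` policy clips probabilities to [0, 1], odds ratios to
(1e-9, ∞) and life-year weights to [0, ∞), and reports the fraction of
draws altered (`clip_rate`; about 0.26% on the calibration set — a
tripwire fires in the tests if it ever exceeds 5%). Clipping the
life-year weights (nonnegative by definition) also makes the coupled
monotonicity guarantees below hold draw by draw rather than only in
expectation. The alternative `resample` policy redraws out-of-domain
values until they land in-domain.

**Reproducibility and coupling.** One master seed spawns a
deterministic substream per *parameter* (`numpy SeedSequence.spawn` in
a fixed enumeration order), and each parameter's entire length-n vector
is drawn in one call. Consequences: results are independent of how
iterations might be batched; runs are bit-reproducible from the
manifest; and two runs sharing a seed but differing in one parameter's
mean/SE (a scenario) reuse identical standard-normal deviates
everywhere — the matched-seed coupling that makes scenario orderings
exact. The per-parameter (rather than per-iteration) substream layout
was chosen because it delivers the same guarantees while permitting
fully vectorized sampling; 100,000 iterations of the full model run in
roughly two seconds on one core.

**Summaries.** Outcome distributions are summarized by the arithmetic
mean and, by default, the empirical percentile interval at
`(1 ± level)/2` using numpy's linear quantile interpolation (pinned in
code and tests: draws 1…100 at level 0.95 give [3.475, 97.525]); a
normal-approximation interval (mean ± z·SD) is available as
`method="normal"`. The probability of net benefit is the strict
fraction of iterations with net years > 0. Human-readable reports round
to 3 significant digits; machine outputs keep full precision.

## Scenarios and sweeps

`mode="scale"` multiplies a parameter's mean *and* SE by the factor, so
a published CI scales proportionally (scaling an OR of 3.50 with CI
2.38–5.16 by 0.9 yields 3.15 with CI 2.14–4.64, as the scaled bounds
imply the scaled SE exactly). `mode="set"` fixes the parameter at a
value with SE 0 — the "suppose the parameter equalled x" reading, in
which all *other* parameters keep their baseline distributions.
Prevalence scenarios transform every stratum, clipping means into
[0, 1] with a warning and a metadata record. `apply_scenario` is pure:
the input set is never mutated, and scale f followed by 1/f returns the
original values to floating-point accuracy.

Sweeps (`harm_sweep` over h ∈ [0, 1]; `prob_surface` over a multiplier
grid for the two odds ratios or either e-cigarette prevalence) rerun
the full Monte Carlo per grid point under matched seeds. Under the
coupling, net years are non-increasing in h, the probability of net
benefit is non-decreasing in the cessation-OR multiplier and
non-increasing in the initiation-OR multiplier, draw by draw; the tests
assert these orderings directly. Fixing the initiation OR at 1 removes
the harm branch exactly, so the probability of positive net years
equals the probability of a positive benefit branch — the structural
ceiling on net benefit when initiation harm is absent. One published
axis in this model class is labelled a relative *risk* of cessation
while the underlying arithmetic multiplies the odds ratio; the sweep
implements the multiplier reading, and `rr_to_or` is provided for the
strict relative-risk interpretation.

## One-year validation

As a near-term check, the first year of each branch is predicted for
*everyone*, not just the e-cigarette-exposed: expected ≥6-month
quitters `Σ Pop·s·q·[e·p_exposed + (1−e)·p_reference]` and expected
initiators `Σ Pop·n·[v·p_exposed + (1−v)·p_baseline]`, with no
persistence factors and no life years. The predicted SE is the SD of
the prediction across Monte Carlo iterations, and the comparison with
an observed count (mean, SE) is a two-sample z-test with independent
SEs — the published source for this model class does not state its
test, so the simplest defensible choice is used and named. The
repository ships only synthetic inputs for this, since the original
survey microdata are restricted; the published validation counts are
not desk-reproducible and are not targeted.

## Synthetic data

The generator (`generate_parameter_set`) draws stratum means from
configurable uniform ranges — defaults chosen to be demographically
plausible for a mid-2010s US cohort (e.g. adult smoking prevalence
12–22%, quit attempts 40–60%, adolescent never-smoking ≥ 90%,
initiation probabilities ≤ 8%/year) — imposes optional monotone age
profiles (life-year effects shrink with age; ever e-cigarette use rises
through adolescence; initiation and daily-conversion probabilities fall
with age), and assigns SEs as a uniform 5–20% relative fraction of the
mean. It emulates the *structure* of survey-estimated inputs, not their
values: no survey design, no between-parameter correlation, no
sampling-weight artefacts. Passing tests on generated sets therefore
demonstrates correctness of the accounting machinery, not fidelity of
any particular published estimate.

The calibration fixture is deterministic: its two exposure aggregates
(Σ Pop·s·q·e = 3,490,000; Σ Pop·n·v = 3,640,000) are enforced exactly
by rescaling the e-cigarette prevalence profiles, its shared odds
ratios and relative harm are the published values, and everything else
is a plausible placeholder explicitly labelled in the set's metadata.
Headline outcomes computed on the fixture (e.g. net years of life) are
properties of the fixture, not reproductions of published results,
which would require the unpublished age-specific input tables.

## Numerical choices and edge cases

- Probabilities are fractions in [0, 1] everywhere; readers of
  percent-scaled sources must divide by 100 before ingestion.
- `se_from_ci` is exact for symmetric normal intervals and is the
  declared convention for asymmetric published intervals too (the
  width-implied SE).
- With n = 1 the percentile interval degenerates to the single draw;
  `summarize` requires n ≥ 1 and flags significance only when the
  interval excludes zero.
- The resample truncation policy raises after 1,000 redraw rounds
  (reachable only with pathological mean/SE combinations).
- Degenerate validation comparisons (both SEs zero, means differ) are
  errors rather than infinities.
- CSV round trips write shortest-round-trip float reprs and parse cells
  with Python's `float`, so write→read is lossless to the last bit.

## Problem sizes

Default study conditions: 9 adult age groups, 18 single youth ages,
100,000 Monte Carlo iterations (the convention for this model class),
95% intervals, 3-significant-digit reports. Sweeps in the test suite
use 10,000 iterations per grid point (Monte Carlo error is irrelevant
there because matched-seed coupling makes the compared quantities
exactly ordered); the acceptance script uses the full 100,000.

## Known limitations

- Structural, not just parameter, uncertainty dominates this model
  class; no model averaging is attempted.
- No relapse after ≥7 years of abstinence, no dual-use intensity
  effects, no effects among former smokers — pathways outside the two
  chains are absent by design.
- Independent normal sampling ignores correlations between survey
  estimates from the same instrument.
- The dilution penalty is a reconstruction of unprinted accounting; it
  is documented, flagged, and testable, but not certain.
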