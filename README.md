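# ecignet

A Monte Carlo stochastic cohort model that weighs the population-level
**benefits** of e-cigarette use (current smokers who quit through
e-cigarettes and stay quit) against its **harms** (never-smoking
adolescents and young adults who initiate cigarette smoking through
e-cigarettes and become daily smokers), expressed as net expected years
of life gained or lost for a single population cohort.

Intended for tobacco-control researchers and health-policy modellers who
want a transparent, reproducible implementation of this class of
harm–benefit accounting: age-stratified multiplicative risk chains,
odds-ratio–based transition probabilities, normal parameter uncertainty
propagated by simulation, and matched-seed sensitivity analysis.

## The model

**Benefit branch** — for each 5-year adult age group *a* (25–29 … 65–69):

```
ΔQ_a = Pop_a · s_a · q_a · e_a · Δcess · p(1y|6m) · p(6y|1y)
```

where `s` is current-smoking prevalence, `q` past-year quit-attempt
prevalence among smokers, `e` current e-cigarette use among attempters,
`Δcess = p_exposed − p_reference` the difference in ≥6-month cessation
probability, and the last two factors carry quitters to ≥7 years of
abstinence (after which relapse is rare and mortality approaches
never-smoker levels). The reference probability is an aid/non-aid
mixture, `p_ref = w·p_aid + (1−w)·p_noaid`, and the exposed probability
applies the cessation odds ratio on the odds scale:

```
p' = OR·p / (1 − p + OR·p)
```

Life years gained, with `h` the residual harm of e-cigarettes relative
to cigarettes (base case `h = 0.05`, i.e. 95% relative harm reduction)
and `Q0_a` the baseline quitters among the same e-cigarette users:

```
B = Σ_a YLG_a · [ (1−h)·ΔQ_a − h·Q0_a ]
```

The `−h·Q0_a` dilution penalty (on by default, switchable) charges
continuing e-cigarette use its residual harm among quitters who would
have quit anyway.

**Harm branch** — for each single year of age *a* (12 … 29):

```
ΔI_a = Pop_a · n_a · v_a · Δinit_a · d_a ,   H = −Σ_a ΔI_a · YLL_a
```

with `n` never-smoking prevalence, `v` ever e-cigarette use among never
smokers, `Δinit` the initiation-probability difference (age-specific
baseline pushed through the pooled initiation odds ratio), and `d` the
probability of being a daily smoker at 35–39 given initiation at age
*a*. **Net life years = B + H**; negative values are years of life lost.

Every uncertain parameter is an independent `N(mean, SE)` draw per
iteration (out-of-domain draws clipped or resampled, with the clip rate
reported); 100,000 iterations by default; outcomes summarized by the
mean and an empirical percentile interval.

## Worked example

The package ships a deterministic calibration parameter set
(`ecignet.calibration_fixture()`): its exposure aggregates are pinned to
the published 2014 US totals — 3,490,000 adult smokers with a past-year
quit attempt who currently used e-cigarettes, and 3,640,000 never-smoking
12–29-year-olds who had ever used e-cigarettes — and its shared odds
ratios to the published meta-analytic estimates (cessation OR 0.86,
95% CI 0.54–1.18; initiation OR 3.50, 95% CI 2.38–5.16). All age-specific
prevalences, baseline probabilities and life-year weights are plausible
placeholders (labelled as such in the set's metadata), because the
original age-specific inputs have no public machine-readable release.

```bash
$ ecignet run --fixture --iterations 100000 --seed 1 --out-dir out
additional_quitters: -18,100 (-61,200 to 22,500)
additional_initiators: 57,400 (27,200 to 86,000)
benefit_years: -175,000 (-476,000 to 104,000)
harm_years: -627,000 (-941,000 to -297,000)
net_years: -802,000 (-1,230,000 to -373,000)
P(net years > 0) = 0.000
```

Reading: under this parameter set the model expects ~18,100 *fewer*
long-term quitters (the cessation OR is below 1), ~57,400 additional
adolescent/young-adult initiators who become daily smokers at 35–39,
and a net loss of ~802,000 years of life (95% CI 373,000–1,230,000
years lost); the probability that e-cigarette use yields a net benefit
is essentially zero here. `out/` contains the full-precision summary
JSON, the per-iteration draws CSV and a reproducibility manifest.

Other subcommands: `sweep-harm` (net years across the relative-harm
grid 0–100%), `sweep-prob` (probability of net benefit along a
parameter multiplier grid), `scenarios` (matched-seed sensitivity
table), `validate` (one-year predicted vs observed quitter/initiator
counts), `simulate-params` (emit synthetic parameter tables). Run
`ecignet <cmd> --help` for options; your own parameter tables go in via
`--adult-table/--youth-table/--shared-config` (CSV/JSON schemas in
`ecignet/parameters.py`).

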