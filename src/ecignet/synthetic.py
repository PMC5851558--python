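"""Synthetic parameter sets with the structure the model assumes.

The model's real inputs are age-stratified survey estimates that have no
public machine-readable release, so this module generates parameter
tables with the right shape and plausible magnitudes: nine 5-year adult
age groups spanning 25-69 and eighteen single years of age 12-29, each
with the full multiplicative-chain inputs and normal parameter
uncertainty.

Two entry points:

* :func:`generate_parameter_set` draws means from configurable uniform
  ranges (with optional monotone age profiles) and assigns relative SEs
  — arbitrary but valid inputs for pipeline testing.
* :func:`calibration_fixture` is a deterministic built-in set whose two
  exposure aggregates are pinned to the published population totals for
  2014 — 3,490,000 adult smokers with a past-year quit attempt who
  currently used e-cigarettes, and 3,640,000 never-smoking adolescents
  and young adults who had ever used e-cigarettes — together with the
  shared effect sizes (cessation OR 0.86, 95% CI 0.54-1.18; initiation
  OR 3.50, 95% CI 2.38-5.16; relative harm 0.05). Every other value is a
  documented plausible placeholder, not a source value.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ecignet.parameters import (ADULT_AGE_GROUPS, YOUTH_AGES, AdultStratum,
                                CessationShared, InitiationShared,
                                ParameterSet, UncertainQuantity, YouthStratum,
                                se_from_ci, validate)

EXPOSED_ADULT_SMOKERS = 3_490_000.0   # quit attempters currently using e-cigs
EXPOSED_NEVER_SMOKERS = 3_640_000.0   # never smokers who ever used e-cigs


@dataclass(frozen=True)
class Range:
    lo: float
    hi: float

    def draw(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.lo, self.hi, size=size)


@dataclass
class GeneratorConfig:
    """Plausible-range configuration for the random generator.

    Means are drawn uniformly within each range; optionally a monotone
    age profile is imposed (initiation probability and the daily-smoker
    conversion decline with age of initiation; ever e-cigarette use
    rises through adolescence). SEs are a uniform relative fraction of
    the mean (default 5-20%).
    """

    seed: int = 0
    n_adult_groups: int = 9
    youth_age_range: tuple[int, int] = (12, 29)
    monotone_profiles: bool = True
    rel_se: Range = field(default_factory=lambda: Range(0.05, 0.20))
    adult_population: Range = field(default_factory=lambda: Range(15e6, 23e6))
    prev_smoking: Range = field(default_factory=lambda: Range(0.12, 0.22))
    prev_attempt: Range = field(default_factory=lambda: Range(0.40, 0.60))
    prev_ecig: Range = field(default_factory=lambda: Range(0.08, 0.20))
    ylg: Range = field(default_factory=lambda: Range(3.0, 10.0))
    youth_population: Range = field(default_factory=lambda: Range(4.0e6, 4.6e6))
    prev_never: Range = field(default_factory=lambda: Range(0.60, 0.98))
    prev_ever_ecig: Range = field(default_factory=lambda: Range(0.02, 0.30))
    p_init: Range = field(default_factory=lambda: Range(0.01, 0.08))
    p_daily: Range = field(default_factory=lambda: Range(0.08, 0.35))
    yll: Range = field(default_factory=lambda: Range(8.0, 13.0))
    or_cessation: tuple[float, float, float] = (0.86, 0.54, 1.18)
    or_initiation: tuple[float, float, float] = (3.50, 2.38, 5.16)
    relative_harm: float = 0.05


def _profile(rng: np.random.Generator, rr: Range, n: int,
             direction: int) -> np.ndarray:
    """Means within a range; direction -1/+1 sorts them along age,
    0 leaves them unordered."""
    vals = rr.draw(rng, n)
    if direction > 0:
        return np.sort(vals)
    if direction < 0:
        return np.sort(vals)[::-1]
    return vals


def generate_parameter_set(cfg: GeneratorConfig | None = None) -> ParameterSet:
    """Random valid parameter set; deterministic for a fixed seed."""
    cfg = cfg or GeneratorConfig()
    if cfg.n_adult_groups != len(ADULT_AGE_GROUPS):
        raise ValueError(
            f"n_adult_groups must be {len(ADULT_AGE_GROUPS)} (5-year bins 25-69)")
    lo_age, hi_age = cfg.youth_age_range
    ages = [a for a in YOUTH_AGES if lo_age <= a <= hi_age]
    if not ages:
        raise ValueError("youth_age_range selects no ages in [12,29]")
    rng = np.random.default_rng(cfg.seed)
    mono = cfg.monotone_profiles

    def uq(mean: float) -> UncertainQuantity:
        return UncertainQuantity(mean=mean, se=mean * cfg.rel_se.draw(rng))

    nA = cfg.n_adult_groups
    s = _profile(rng, cfg.prev_smoking, nA, 0)
    q = _profile(rng, cfg.prev_attempt, nA, 0)
    e = _profile(rng, cfg.prev_ecig, nA, 0)
    ylg = _profile(rng, cfg.ylg, nA, -1 if mono else 0)  # gain shrinks with age
    adult = [
        AdultStratum(
            age_group=ADULT_AGE_GROUPS[i],
            population=float(cfg.adult_population.draw(rng)),
            prev_current_smoking=uq(s[i]),
            prev_quit_attempt=uq(q[i]),
            prev_current_ecig=uq(e[i]),
            yl_gained_per_quitter=uq(ylg[i]),
        )
        for i in range(nA)
    ]

    nY = len(ages)
    nvr = _profile(rng, cfg.prev_never, nY, -1 if mono else 0)
    ever = _profile(rng, cfg.prev_ever_ecig, nY, +1 if mono else 0)
    p_init = _profile(rng, cfg.p_init, nY, -1 if mono else 0)
    p_daily = _profile(rng, cfg.p_daily, nY, -1 if mono else 0)
    yll = _profile(rng, cfg.yll, nY, -1 if mono else 0)
    youth = [
        YouthStratum(
            age=ages[i],
            population=float(cfg.youth_population.draw(rng)),
            prev_never_smoking=uq(nvr[i]),
            prev_ever_ecig=uq(ever[i]),
            p_init_baseline=uq(p_init[i]),
            p_daily_35_39=uq(p_daily[i]),
            yl_lost_per_daily_smoker=uq(yll[i]),
        )
        for i in range(nY)
    ]

    def or_uq(spec: tuple[float, float, float]) -> UncertainQuantity:
        mean, lo, hi = spec
        return UncertainQuantity(mean=mean, se=se_from_ci(lo, hi, 0.95))

    ps = ParameterSet(
        adult_strata=adult,
        youth_strata=youth,
        cessation=CessationShared(
            or_cessation=or_uq(cfg.or_cessation),
            w_pharma_aid=uq(0.321),
            p_cess_aid=uq(0.15),
            p_cess_noaid=uq(0.05),
            p_abst_1y_given_6m=uq(0.80),
            p_abst_6y_given_1y=uq(0.60),
            relative_harm=cfg.relative_harm,
        ),
        initiation=InitiationShared(or_initiation=or_uq(cfg.or_initiation)),
        metadata={"source": f"synthetic generator, seed={cfg.seed}",
                  "note": "randomly drawn plausible values for pipeline testing"},
    )
    violations = validate(ps)
    if violations:  # defensive: ranges outside domains
        raise ValueError(f"generated set invalid: {violations}")
    return ps


# Plausible placeholder age profiles for the calibration fixture. The
# populations approximate 2014 US census magnitudes; prevalences and
# life-year weights are round plausible values with the broad age
# patterns seen in national surveys, NOT transcriptions of any source.
_ADULT_POP = np.array([21.5, 21.0, 20.0, 19.7, 20.5, 21.8, 22.0, 18.5, 15.0]) * 1e6
_ADULT_SMOKING = np.array([0.20, 0.21, 0.20, 0.19, 0.19, 0.18, 0.17, 0.15, 0.13])
_ADULT_ATTEMPT = np.array([0.58, 0.56, 0.54, 0.52, 0.50, 0.47, 0.44, 0.42, 0.40])
_ADULT_ECIG_RAW = np.array([0.17, 0.16, 0.15, 0.14, 0.13, 0.12, 0.11, 0.10, 0.09])
_ADULT_YLG = np.array([9.9, 9.0, 8.0, 7.0, 6.1, 5.2, 4.4, 3.7, 3.0])

_YOUTH_POP = np.linspace(4.15e6, 4.55e6, 18)
_YOUTH_NEVER = np.linspace(0.98, 0.62, 18)
_YOUTH_EVER_ECIG_RAW = np.concatenate([
    np.linspace(0.03, 0.24, 8),           # ages 12-19: steep adolescent rise
    np.linspace(0.25, 0.30, 10),          # ages 20-29: plateau
])
_YOUTH_P_INIT = np.concatenate([
    np.linspace(0.030, 0.060, 5),         # 12-16: rising through mid-teens
    np.linspace(0.055, 0.010, 13),        # 17-29: declining
])
_YOUTH_P_DAILY = np.linspace(0.32, 0.10, 18)
_YOUTH_YLL = np.linspace(12.0, 9.5, 18)

_REL_SE = 0.08  # placeholder relative SE for fixture prevalences/weights


def calibration_fixture() -> ParameterSet:
    """Deterministic parameter set pinned to the published 2014 exposure
    aggregates.

    The e-cigarette exposure prevalences are rescaled so that
    Σ Pop·s·q·e = 3,490,000 (adult branch) and Σ Pop·n·v = 3,640,000
    (youth branch) hold exactly; the shared odds ratios, their CIs, and
    the relative harm are the published values. All remaining entries
    are plausible placeholders (see metadata) — they are NOT the model's
    original age-specific inputs, which have no public release.
    """
    adult_agg = float(np.sum(_ADULT_POP * _ADULT_SMOKING * _ADULT_ATTEMPT
                             * _ADULT_ECIG_RAW))
    e = _ADULT_ECIG_RAW * (EXPOSED_ADULT_SMOKERS / adult_agg)
    youth_agg = float(np.sum(_YOUTH_POP * _YOUTH_NEVER * _YOUTH_EVER_ECIG_RAW))
    v = _YOUTH_EVER_ECIG_RAW * (EXPOSED_NEVER_SMOKERS / youth_agg)

    def uq(mean: float, rel: float = _REL_SE) -> UncertainQuantity:
        return UncertainQuantity(mean=float(mean), se=float(mean) * rel)

    adult = [
        AdultStratum(
            age_group=ADULT_AGE_GROUPS[i],
            population=float(_ADULT_POP[i]),
            prev_current_smoking=uq(_ADULT_SMOKING[i], 0.05),
            prev_quit_attempt=uq(_ADULT_ATTEMPT[i], 0.05),
            prev_current_ecig=uq(e[i]),
            yl_gained_per_quitter=uq(_ADULT_YLG[i], 0.10),
        )
        for i in range(9)
    ]
    youth = [
        YouthStratum(
            age=YOUTH_AGES[i],
            population=float(_YOUTH_POP[i]),
            prev_never_smoking=uq(_YOUTH_NEVER[i], 0.03),
            prev_ever_ecig=uq(v[i]),
            p_init_baseline=uq(_YOUTH_P_INIT[i]),
            p_daily_35_39=uq(_YOUTH_P_DAILY[i]),
            yl_lost_per_daily_smoker=uq(_YOUTH_YLL[i], 0.10),
        )
        for i in range(18)
    ]
    return ParameterSet(
        adult_strata=adult,
        youth_strata=youth,
        cessation=CessationShared(
            or_cessation=UncertainQuantity(0.86, se_from_ci(0.54, 1.18, 0.95)),
            w_pharma_aid=uq(0.321, 0.05),
            p_cess_aid=uq(0.15),
            p_cess_noaid=uq(0.05),
            p_abst_1y_given_6m=uq(0.80, 0.05),
            p_abst_6y_given_1y=uq(0.60, 0.05),
            relative_harm=0.05,
        ),
        initiation=InitiationShared(
            or_initiation=UncertainQuantity(3.50, se_from_ci(2.38, 5.16, 0.95))),
        metadata={
            "source": "synthetic calibration fixture",
            "note": ("exposure aggregates pinned to the published 2014 totals "
                     "(3,490,000 adult; 3,640,000 youth) and shared odds "
                     "ratios to their published CIs; every other value is a "
                     "plausible placeholder, not a source value"),
        },
    )


_DOMAIN_CAPS = {"prob": 1.0}


def perturb(ps: ParameterSet, seed: int, relative_jitter: float) -> ParameterSet:
    """Multiplicatively jitter every uncertain mean within its domain.

    Each mean is multiplied by (1 + jitter·u), u ~ Uniform(-1, 1), then
    clipped to its domain; jitter 0 is the identity. For robustness
    testing of downstream code against input wiggle.
    """
    if relative_jitter < 0:
        raise ValueError("jitter must be nonnegative")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(ps)

    def jit(uq: UncertainQuantity, cap: float | None = None) -> UncertainQuantity:
        m = uq.mean * (1.0 + relative_jitter * rng.uniform(-1.0, 1.0))
        m = max(m, 0.0)
        if cap is not None:
            m = min(m, cap)
        return UncertainQuantity(mean=m, se=uq.se)

    import dataclasses as dc
    out.adult_strata = [
        dc.replace(
            st,
            prev_current_smoking=jit(st.prev_current_smoking, 1.0),
            prev_quit_attempt=jit(st.prev_quit_attempt, 1.0),
            prev_current_ecig=jit(st.prev_current_ecig, 1.0),
            yl_gained_per_quitter=jit(st.yl_gained_per_quitter),
        )
        for st in ps.adult_strata
    ]
    out.youth_strata = [
        dc.replace(
            st,
            prev_never_smoking=jit(st.prev_never_smoking, 1.0),
            prev_ever_ecig=jit(st.prev_ever_ecig, 1.0),
            p_init_baseline=jit(st.p_init_baseline, 1.0),
            p_daily_35_39=jit(st.p_daily_35_39, 1.0),
            yl_lost_per_daily_smoker=jit(st.yl_lost_per_daily_smoker),
        )
        for st in ps.youth_strata
    ]
    out.cessation = dc.replace(
        ps.cessation,
        or_cessation=jit(ps.cessation.or_cessation),
        w_pharma_aid=jit(ps.cessation.w_pharma_aid, 1.0),
        p_cess_aid=jit(ps.cessation.p_cess_aid, 1.0),
        p_cess_noaid=jit(ps.cessation.p_cess_noaid, 1.0),
        p_abst_1y_given_6m=jit(ps.cessation.p_abst_1y_given_6m, 1.0),
        p_abst_6y_given_1y=jit(ps.cessation.p_abst_6y_given_1y, 1.0),
    )
    out.initiation = dc.replace(
        ps.initiation, or_initiation=jit(ps.initiation.or_initiation))
    return out
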