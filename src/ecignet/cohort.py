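"""Deterministic cohort accounting: the two multiplicative chains.

Benefit branch (adults 25-69 in 5-year groups). For age group a,

    ΔQ_a = Pop_a · s_a · q_a · e_a · Δcess · p_{1y|6m} · p_{6y|1y}

is the additional number of current smokers who quit through e-cigarette
use and stay abstinent ≥7 years, where s = current-smoking prevalence,
q = past-year quit-attempt prevalence among smokers, e = current
e-cigarette use among attempters, and Δcess the cessation-probability
difference. The companion baseline count Q0_a replaces Δcess with the
reference cessation probability: the e-cigarette-using quitters who
would have quit anyway. Life years:

    B = Σ_a YLG_a · [ (1-h)·ΔQ_a − h·Q0_a·1{penalty} ]

with h the residual harm of e-cigarettes relative to cigarettes. The
dilution penalty term −h·Q0_a·YLG_a (on by default) charges continuing
e-cigarette use its residual harm among quitters who did not need
e-cigarettes to quit.

Harm branch (youth 12-29 by single year). For age a,

    ΔI_a = Pop_a · n_a · v_a · Δinit_a · d_a

is the additional number of never-smokers who initiate through ever
e-cigarette use and are daily smokers at 35-39 (n = never-smoking
prevalence, v = ever e-cigarette use among never smokers, d = daily
conversion probability), and H = −Σ_a ΔI_a · YLL_a ≤ 0.

Net life years = B + H; negative net years are years of life lost.

All chain arithmetic broadcasts: stratum parameters may be shape (A,)
(one realization) or (A, n) (n Monte Carlo draws as columns), shared
parameters scalar or shape (n,). Counts are real-valued expectations;
rounding happens only at report formatting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ecignet.parameters import ParameterSet
from ecignet.transitions import apply_or_to_prob, baseline_cessation_prob


@dataclass
class Realization:
    """A parameter set with every uncertain quantity replaced by plain
    values: scalars/means for a point evaluation, or arrays with one
    column per Monte Carlo draw."""

    adult_age_groups: list[str]
    adult_population: np.ndarray  # (A,), fixed
    prev_smoking: np.ndarray      # (A,) or (A, n)
    prev_attempt: np.ndarray
    prev_ecig: np.ndarray
    ylg: np.ndarray

    youth_ages: list[int]
    youth_population: np.ndarray  # (Y,), fixed
    prev_never: np.ndarray        # (Y,) or (Y, n)
    prev_ever_ecig: np.ndarray
    p_init: np.ndarray
    p_daily: np.ndarray
    yll: np.ndarray

    or_cessation: Any             # scalar or (n,)
    w_pharma_aid: Any
    p_cess_aid: Any
    p_cess_noaid: Any
    p_abst_1y_given_6m: Any
    p_abst_6y_given_1y: Any
    or_initiation: Any
    relative_harm: float = 0.05


@dataclass
class BranchResult:
    """Per-stratum and total expected counts for one branch."""

    per_stratum: dict[str, Any] = field(default_factory=dict)

    @property
    def total(self):
        return sum(self.per_stratum.values())

    @classmethod
    def from_arrays(cls, labels, values: np.ndarray) -> "BranchResult":
        return cls(per_stratum={lab: values[i] for i, lab in enumerate(labels)})


@dataclass
class Outcome:
    """The five model outcomes of one evaluation (scalars or draw vectors)."""

    additional_quitters: Any
    additional_initiators: Any
    benefit_years: Any
    harm_years: Any

    @property
    def net_years(self):
        return self.benefit_years + self.harm_years

    FIELDS = ("additional_quitters", "additional_initiators",
              "benefit_years", "harm_years", "net_years")

    def as_dict(self) -> dict[str, Any]:
        return {name: getattr(self, name) for name in self.FIELDS}


def _per_iter(pop: np.ndarray, like: np.ndarray) -> np.ndarray:
    # lift the fixed (A,) population to (A, 1) when parameters carry draws
    return pop[:, None] if np.ndim(like) == 2 else pop


def realize_point(ps: ParameterSet) -> Realization:
    """Realization with every uncertain quantity at its mean."""
    return Realization(
        adult_age_groups=[st.age_group for st in ps.adult_strata],
        adult_population=np.array([st.population for st in ps.adult_strata], float),
        prev_smoking=np.array([st.prev_current_smoking.mean for st in ps.adult_strata]),
        prev_attempt=np.array([st.prev_quit_attempt.mean for st in ps.adult_strata]),
        prev_ecig=np.array([st.prev_current_ecig.mean for st in ps.adult_strata]),
        ylg=np.array([st.yl_gained_per_quitter.mean for st in ps.adult_strata]),
        youth_ages=[st.age for st in ps.youth_strata],
        youth_population=np.array([st.population for st in ps.youth_strata], float),
        prev_never=np.array([st.prev_never_smoking.mean for st in ps.youth_strata]),
        prev_ever_ecig=np.array([st.prev_ever_ecig.mean for st in ps.youth_strata]),
        p_init=np.array([st.p_init_baseline.mean for st in ps.youth_strata]),
        p_daily=np.array([st.p_daily_35_39.mean for st in ps.youth_strata]),
        yll=np.array([st.yl_lost_per_daily_smoker.mean for st in ps.youth_strata]),
        or_cessation=ps.cessation.or_cessation.mean,
        w_pharma_aid=ps.cessation.w_pharma_aid.mean,
        p_cess_aid=ps.cessation.p_cess_aid.mean,
        p_cess_noaid=ps.cessation.p_cess_noaid.mean,
        p_abst_1y_given_6m=ps.cessation.p_abst_1y_given_6m.mean,
        p_abst_6y_given_1y=ps.cessation.p_abst_6y_given_1y.mean,
        or_initiation=ps.initiation.or_initiation.mean,
        relative_harm=ps.cessation.relative_harm,
    )


def cessation_probs(r: Realization):
    """(p_reference, p_exposed) for the cessation branch of ``r``."""
    p_ref = baseline_cessation_prob(r.w_pharma_aid, r.p_cess_aid, r.p_cess_noaid)
    p_exp = apply_or_to_prob(p_ref, r.or_cessation)
    return p_ref, p_exp


def additional_quitters(r: Realization) -> tuple[BranchResult, BranchResult]:
    """Benefit-branch counts: (ΔQ, Q0).

    ΔQ = additional ≥7-year quitters attributable to e-cigarette use;
    Q0 = baseline ≥7-year quitters among the same e-cigarette users (the
    quitters who would have quit without e-cigarettes).
    """
    p_ref, p_exp = cessation_probs(r)
    persistence = np.multiply(r.p_abst_1y_given_6m, r.p_abst_6y_given_1y)
    pop = _per_iter(r.adult_population, r.prev_smoking)
    exposure = pop * r.prev_smoking * r.prev_attempt * r.prev_ecig
    dq = exposure * (p_exp - p_ref) * persistence
    q0 = exposure * p_ref * persistence
    return (BranchResult.from_arrays(r.adult_age_groups, dq),
            BranchResult.from_arrays(r.adult_age_groups, q0))


def additional_initiators(r: Realization) -> BranchResult:
    """Harm-branch counts ΔI: additional initiators who become daily
    smokers at 35-39, per single year of age."""
    pop = _per_iter(r.youth_population, r.prev_never)
    p_exp = apply_or_to_prob(r.p_init, r.or_initiation)
    di = pop * r.prev_never * r.prev_ever_ecig * (p_exp - r.p_init) * r.p_daily
    return BranchResult.from_arrays(r.youth_ages, di)


def benefit_years(delta_q: BranchResult, baseline_q0: BranchResult,
                  ylg: np.ndarray, relative_harm: float,
                  include_dilution_penalty: bool = True):
    """Life years gained in the benefit branch.

    B = Σ_a YLG_a · [(1-h)·ΔQ_a − h·Q0_a·1{penalty}]. Non-increasing in
    h; equals Σ ΔQ·YLG at h = 0 with the penalty off.
    """
    h = relative_harm
    if np.any(np.asarray(h) < 0) or np.any(np.asarray(h) > 1):
        raise ValueError("relative harm must lie in [0,1]")
    labels = list(delta_q.per_stratum)
    total = 0.0
    for i, lab in enumerate(labels):
        term = (1.0 - h) * delta_q.per_stratum[lab]
        if include_dilution_penalty:
            term = term - h * baseline_q0.per_stratum[lab]
        total = total + ylg[i] * term
    return total


def harm_years(delta_i: BranchResult, yll: np.ndarray):
    """Life years in the harm branch: H = −Σ_a ΔI_a · YLL_a (≤ 0 when
    ΔI, YLL ≥ 0)."""
    labels = list(delta_i.per_stratum)
    total = 0.0
    for i, lab in enumerate(labels):
        total = total + delta_i.per_stratum[lab] * yll[i]
    return -total


def evaluate(r: Realization, include_dilution_penalty: bool = True) -> Outcome:
    """Full chain on one realization (or a vectorized batch of draws)."""
    dq, q0 = additional_quitters(r)
    di = additional_initiators(r)
    b = benefit_years(dq, q0, r.ylg, r.relative_harm, include_dilution_penalty)
    h = harm_years(di, r.yll)
    return Outcome(additional_quitters=dq.total, additional_initiators=di.total,
                   benefit_years=b, harm_years=h)


def point_estimate(ps: ParameterSet,
                   include_dilution_penalty: bool = True) -> Outcome:
    """Outcome with every uncertain quantity at its mean."""
    return evaluate(realize_point(ps), include_dilution_penalty)
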