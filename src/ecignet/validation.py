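"""One-year intermediate-outcome validation.

The full model tracks multi-year outcomes that cannot be observed for
years; as a nearer-term check, the first year of each branch can be
compared with observation. The predictors below compute the *total*
one-year counts — ≥6-month quitters among all current smokers who tried
to quit (both e-cigarette users and non-users; no 1-year / 6-year
persistence, no life years) and smoking initiators among all never
smokers (both ever and never e-cigarette users) — from a prior-year
parameter set. The Monte Carlo distribution of each prediction supplies
its standard error, and a two-sample z-test with independent SEs
compares prediction with observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ecignet.cohort import Realization, _per_iter, cessation_probs, realize_point
from ecignet.parameters import ParameterSet, SimConfig
from ecignet.transitions import apply_or_to_prob
from ecignet.uncertainty import draw_realization


def predict_quitters_one_year(r: Realization):
    """Expected ≥6-month quitters in one year among all quit attempters.

    Σ_a Pop_a · s_a · q_a · [e_a · p_exposed + (1 − e_a) · p_reference].
    """
    p_ref, p_exp = cessation_probs(r)
    pop = _per_iter(r.adult_population, r.prev_smoking)
    mix = r.prev_ecig * p_exp + (1.0 - r.prev_ecig) * p_ref
    return np.sum(pop * r.prev_smoking * r.prev_attempt * mix, axis=0)


def predict_initiators_one_year(r: Realization):
    """Expected smoking initiators in one year among all never smokers.

    Σ_a Pop_a · n_a · [v_a · p_exposed,a + (1 − v_a) · p_baseline,a].
    """
    p_exp = apply_or_to_prob(r.p_init, r.or_initiation)
    pop = _per_iter(r.youth_population, r.prev_never)
    mix = r.prev_ever_ecig * p_exp + (1.0 - r.prev_ever_ecig) * r.p_init
    return np.sum(pop * r.prev_never * mix, axis=0)


@dataclass(frozen=True)
class ValidationComparison:
    """Predicted vs observed count with a two-sample z-test."""

    predicted_mean: float
    predicted_se: float
    observed_mean: float
    observed_se: float

    @property
    def z(self) -> float:
        denom = float(np.hypot(self.predicted_se, self.observed_se))
        if denom == 0:
            if self.predicted_mean != self.observed_mean:
                raise ValueError("degenerate comparison: both SEs are zero "
                                 "and means differ")
            return 0.0
        return float((self.predicted_mean - self.observed_mean) / denom)

    @property
    def p_two_sided(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))


def compare_to_observed(predicted_mean: float, predicted_se: float,
                        observed_mean: float, observed_se: float
                        ) -> ValidationComparison:
    """Two-sided normal test of predicted vs observed counts.

    z = (predicted − observed) / sqrt(se_pred² + se_obs²). Equal means
    give z = 0, p = 1; both SEs zero with unequal means is degenerate.
    """
    if predicted_se < 0 or observed_se < 0:
        raise ValueError("standard errors must be nonnegative")
    if predicted_se == 0 and observed_se == 0 and predicted_mean != observed_mean:
        raise ValueError("degenerate comparison: both SEs zero and means differ")
    return ValidationComparison(predicted_mean=float(predicted_mean),
                                predicted_se=float(predicted_se),
                                observed_mean=float(observed_mean),
                                observed_se=float(observed_se))


def run_validation(ps: ParameterSet, cfg: SimConfig,
                   observed: dict[str, tuple[float, float]]
                   ) -> dict[str, ValidationComparison]:
    """Monte Carlo one-year predictions compared with observed counts.

    ``observed`` maps 'quitters' and/or 'initiators' to (mean, se)
    observed counts. Predicted SE is the SD of the prediction across
    iterations.
    """
    r, _ = draw_realization(ps, cfg.seed, n=cfg.n_iterations,
                            truncation_policy=cfg.truncation_policy)
    preds = {
        "quitters": predict_quitters_one_year(r),
        "initiators": predict_initiators_one_year(r),
    }
    out: dict[str, ValidationComparison] = {}
    for key, (obs_mean, obs_se) in observed.items():
        if key not in preds:
            raise KeyError(f"unknown validation outcome {key!r}; "
                           "expected 'quitters' or 'initiators'")
        v = np.asarray(preds[key], float)
        se = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        out[key] = compare_to_observed(float(np.mean(v)), se, obs_mean, obs_se)
    return out
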