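"""Odds-ratio / relative-risk calculus for transition probabilities.

Published effect sizes enter the model as odds ratios. An odds ratio is
applied to a baseline transition probability on the odds scale,

    p' = OR * p / (1 - p + OR * p),

yielding the exposed-group probability, and the model works with the
difference Δ = p' - p: the excess (or deficit) one-period transition
probability attributable to e-cigarette exposure, for both ≥6-month
smoking cessation (adults) and smoking initiation (youth).

All functions are pure and accept scalars or numpy arrays elementwise,
so the same code path serves the deterministic point estimate and the
vectorized Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ArrayLike = "float | np.ndarray"


@dataclass(frozen=True)
class TransitionDelta:
    """Reference and exposed transition probabilities and their difference."""

    p_reference: "float | np.ndarray"
    p_exposed: "float | np.ndarray"

    @property
    def delta(self):
        return self.p_exposed - self.p_reference


def apply_or_to_prob(p, or_):
    """Convert a baseline probability to the exposed-group probability.

    p' = OR*p / (1 - p + OR*p). Identity at OR = 1; strictly increasing
    in OR for 0 < p < 1; maps [0, 1] into [0, 1].
    """
    p = np.asarray(p, dtype=float) if np.ndim(p) else float(p)
    if np.any(np.asarray(or_) <= 0):
        raise ValueError("odds ratio must be positive")
    num = np.multiply(or_, p)
    return num / (1.0 - p + num)


def rr_to_or(rr, p_control):
    """Convert a relative risk to an odds ratio at a given control risk.

    OR = [rr*p/(1 - rr*p)] / [p/(1 - p)]. Approaches rr as p_control → 0.
    E.g. a cessation RR of 1.26 at a 5.8% control risk gives OR 1.28.
    """
    rr = np.asarray(rr, dtype=float) if np.ndim(rr) else float(rr)
    p = np.asarray(p_control, dtype=float) if np.ndim(p_control) else float(p_control)
    if np.any(np.asarray(p) <= 0) or np.any(np.asarray(p) >= 1):
        raise ValueError("p_control must lie strictly inside (0, 1)")
    p_treat = np.multiply(rr, p)
    if np.any(np.asarray(p_treat) >= 1):
        raise ValueError("treatment risk >= 1")
    return (p_treat / (1.0 - p_treat)) / (p / (1.0 - p))


def or_to_rr(or_, p_control):
    """Inverse of :func:`rr_to_or`: the relative risk implied by an odds
    ratio at a given control risk."""
    p_exposed = apply_or_to_prob(p_control, or_)
    return p_exposed / p_control


def baseline_cessation_prob(w_aid, p_aid, p_noaid):
    """Reference ≥6-month cessation probability among quit attempters.

    A two-component mixture over pharmaceutical-aid use during the quit
    attempt: w_aid * p_aid + (1 - w_aid) * p_noaid.
    """
    return np.multiply(w_aid, p_aid) + np.multiply(1.0 - np.asarray(w_aid), p_noaid)


def _plain(v):
    # accept an UncertainQuantity (point use) or an already-drawn value
    return v.mean if hasattr(v, "mean") and hasattr(v, "se") else v


def delta_cessation(shared) -> TransitionDelta:
    """Δ transition probability of ≥6-month cessation.

    Difference between quit attempters who use e-cigarettes as a
    cessation tool (mixture baseline pushed through the cessation OR)
    and those who do not (the mixture baseline itself). Negative when
    OR < 1.

    ``shared`` is any object with attributes ``or_cessation``,
    ``w_pharma_aid``, ``p_cess_aid`` and ``p_cess_noaid``, each either an
    :class:`~ecignet.parameters.UncertainQuantity` (its mean is used) or
    an already-realized value/array.
    """
    p_ref = baseline_cessation_prob(
        _plain(shared.w_pharma_aid), _plain(shared.p_cess_aid),
        _plain(shared.p_cess_noaid))
    p_exp = apply_or_to_prob(p_ref, _plain(shared.or_cessation))
    return TransitionDelta(p_reference=p_ref, p_exposed=p_exp)


def delta_initiation(p_baseline, or_initiation) -> TransitionDelta:
    """Δ transition probability of smoking initiation at one age.

    Difference between never-smokers who have ever used e-cigarettes
    (age-specific baseline pushed through the pooled initiation OR) and
    those who never have. Nonnegative iff OR >= 1; zero at zero baseline.
    """
    p_exp = apply_or_to_prob(p_baseline, or_initiation)
    return TransitionDelta(p_reference=p_baseline, p_exposed=p_exp)
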