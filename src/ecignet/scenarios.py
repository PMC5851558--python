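"""Sensitivity machinery: scenario transforms, sweeps and surfaces.

A scenario either *scales* a parameter (mean and SE multiply by the
factor, so a published CI scales proportionally — scaling the initiation
OR 3.50 (2.38-5.16) by 0.9 gives 3.15 (2.14-4.64)) or *sets* it to a
fixed value (SE forced to 0: the parameter is supposed known, all other
parameters keep their baseline distributions).

All sweeps use matched seeds: every grid point re-runs the Monte Carlo
with the same master seed, so each iteration reuses identical underlying
standard-normal deviates and differences across grid points are free of
sampling noise. That makes the structural monotonicities (net years
non-increasing in relative harm; probability of net benefit
non-decreasing in the cessation OR and non-increasing in the initiation
OR) hold draw by draw, not just on average.
"""

from __future__ import annotations

import copy
import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ecignet.parameters import ParameterSet, SimConfig, UncertainQuantity
from ecignet.uncertainty import (OutcomeSummary, format_sig, prob_positive,
                                 run_monte_carlo, summarize)

SCENARIO_TARGETS = ("or_cessation", "or_initiation", "prev_current_ecig",
                    "prev_ever_ecig", "relative_harm")


@dataclass(frozen=True)
class ScenarioSpec:
    """One parameter transformation.

    target: which parameter (the four key sensitivity parameters or the
    relative harm); mode: 'scale' (multiply mean and SE) or 'set' (fix
    the value, SE = 0); value: the factor or the fixed value.
    """

    target: str
    mode: str
    value: float
    label: str = ""

    def __post_init__(self):
        if self.target not in SCENARIO_TARGETS:
            raise ValueError(
                f"unknown scenario target {self.target!r}; "
                f"choose from {SCENARIO_TARGETS}")
        if self.mode not in ("scale", "set"):
            raise ValueError("mode must be 'scale' or 'set'")
        if self.mode == "scale" and self.value <= 0:
            raise ValueError("scale factor must be positive")


def _transform_uq(uq: UncertainQuantity, spec: ScenarioSpec,
                  is_proportion: bool, where: str,
                  notes: list[str]) -> UncertainQuantity:
    if spec.mode == "scale":
        mean, se = uq.mean * spec.value, uq.se * spec.value
    else:
        mean, se = float(spec.value), 0.0
    if is_proportion and mean > 1.0:
        notes.append(f"{where}: scaled mean {mean:.6g} clipped to 1")
        mean = 1.0
    if is_proportion and mean < 0.0:
        notes.append(f"{where}: scaled mean {mean:.6g} clipped to 0")
        mean = 0.0
    return UncertainQuantity(mean=mean, se=se)


def apply_scenario(ps: ParameterSet, spec: ScenarioSpec) -> ParameterSet:
    """Return a transformed copy of ``ps``; the input is untouched.

    Prevalence targets transform every stratum's quantity, with
    post-hoc clipping of out-of-range means to [0, 1] (recorded in the
    returned set's metadata and warned once).
    """
    out = copy.deepcopy(ps)
    notes: list[str] = []
    if spec.target == "relative_harm":
        value = (ps.cessation.relative_harm * spec.value
                 if spec.mode == "scale" else float(spec.value))
        if not 0.0 <= value <= 1.0:
            raise ValueError("relative harm must lie in [0,1]")
        out.cessation = dataclasses.replace(out.cessation, relative_harm=value)
    elif spec.target == "or_cessation":
        out.cessation = dataclasses.replace(
            out.cessation,
            or_cessation=_transform_uq(ps.cessation.or_cessation, spec, False,
                                       "cessation.or_cessation", notes))
    elif spec.target == "or_initiation":
        out.initiation = dataclasses.replace(
            out.initiation,
            or_initiation=_transform_uq(ps.initiation.or_initiation, spec, False,
                                        "initiation.or_initiation", notes))
    elif spec.target == "prev_current_ecig":
        out.adult_strata = [
            dataclasses.replace(
                st, prev_current_ecig=_transform_uq(
                    st.prev_current_ecig, spec, True,
                    f"adult[{st.age_group}].prev_ecig", notes))
            for st in ps.adult_strata
        ]
    elif spec.target == "prev_ever_ecig":
        out.youth_strata = [
            dataclasses.replace(
                st, prev_ever_ecig=_transform_uq(
                    st.prev_ever_ecig, spec, True,
                    f"youth[{st.age}].prev_ever_ecig", notes))
            for st in ps.youth_strata
        ]
    if notes:
        warnings.warn("scenario clipping: " + "; ".join(notes))
        out.metadata = dict(out.metadata, scenario_clipping=notes)
    return out


@dataclass
class SweepResult:
    """Per-grid-point Monte Carlo summaries for one swept parameter."""

    target: str
    grid: list[float]
    summaries: list[OutcomeSummary]
    prob_positive: list[float]
    labels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tidy rows: scenario,target,value,outcome,mean,ci_lower,
        ci_upper,prob_positive."""
        rows = []
        for i, v in enumerate(self.grid):
            label = self.labels[i] if self.labels else f"{self.target}={v:g}"
            s = self.summaries[i]
            for name in s.mean:
                rows.append({
                    "scenario": label, "target": self.target, "value": v,
                    "outcome": name, "mean": s.mean[name],
                    "ci_lower": s.ci_lower[name], "ci_upper": s.ci_upper[name],
                    "prob_positive": self.prob_positive[i],
                })
        return pd.DataFrame(rows)


DEFAULT_HARM_GRID = tuple(np.round(np.linspace(0.0, 1.0, 21), 10))


def harm_sweep(ps: ParameterSet, cfg: SimConfig,
               h_grid: Sequence[float] = DEFAULT_HARM_GRID) -> SweepResult:
    """Sweep the relative harm of e-cigarettes over ``h_grid`` in [0, 1].

    One full matched-seed Monte Carlo per grid point; the point at the
    baseline h reproduces the base-case run exactly.
    """
    h_grid = [float(h) for h in h_grid]
    if any(h < 0 or h > 1 for h in h_grid):
        raise ValueError("relative harm values must lie in [0,1]")
    summaries, probs = [], []
    for h in h_grid:
        ps_h = apply_scenario(ps, ScenarioSpec("relative_harm", "set", h))
        draws = run_monte_carlo(ps_h, cfg)
        summaries.append(summarize(draws, cfg.ci_level,
                                   sig_digits=cfg.report_sig_digits))
        probs.append(prob_positive(draws))
    return SweepResult(target="relative_harm", grid=h_grid,
                       summaries=summaries, prob_positive=probs)


def prob_surface(ps: ParameterSet, cfg: SimConfig, target: str,
                 multiplier_grid: Sequence[float],
                 mode: str = "scale") -> SweepResult:
    """Probability of positive net life years along a parameter grid.

    For each multiplier m, transform the target (default: scale its
    mean and SE by m), re-run the matched-seed Monte Carlo and record
    P(net years > 0). With ``mode='set'`` the target is fixed at
    m × its baseline mean instead (supposed known, SE 0).
    """
    grid = [float(m) for m in multiplier_grid]
    if any(m <= 0 for m in grid):
        raise ValueError("multipliers must be positive")
    base_mean = {
        "or_cessation": ps.cessation.or_cessation.mean,
        "or_initiation": ps.initiation.or_initiation.mean,
    }
    summaries, probs = [], []
    for m in grid:
        if mode == "scale":
            spec = ScenarioSpec(target, "scale", m)
        else:
            if target not in base_mean:
                raise ValueError(f"mode='set' surface unsupported for {target!r}")
            spec = ScenarioSpec(target, "set", m * base_mean[target])
        draws = run_monte_carlo(apply_scenario(ps, spec), cfg)
        summaries.append(summarize(draws, cfg.ci_level,
                                   sig_digits=cfg.report_sig_digits))
        probs.append(prob_positive(draws))
    return SweepResult(target=target, grid=grid, summaries=summaries,
                       prob_positive=probs)


def _param_point_ci(ps: ParameterSet, target: str, ci_level: float) -> str:
    if target == "or_cessation":
        uq = ps.cessation.or_cessation
    elif target == "or_initiation":
        uq = ps.initiation.or_initiation
    elif target == "relative_harm":
        return f"{ps.cessation.relative_harm:g}"
    else:
        return "Age-Specific"
    z = stats.norm.ppf((1.0 + ci_level) / 2.0)
    return (f"{uq.mean:.2f} ({uq.mean - z * uq.se:.2f} to "
            f"{uq.mean + z * uq.se:.2f})")


def scenario_table(ps: ParameterSet, cfg: SimConfig,
                   specs: Sequence[ScenarioSpec]) -> pd.DataFrame:
    """Sensitivity table: base case first, one row per scenario.

    Each row carries the transformed parameter's point estimate and CI
    alongside the net-years mean and CI (formatted at the configured
    significant digits) under matched seeds.
    """
    rows = []
    variants = [("Base Case", None, ps)]
    for spec in specs:
        label = spec.label or f"{spec.target} {spec.mode} {spec.value:g}"
        variants.append((label, spec, apply_scenario(ps, spec)))
    for label, spec, ps_v in variants:
        draws = run_monte_carlo(ps_v, cfg)
        s = summarize(draws, cfg.ci_level, sig_digits=cfg.report_sig_digits)
        target = spec.target if spec is not None else "base"
        pt = _param_point_ci(ps_v, spec.target, cfg.ci_level) if spec else ""
        rows.append({
            "scenario": label,
            "target": target,
            "parameter_point_ci": pt,
            "net_years_mean": s.mean["net_years"],
            "net_years_ci_lower": s.ci_lower["net_years"],
            "net_years_ci_upper": s.ci_upper["net_years"],
            "net_years_formatted": s.formatted["net_years"],
            "prob_positive_net": prob_positive(draws),
        })
    return pd.DataFrame(rows)
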