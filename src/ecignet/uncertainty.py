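"""Monte Carlo propagation of parameter uncertainty.

Every uncertain quantity is drawn independently from a normal
distribution N(mean, se); quantities with se = 0 (census counts,
fixed assumptions) are passed through exactly. Out-of-domain draws are
handled by a truncation policy: ``clip`` (default) clips probabilities
to [0, 1], odds ratios to (1e-9, ∞) and life-year weights to [0, ∞),
reporting the fraction of draws altered; ``resample`` redraws
out-of-domain values until they land in-domain.

Reproducibility: one master seed spawns a deterministic substream per
parameter in a fixed enumeration order, and each parameter's whole
length-n vector is drawn in one call. Results are therefore independent
of iteration batching, and two runs that share a seed but differ only in
one parameter's mean/SE (a scenario scaling) use identical underlying
standard-normal deviates for every parameter — the matched-seed coupling
the scenario machinery relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from ecignet import cohort
from ecignet.parameters import ParameterSet, SimConfig, UncertainQuantity

_DOMAINS = {
    "prob": (0.0, 1.0),
    "odds_ratio": (1e-9, np.inf),
    "nonneg": (0.0, np.inf),
    "real": (-np.inf, np.inf),
}

_RESAMPLE_MAX_ROUNDS = 1000


def _enumerate_parameters(ps: ParameterSet) -> Iterator[tuple[str, UncertainQuantity, str]]:
    """Fixed-order enumeration (key, quantity, domain) of all sampled
    parameters. The order defines substream assignment and must not
    depend on parameter values."""
    for st in ps.adult_strata:
        g = st.age_group
        yield f"adult[{g}].prev_smoking", st.prev_current_smoking, "prob"
        yield f"adult[{g}].prev_attempt", st.prev_quit_attempt, "prob"
        yield f"adult[{g}].prev_ecig", st.prev_current_ecig, "prob"
        yield f"adult[{g}].ylg", st.yl_gained_per_quitter, "nonneg"
    for st in ps.youth_strata:
        a = st.age
        yield f"youth[{a}].prev_never", st.prev_never_smoking, "prob"
        yield f"youth[{a}].prev_ever_ecig", st.prev_ever_ecig, "prob"
        yield f"youth[{a}].p_init", st.p_init_baseline, "prob"
        yield f"youth[{a}].p_daily", st.p_daily_35_39, "prob"
        yield f"youth[{a}].yll", st.yl_lost_per_daily_smoker, "nonneg"
    c = ps.cessation
    yield "cessation.or_cessation", c.or_cessation, "odds_ratio"
    yield "cessation.w_pharma_aid", c.w_pharma_aid, "prob"
    yield "cessation.p_cess_aid", c.p_cess_aid, "prob"
    yield "cessation.p_cess_noaid", c.p_cess_noaid, "prob"
    yield "cessation.p_abst_1y_given_6m", c.p_abst_1y_given_6m, "prob"
    yield "cessation.p_abst_6y_given_1y", c.p_abst_6y_given_1y, "prob"
    yield "initiation.or_initiation", ps.initiation.or_initiation, "odds_ratio"


def draw_realization(ps: ParameterSet, seed: int, n: int = 1,
                     truncation_policy: str = "clip",
                     ) -> tuple[cohort.Realization, float]:
    """Draw ``n`` independent realizations of every uncertain quantity.

    Returns (realization, clip_rate). The realization's stratum fields
    have shape (A, n) / (Y, n) and shared fields shape (n,); it is a
    pure function of (ps, seed, n, truncation_policy). clip_rate is the
    fraction of sampled values altered by truncation (0 under
    ``resample``, which redraws instead of altering).
    """
    params = list(_enumerate_parameters(ps))
    children = np.random.SeedSequence(seed).spawn(len(params))
    values: dict[str, np.ndarray] = {}
    n_altered = 0
    n_sampled = 0
    for (key, uq, domain), child in zip(params, children):
        rng = np.random.Generator(np.random.PCG64(child))
        z = rng.standard_normal(n)
        if uq.se == 0.0:
            values[key] = np.full(n, uq.mean)
            continue
        raw = uq.mean + uq.se * z
        lo, hi = _DOMAINS[domain]
        if truncation_policy == "clip":
            clipped = np.clip(raw, lo, hi)
            n_altered += int(np.count_nonzero(clipped != raw))
            values[key] = clipped
        elif truncation_policy == "resample":
            bad = (raw < lo) | (raw > hi)
            rounds = 0
            while bad.any():
                rounds += 1
                if rounds > _RESAMPLE_MAX_ROUNDS:
                    raise RuntimeError(
                        f"resampling {key} did not land in-domain after "
                        f"{_RESAMPLE_MAX_ROUNDS} rounds")
                raw[bad] = uq.mean + uq.se * rng.standard_normal(int(bad.sum()))
                bad = (raw < lo) | (raw > hi)
            values[key] = raw
        else:
            raise ValueError(f"unknown truncation policy {truncation_policy!r}")
        n_sampled += n
    clip_rate = n_altered / n_sampled if n_sampled else 0.0

    def stack(kind: str, labels, name: str) -> np.ndarray:
        return np.stack([values[f"{kind}[{lab}].{name}"] for lab in labels])

    adult_labels = [st.age_group for st in ps.adult_strata]
    youth_labels = [st.age for st in ps.youth_strata]
    r = cohort.Realization(
        adult_age_groups=adult_labels,
        adult_population=np.array([st.population for st in ps.adult_strata], float),
        prev_smoking=stack("adult", adult_labels, "prev_smoking"),
        prev_attempt=stack("adult", adult_labels, "prev_attempt"),
        prev_ecig=stack("adult", adult_labels, "prev_ecig"),
        ylg=stack("adult", adult_labels, "ylg"),
        youth_ages=youth_labels,
        youth_population=np.array([st.population for st in ps.youth_strata], float),
        prev_never=stack("youth", youth_labels, "prev_never"),
        prev_ever_ecig=stack("youth", youth_labels, "prev_ever_ecig"),
        p_init=stack("youth", youth_labels, "p_init"),
        p_daily=stack("youth", youth_labels, "p_daily"),
        yll=stack("youth", youth_labels, "yll"),
        or_cessation=values["cessation.or_cessation"],
        w_pharma_aid=values["cessation.w_pharma_aid"],
        p_cess_aid=values["cessation.p_cess_aid"],
        p_cess_noaid=values["cessation.p_cess_noaid"],
        p_abst_1y_given_6m=values["cessation.p_abst_1y_given_6m"],
        p_abst_6y_given_1y=values["cessation.p_abst_6y_given_1y"],
        or_initiation=values["initiation.or_initiation"],
        relative_harm=ps.cessation.relative_harm,
    )
    return r, clip_rate


@dataclass
class OutcomeDraws:
    """Per-iteration vectors of the five outcomes plus run metadata."""

    n: int
    additional_quitters: np.ndarray
    additional_initiators: np.ndarray
    benefit_years: np.ndarray
    harm_years: np.ndarray
    net_years: np.ndarray
    seed: int = 0
    truncation_policy: str = "clip"
    clip_rate: float = 0.0

    FIELDS = cohort.Outcome.FIELDS

    def field(self, name: str) -> np.ndarray:
        if name not in self.FIELDS:
            raise KeyError(f"unknown outcome field {name!r}; "
                           f"expected one of {self.FIELDS}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        """One row per iteration, full precision, for external audit."""
        return pd.DataFrame({name: self.field(name) for name in self.FIELDS})


def run_monte_carlo(ps: ParameterSet, cfg: SimConfig) -> OutcomeDraws:
    """Propagate parameter uncertainty through the cohort chain.

    Each iteration draws every parameter independently, recomputes the
    transition deltas and both branch chains, and records the five
    outcomes. Bit-reproducible for a given (ps, cfg).
    """
    r, clip_rate = draw_realization(
        ps, cfg.seed, n=cfg.n_iterations,
        truncation_policy=cfg.truncation_policy)
    out = cohort.evaluate(r, include_dilution_penalty=cfg.include_dilution_penalty)
    return OutcomeDraws(
        n=cfg.n_iterations,
        additional_quitters=np.asarray(out.additional_quitters, float),
        additional_initiators=np.asarray(out.additional_initiators, float),
        benefit_years=np.asarray(out.benefit_years, float),
        harm_years=np.asarray(out.harm_years, float),
        net_years=np.asarray(out.net_years, float),
        seed=cfg.seed,
        truncation_policy=cfg.truncation_policy,
        clip_rate=clip_rate,
    )


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant digits (half away handled by float
    formatting; 0 stays 0)."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{sig}g}")


def format_sig(x: float, sig: int = 3) -> str:
    """Report formatting: 3 significant digits, thousands separators.

    1,513,842 -> '1,510,000'.
    """
    r = round_sig(x, sig)
    if not np.isfinite(r):
        return str(r)
    if r == int(r):
        return f"{int(r):,}"
    return f"{r:,}"


@dataclass
class OutcomeSummary:
    """Means and interval bounds per outcome, plus report strings."""

    mean: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    ci_level: float
    method: str = "percentile"
    sig_digits: int = 3
    formatted: dict[str, str] = field(default_factory=dict)

    def significant(self, name: str) -> bool:
        """True when the interval excludes zero."""
        return self.ci_lower[name] > 0 or self.ci_upper[name] < 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in OutcomeDraws.FIELDS:
            rows.append({
                "outcome": name,
                "mean": self.mean[name],
                "ci_lower": self.ci_lower[name],
                "ci_upper": self.ci_upper[name],
                "formatted": self.formatted[name],
            })
        return pd.DataFrame(rows)


def summarize(draws: OutcomeDraws, ci_level: float = 0.95,
              method: str = "percentile", sig_digits: int = 3) -> OutcomeSummary:
    """Mean and interval per outcome.

    ``percentile`` (default) uses the empirical quantile interval at
    (1 ± ci_level)/2 with numpy's linear interpolation rule
    (quantile method="linear"); ``normal`` uses mean ± z·SD.
    """
    if draws.n < 1:
        raise ValueError("no draws to summarize")
    alpha = (1.0 - ci_level) / 2.0
    mean, lo, hi, fmt = {}, {}, {}, {}
    for name in OutcomeDraws.FIELDS:
        v = draws.field(name)
        m = float(np.mean(v))
        if method == "percentile":
            ql, qh = np.quantile(v, [alpha, 1.0 - alpha], method="linear")
        elif method == "normal":
            from scipy import stats
            z = stats.norm.ppf(1.0 - alpha)
            sd = float(np.std(v, ddof=1)) if draws.n > 1 else 0.0
            ql, qh = m - z * sd, m + z * sd
        else:
            raise ValueError(f"unknown interval method {method!r}")
        mean[name], lo[name], hi[name] = m, float(ql), float(qh)
        fmt[name] = (f"{format_sig(m, sig_digits)} "
                     f"({format_sig(float(ql), sig_digits)} to "
                     f"{format_sig(float(qh), sig_digits)})")
    return OutcomeSummary(mean=mean, ci_lower=lo, ci_upper=hi,
                          ci_level=ci_level, method=method,
                          sig_digits=sig_digits, formatted=fmt)


def prob_positive(draws: OutcomeDraws, name: str = "net_years") -> float:
    """Fraction of iterations with a strictly positive outcome value."""
    v = draws.field(name)
    return float(np.count_nonzero(v > 0) / draws.n)
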