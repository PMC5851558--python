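"""Parameter data model and table I/O.

The model is driven by age-stratified parameter tables: nine 5-year adult
age groups (25-29 through 65-69) for the cessation-benefit branch, and
eighteen single years of age (12 through 29) for the initiation-harm
branch, plus a handful of shared effect sizes and conditional
probabilities. Every sampled parameter is an :class:`UncertainQuantity`:
a point estimate with a standard error, sampled independently from a
normal distribution during Monte Carlo runs. Zero-SE quantities (e.g.
census population counts) are treated as fixed.

Proportions are stored as fractions in [0, 1]. Parameters published as
95% confidence intervals are converted to SEs with the symmetric normal
interval formula (:func:`se_from_ci`), consistent with the normal
sampling model.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
from scipy import stats

ADULT_AGE_GROUPS = tuple(f"{lo}-{lo + 4}" for lo in range(25, 70, 5))
YOUTH_AGES = tuple(range(12, 30))

ADULT_COLUMNS = [
    "age_group", "population",
    "prev_smoking_mean", "prev_smoking_se",
    "prev_attempt_mean", "prev_attempt_se",
    "prev_ecig_mean", "prev_ecig_se",
    "ylg_mean", "ylg_se",
]
YOUTH_COLUMNS = [
    "age", "population",
    "prev_never_mean", "prev_never_se",
    "prev_ever_ecig_mean", "prev_ever_ecig_se",
    "p_init_mean", "p_init_se",
    "p_daily_mean", "p_daily_se",
    "yll_mean", "yll_se",
]


class SchemaError(ValueError):
    """A parameter table does not match the documented column schema."""


class ParseError(ValueError):
    """A parameter table cell could not be parsed as a number."""


class ValidationError(ValueError):
    """A parameter set violates one or more model invariants."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        lines = "; ".join(str(v) for v in violations)
        super().__init__(f"{len(violations)} violation(s): {lines}")


@dataclass(frozen=True)
class UncertainQuantity:
    """A point estimate and its standard error, in the same units.

    The unit of Monte Carlo sampling: each draw is an independent normal
    deviate N(mean, se). se = 0 means the quantity is treated as fixed.
    """

    mean: float
    se: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "mean", float(self.mean))
        object.__setattr__(self, "se", float(self.se))


@dataclass(frozen=True)
class AdultStratum:
    """One 5-year adult age group's inputs for the cessation branch."""

    age_group: str
    population: float
    prev_current_smoking: UncertainQuantity
    prev_quit_attempt: UncertainQuantity  # among current smokers
    prev_current_ecig: UncertainQuantity  # among past-year quit attempters
    yl_gained_per_quitter: UncertainQuantity  # years per long-term quitter


@dataclass(frozen=True)
class YouthStratum:
    """One single year of age's inputs for the initiation branch."""

    age: int
    population: float
    prev_never_smoking: UncertainQuantity
    prev_ever_ecig: UncertainQuantity  # among never smokers
    p_init_baseline: UncertainQuantity  # 1-year initiation, never e-cig users
    p_daily_35_39: UncertainQuantity  # daily smoker at 35-39 | initiation now
    yl_lost_per_daily_smoker: UncertainQuantity


@dataclass(frozen=True)
class CessationShared:
    """Shared cessation-branch parameters.

    The reference ≥6-month cessation probability is an aid/non-aid
    mixture: w_pharma_aid * p_cess_aid + (1 - w_pharma_aid) *
    p_cess_noaid. The e-cigarette effect enters as an odds ratio applied
    to that mixture. relative_harm is the residual harm of e-cigarettes
    as a fraction of cigarette harm (base case 0.05, i.e. 95% relative
    harm reduction); it is a scenario knob, not a sampled quantity.
    """

    or_cessation: UncertainQuantity
    w_pharma_aid: UncertainQuantity
    p_cess_aid: UncertainQuantity
    p_cess_noaid: UncertainQuantity
    p_abst_1y_given_6m: UncertainQuantity
    p_abst_6y_given_1y: UncertainQuantity
    relative_harm: float = 0.05


@dataclass(frozen=True)
class InitiationShared:
    """Shared initiation-branch parameter: the pooled adjusted odds ratio
    of smoking initiation, ever vs never e-cigarette users."""

    or_initiation: UncertainQuantity


@dataclass
class ParameterSet:
    """Complete model input: strata, shared effects, provenance notes."""

    adult_strata: list[AdultStratum]
    youth_strata: list[YouthStratum]
    cessation: CessationShared
    initiation: InitiationShared
    metadata: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class SimConfig:
    """Monte Carlo run configuration."""

    n_iterations: int = 100_000
    seed: int = 0
    ci_level: float = 0.95
    truncation_policy: str = "clip"  # or "resample"
    include_dilution_penalty: bool = True
    report_sig_digits: int = 3

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie strictly inside (0, 1)")
        if self.truncation_policy not in ("clip", "resample"):
            raise ValueError("truncation_policy must be 'clip' or 'resample'")


@dataclass(frozen=True)
class Violation:
    """One invariant violation: where it is, which field, which rule."""

    where: str
    fieldname: str
    rule: str

    def __str__(self) -> str:
        return f"{self.where}.{self.fieldname}: {self.rule}"


def se_from_ci(lower: float, upper: float, level: float = 0.95) -> float:
    """SE implied by a symmetric normal confidence interval.

    Returns (upper - lower) / (2 z) with z the standard-normal quantile
    at (1 + level) / 2. Used to ingest parameters published as CIs, e.g.
    an odds ratio of 3.50 (2.38 to 5.16) gives SE 0.7092.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly inside (0, 1)")
    if upper < lower:
        raise ValueError(f"upper ({upper}) < lower ({lower})")
    z = stats.norm.ppf((1.0 + level) / 2.0)
    return (upper - lower) / (2.0 * z)


def _check_uq(out: list[Violation], where: str, name: str, uq: UncertainQuantity,
              kind: str) -> None:
    if not math.isfinite(uq.mean) or not math.isfinite(uq.se):
        out.append(Violation(where, name, "mean and se must be finite"))
        return
    if uq.se < 0:
        out.append(Violation(where, name, "se must be nonnegative"))
    if kind == "proportion" and not 0.0 <= uq.mean <= 1.0:
        out.append(Violation(where, name, "proportion out of range [0,1]"))
    elif kind == "odds_ratio" and uq.mean <= 0:
        out.append(Violation(where, name, "odds ratio must be positive"))
    elif kind == "years" and uq.mean < 0:
        out.append(Violation(where, name, "life-year weight must be nonnegative"))


def validate(ps: ParameterSet) -> list[Violation]:
    """Check every model invariant; return violations as data, not errors.

    An empty list means the parameter set is valid. Deterministic and
    side-effect free.
    """
    out: list[Violation] = []

    seen_groups: set[str] = set()
    for st in ps.adult_strata:
        w = f"adult[{st.age_group}]"
        if st.age_group in seen_groups:
            out.append(Violation(w, "age_group", "duplicate age group"))
        seen_groups.add(st.age_group)
        if st.age_group not in ADULT_AGE_GROUPS:
            out.append(Violation(w, "age_group",
                                 f"unknown age group (expected one of {ADULT_AGE_GROUPS[0]}..{ADULT_AGE_GROUPS[-1]})"))
        if not (math.isfinite(st.population) and st.population >= 0):
            out.append(Violation(w, "population", "population must be >= 0"))
        _check_uq(out, w, "prev_current_smoking", st.prev_current_smoking, "proportion")
        _check_uq(out, w, "prev_quit_attempt", st.prev_quit_attempt, "proportion")
        _check_uq(out, w, "prev_current_ecig", st.prev_current_ecig, "proportion")
        _check_uq(out, w, "yl_gained_per_quitter", st.yl_gained_per_quitter, "years")

    seen_ages: set[int] = set()
    for st in ps.youth_strata:
        w = f"youth[{st.age}]"
        if st.age in seen_ages:
            out.append(Violation(w, "age", "duplicate age"))
        seen_ages.add(st.age)
        if st.age not in YOUTH_AGES:
            out.append(Violation(w, "age", "age outside [12,29]"))
        if not (math.isfinite(st.population) and st.population >= 0):
            out.append(Violation(w, "population", "population must be >= 0"))
        _check_uq(out, w, "prev_never_smoking", st.prev_never_smoking, "proportion")
        _check_uq(out, w, "prev_ever_ecig", st.prev_ever_ecig, "proportion")
        _check_uq(out, w, "p_init_baseline", st.p_init_baseline, "proportion")
        _check_uq(out, w, "p_daily_35_39", st.p_daily_35_39, "proportion")
        _check_uq(out, w, "yl_lost_per_daily_smoker", st.yl_lost_per_daily_smoker, "years")

    c = ps.cessation
    _check_uq(out, "cessation", "or_cessation", c.or_cessation, "odds_ratio")
    _check_uq(out, "cessation", "w_pharma_aid", c.w_pharma_aid, "proportion")
    _check_uq(out, "cessation", "p_cess_aid", c.p_cess_aid, "proportion")
    _check_uq(out, "cessation", "p_cess_noaid", c.p_cess_noaid, "proportion")
    _check_uq(out, "cessation", "p_abst_1y_given_6m", c.p_abst_1y_given_6m, "proportion")
    _check_uq(out, "cessation", "p_abst_6y_given_1y", c.p_abst_6y_given_1y, "proportion")
    if not 0.0 <= c.relative_harm <= 1.0:
        out.append(Violation("cessation", "relative_harm",
                             "relative harm must lie in [0,1]"))
    _check_uq(out, "initiation", "or_initiation",
              ps.initiation.or_initiation, "odds_ratio")
    return out


def _parse_numeric_column(df: pd.DataFrame, col: str, table: str) -> pd.Series:
    # cell-wise float() keeps full round-trip precision (pandas' fast
    # parsers do not) and pinpoints the offending row
    out = []
    for row, cell in df[col].items():
        try:
            out.append(float(cell))
        except (TypeError, ValueError):
            raise ParseError(
                f"{table} table: non-numeric value {cell!r} in column "
                f"{col!r} at row {row}") from None
    return pd.Series(out, index=df.index, dtype=float)


def _read_table(path: Path, columns: list[str], table: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table {path}: missing column(s) {missing}")
    out = pd.DataFrame(index=df.index)
    for col in columns:
        if col == "age_group":
            out[col] = df[col].astype(str)
        else:
            out[col] = _parse_numeric_column(df, col, table)
    return out


def _uq_from_row(row, prefix: str) -> UncertainQuantity:
    return UncertainQuantity(mean=row[f"{prefix}_mean"], se=row[f"{prefix}_se"])


def read_parameter_set(adult_table_path, youth_table_path,
                       shared_config_path) -> ParameterSet:
    """Read a full parameter set from two CSV tables and a JSON config.

    Raises :class:`SchemaError` for a missing column, :class:`ParseError`
    for a non-numeric cell (with its row index), and
    :class:`ValidationError` if the assembled set violates any invariant.
    """
    adult_df = _read_table(Path(adult_table_path), ADULT_COLUMNS, "adult")
    youth_df = _read_table(Path(youth_table_path), YOUTH_COLUMNS, "youth")

    adult = [
        AdultStratum(
            age_group=row["age_group"],
            population=row["population"],
            prev_current_smoking=_uq_from_row(row, "prev_smoking"),
            prev_quit_attempt=_uq_from_row(row, "prev_attempt"),
            prev_current_ecig=_uq_from_row(row, "prev_ecig"),
            yl_gained_per_quitter=_uq_from_row(row, "ylg"),
        )
        for _, row in adult_df.iterrows()
    ]
    youth = [
        YouthStratum(
            age=int(row["age"]),
            population=row["population"],
            prev_never_smoking=_uq_from_row(row, "prev_never"),
            prev_ever_ecig=_uq_from_row(row, "prev_ever_ecig"),
            p_init_baseline=_uq_from_row(row, "p_init"),
            p_daily_35_39=_uq_from_row(row, "p_daily"),
            yl_lost_per_daily_smoker=_uq_from_row(row, "yll"),
        )
        for _, row in youth_df.iterrows()
    ]

    with open(shared_config_path) as fh:
        cfg = json.load(fh)

    def uq(d: dict) -> UncertainQuantity:
        return UncertainQuantity(mean=d["mean"], se=d.get("se", 0.0))

    cd = cfg["cessation"]
    cessation = CessationShared(
        or_cessation=uq(cd["or_cessation"]),
        w_pharma_aid=uq(cd["w_pharma_aid"]),
        p_cess_aid=uq(cd["p_cess_aid"]),
        p_cess_noaid=uq(cd["p_cess_noaid"]),
        p_abst_1y_given_6m=uq(cd["p_abst_1y_given_6m"]),
        p_abst_6y_given_1y=uq(cd["p_abst_6y_given_1y"]),
        relative_harm=float(cd.get("relative_harm", 0.05)),
    )
    initiation = InitiationShared(or_initiation=uq(cfg["initiation"]["or_initiation"]))

    ps = ParameterSet(
        adult_strata=adult, youth_strata=youth, cessation=cessation,
        initiation=initiation, metadata=cfg.get("metadata", {}),
    )
    violations = validate(ps)
    if violations:
        raise ValidationError(violations)
    return ps


def read_sim_config(shared_config_path) -> SimConfig:
    """Read the SimConfig block of a shared config file (defaults if absent)."""
    with open(shared_config_path) as fh:
        cfg = json.load(fh)
    return SimConfig(**cfg.get("sim", {}))


def write_parameter_set(ps: ParameterSet, out_dir, sim: SimConfig | None = None,
                        require_full_run: bool = False) -> dict[str, Path]:
    """Write ps to ``out_dir`` in the schema :func:`read_parameter_set` reads.

    Floats are written with ``repr`` precision so the round trip is
    lossless. Returns the paths written, keyed 'adult', 'youth', 'shared'.
    """
    if require_full_run and (not ps.adult_strata or not ps.youth_strata):
        raise ValidationError(
            [Violation("parameter_set", "strata", "non-empty strata required")])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    adult_rows = [
        {
            "age_group": st.age_group,
            "population": st.population,
            "prev_smoking_mean": st.prev_current_smoking.mean,
            "prev_smoking_se": st.prev_current_smoking.se,
            "prev_attempt_mean": st.prev_quit_attempt.mean,
            "prev_attempt_se": st.prev_quit_attempt.se,
            "prev_ecig_mean": st.prev_current_ecig.mean,
            "prev_ecig_se": st.prev_current_ecig.se,
            "ylg_mean": st.yl_gained_per_quitter.mean,
            "ylg_se": st.yl_gained_per_quitter.se,
        }
        for st in ps.adult_strata
    ]
    youth_rows = [
        {
            "age": st.age,
            "population": st.population,
            "prev_never_mean": st.prev_never_smoking.mean,
            "prev_never_se": st.prev_never_smoking.se,
            "prev_ever_ecig_mean": st.prev_ever_ecig.mean,
            "prev_ever_ecig_se": st.prev_ever_ecig.se,
            "p_init_mean": st.p_init_baseline.mean,
            "p_init_se": st.p_init_baseline.se,
            "p_daily_mean": st.p_daily_35_39.mean,
            "p_daily_se": st.p_daily_35_39.se,
            "yll_mean": st.yl_lost_per_daily_smoker.mean,
            "yll_se": st.yl_lost_per_daily_smoker.se,
        }
        for st in ps.youth_strata
    ]
    adult_path = out_dir / "adult_parameters.csv"
    youth_path = out_dir / "youth_parameters.csv"
    shared_path = out_dir / "shared_config.json"
    # write numerics as shortest-round-trip repr strings: lossless
    def stringify(df: pd.DataFrame) -> pd.DataFrame:
        return df.map(lambda x: repr(x) if isinstance(x, float) else x)

    stringify(pd.DataFrame(adult_rows, columns=ADULT_COLUMNS)).to_csv(
        adult_path, index=False)
    stringify(pd.DataFrame(youth_rows, columns=YOUTH_COLUMNS)).to_csv(
        youth_path, index=False)

    def uq_dict(uq: UncertainQuantity) -> dict:
        return {"mean": uq.mean, "se": uq.se}

    shared = {
        "cessation": {
            "or_cessation": uq_dict(ps.cessation.or_cessation),
            "w_pharma_aid": uq_dict(ps.cessation.w_pharma_aid),
            "p_cess_aid": uq_dict(ps.cessation.p_cess_aid),
            "p_cess_noaid": uq_dict(ps.cessation.p_cess_noaid),
            "p_abst_1y_given_6m": uq_dict(ps.cessation.p_abst_1y_given_6m),
            "p_abst_6y_given_1y": uq_dict(ps.cessation.p_abst_6y_given_1y),
            "relative_harm": ps.cessation.relative_harm,
        },
        "initiation": {"or_initiation": uq_dict(ps.initiation.or_initiation)},
        "metadata": ps.metadata,
    }
    if sim is not None:
        shared["sim"] = dataclasses.asdict(sim)
    with open(shared_path, "w") as fh:
        json.dump(shared, fh, indent=2)
    return {"adult": adult_path, "youth": youth_path, "shared": shared_path}
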