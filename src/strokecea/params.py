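"""Model inputs: domain types, validation, and configuration I/O.

The model compares two acute-stroke care strategies — mechanical
thrombectomy on top of standard medical care (``MT_SMC``) versus standard
medical care alone (``SMC``) — for patients treated 6–24 h after symptom
onset.  All inputs (costs in 2019 USD, health-state utilities, transition
probabilities, hazard ratios, uncertainty distributions) live in one
human-editable YAML file whose sections mirror the published input table,
plus CSV files for the life table and the 90-day efficacy distributions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParameterError",
    "MrsDistribution",
    "validate_mrs_distribution",
    "StrategyArm",
    "SubgroupDefinition",
    "TransitionInputs",
    "CostInputs",
    "UtilityInputs",
    "DistributionSpec",
    "ModelSettings",
    "LifeTable",
    "ParameterSet",
    "beta_from_range",
    "load_parameters",
    "save_parameters",
    "load_efficacy",
    "subgroups_from_frame",
    "efficacy_to_frame",
    "load_study",
    "StudyConfig",
    "STRATEGIES",
    "N_MRS",
    "DEAD",
]

#: mRS health states 0..5 (alive) plus mRS 6 = death.
N_MRS = 7
N_ALIVE = 6
DEAD = 6

STRATEGIES = ("MT_SMC", "SMC")
TRIALS = ("DAWN", "DEFUSE3")

_SUM_TOL = 1e-9


class ParameterError(ValueError):
    """Validation failure for a named model input field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        self.message = message
        super().__init__(f"{field_name}: {message}")


def _check_prob(name: str, value: float) -> float:
    if not (0.0 <= value <= 1.0) or not math.isfinite(value):
        raise ParameterError(name, f"probability out of [0,1]: {value!r}")
    return float(value)


def _check_nonneg(name: str, value: float) -> float:
    if value < 0 or not math.isfinite(value):
        raise ParameterError(name, f"must be a finite non-negative number: {value!r}")
    return float(value)


# ---------------------------------------------------------------------------
# mRS distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MrsDistribution:
    """Probability vector over mRS 0..6 at 90 days (mRS 6 = death)."""

    p: tuple[float, ...]

    def __post_init__(self):
        if len(self.p) != N_MRS:
            raise ParameterError("mrs_distribution", f"expected {N_MRS} probabilities, got {len(self.p)}")
        for i, v in enumerate(self.p):
            if v < -_SUM_TOL or not math.isfinite(v):
                raise ParameterError(f"mrs_distribution[p{i}]", f"negative probability {v!r}")
        total = float(sum(self.p))
        if abs(total - 1.0) > 1e-6:
            raise ParameterError("mrs_distribution", f"probabilities sum to {total}, not 1")
        # store a clipped, exactly summing tuple
        arr = np.clip(np.asarray(self.p, dtype=float), 0.0, None)
        object.__setattr__(self, "p", tuple(arr / arr.sum()))

    @classmethod
    def from_values(cls, *values: float) -> "MrsDistribution":
        return cls(tuple(float(v) for v in values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.p, dtype=float)

    @property
    def p_death(self) -> float:
        return self.p[DEAD]

    def survivors(self) -> "MrsDistribution":
        """Distribution conditioned on 90-day survival (death mass removed)."""
        alive = self.as_array()[:N_ALIVE]
        s = alive.sum()
        if s <= 0:
            raise ParameterError("mrs_distribution", "no survivors to condition on")
        out = np.zeros(N_MRS)
        out[:N_ALIVE] = alive / s
        return MrsDistribution(tuple(out))

    def __getitem__(self, i: int) -> float:
        return self.p[i]


def validate_mrs_distribution(d: MrsDistribution | Sequence[float]) -> MrsDistribution:
    """Validate a 7-category mRS probability vector, returning it if valid.

    Raises :class:`ParameterError` when an entry is negative or the vector
    does not sum to 1.
    """
    if isinstance(d, MrsDistribution):
        return MrsDistribution(d.p)
    return MrsDistribution(tuple(float(v) for v in d))


# ---------------------------------------------------------------------------
# Distribution specifications for probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

_FAMILIES = {"beta", "beta_pert", "dirichlet", "log_normal", "uniform", "fixed"}


def beta_from_range(mean: float, low: float, high: float) -> tuple[float, float]:
    """Moment-match a Beta distribution to a base value and printed range.

    The mean is pinned to ``mean`` and the standard deviation to
    ``(high - low) / 3.92`` so the central ~95% mass spans the range.
    """
    if not (0.0 < mean < 1.0):
        raise ParameterError("beta_from_range", f"mean must be in (0,1), got {mean}")
    if high <= low:
        raise ParameterError("beta_from_range", f"invalid range ({low}, {high})")
    sd = (high - low) / 3.92
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    nu = max(nu, 2.0)
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class DistributionSpec:
    """Family + parameters for one uncertain model input.

    ``range`` carries the published low/high bounds when the source table
    prints them; the one-way sensitivity analysis varies parameters over
    exactly these bounds.
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)
    range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ParameterError("distribution.family", f"unknown family {self.family!r}")
        p = dict(self.params)
        f = self.family
        if f == "beta":
            if p.get("alpha", 0) <= 0 or p.get("beta", 0) <= 0:
                raise ParameterError("distribution.beta", f"alpha, beta must be > 0: {p}")
        elif f == "beta_pert":
            try:
                lo, mode, hi = p["min"], p["mode"], p["max"]
            except KeyError as e:
                raise ParameterError("distribution.beta_pert", f"missing {e}") from None
            if not (lo <= mode <= hi):
                raise ParameterError("distribution.beta_pert", f"need min <= mode <= max, got {p}")
        elif f == "log_normal":
            if p.get("base", 0) <= 0:
                raise ParameterError("distribution.log_normal", "base must be > 0")
            if p.get("se", -1) < 0:
                raise ParameterError("distribution.log_normal", "se must be >= 0")
        elif f == "uniform":
            if p.get("low", 0) > p.get("high", 0):
                raise ParameterError("distribution.uniform", f"need low <= high, got {p}")
        elif f == "fixed":
            if "value" not in p:
                raise ParameterError("distribution.fixed", "missing value")
        object.__setattr__(self, "params", p)

    def bounds(self) -> tuple[float, float]:
        """Low/high bounds for one-way sensitivity (printed range preferred)."""
        if self.range is not None:
            return self.range
        p = self.params
        if self.family == "beta_pert":
            return p["min"], p["max"]
        if self.family == "uniform":
            return p["low"], p["high"]
        if self.family == "beta":
            from scipy import stats
            return tuple(stats.beta.ppf([0.025, 0.975], p["alpha"], p["beta"]))
        if self.family == "log_normal":
            lo = math.exp(math.log(p["base"]) - 1.959963984540054 * p["se"])
            hi = math.exp(math.log(p["base"]) + 1.959963984540054 * p["se"])
            return lo, hi
        if self.family == "fixed":
            return p["value"], p["value"]
        raise ParameterError("distribution.bounds", f"no scalar bounds for family {self.family}")


def _spec_from_config(name: str, base: float, node: Mapping | None) -> DistributionSpec:
    """Build a DistributionSpec from a YAML ``dist`` node."""
    if node is None:
        return DistributionSpec("fixed", {"value": base})
    node = dict(node)
    family = node.pop("family", None)
    if family is None:
        raise ParameterError(name, "distribution missing 'family'")
    rng = node.pop("range", None)
    rng_t = tuple(float(v) for v in rng) if rng is not None else None
    if family == "beta" and "alpha" not in node:
        # beta given only as base + range: moment-match
        if rng_t is None:
            raise ParameterError(name, "beta distribution needs alpha/beta or a range")
        try:
            a, b = beta_from_range(base, *rng_t)
        except ParameterError as e:
            raise ParameterError(name, e.message) from None
        return DistributionSpec("beta", {"alpha": a, "beta": b}, range=rng_t)
    if family == "beta_pert" and "mode" not in node:
        if rng_t is None:
            raise ParameterError(name, "beta_pert distribution needs a range")
        node.update(min=rng_t[0], mode=base, max=rng_t[1])
    if family == "log_normal" and "base" not in node:
        node["base"] = base
    if family == "fixed" and "value" not in node:
        node["value"] = base
    try:
        return DistributionSpec(family, {k: float(v) for k, v in node.items()}, range=rng_t)
    except ParameterError as e:
        raise ParameterError(name, str(e)) from None


# ---------------------------------------------------------------------------
# Structured inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionInputs:
    """3-monthly Markov transition inputs.

    ``death_hr`` are all-cause mortality hazard ratios per mRS 0..5 relative
    to the general population of the same age and sex (mRS 0/1 are the
    reference states with HR 1).
    """

    recurrence_prob: float = 0.013
    post_recurrence_death: float = 0.0513
    death_hr: tuple[float, ...] = (1.0, 1.0, 1.11, 1.27, 1.71, 2.37)
    #: Optional per-origin-state weights over strictly worse alive states
    #: (rows for mRS 0..4, each summing to 1); None means an equal split.
    recurrence_split: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self):
        _check_prob("transitions.recurrence_prob", self.recurrence_prob)
        _check_prob("transitions.post_recurrence_death", self.post_recurrence_death)
        if len(self.death_hr) != N_ALIVE:
            raise ParameterError("transitions.death_hr", f"expected {N_ALIVE} hazard ratios")
        for i, hr in enumerate(self.death_hr):
            if hr <= 0 or not math.isfinite(hr):
                raise ParameterError(f"transitions.death_hr.mrs{i}", f"hazard ratio must be > 0: {hr!r}")
        object.__setattr__(self, "death_hr", tuple(float(h) for h in self.death_hr))
        if self.recurrence_split is not None:
            if len(self.recurrence_split) != N_ALIVE - 1:
                raise ParameterError("transitions.recurrence_split", "expected rows for mRS 0..4")
            rows = []
            for i, row in enumerate(self.recurrence_split):
                n_worse = N_ALIVE - 1 - i
                if len(row) != n_worse:
                    raise ParameterError(
                        f"transitions.recurrence_split.mrs{i}",
                        f"expected {n_worse} weights, got {len(row)}",
                    )
                if any(w < 0 for w in row) or abs(sum(row) - 1.0) > 1e-6:
                    raise ParameterError(
                        f"transitions.recurrence_split.mrs{i}", "weights must be >= 0 and sum to 1"
                    )
                rows.append(tuple(float(w) for w in row))
            object.__setattr__(self, "recurrence_split", tuple(rows))


_IMAGING = ("ct", "cta", "mri", "mra", "ctp", "software")
_ACUTE_TIERS = ("mrs0_2", "mrs3_5", "death")


@dataclass(frozen=True)
class CostInputs:
    """Decision-tree and Markov cost inputs, 2019 USD.

    ``recurrent_stroke_cost`` is derived from the decision tree per strategy
    at run time; an override mapping may pin it (e.g. to published totals).
    """

    imaging: Mapping[str, float]
    freq_cta_vs_mra: float = 0.5
    freq_ctp_vs_mri: float = 0.5
    tpa_cost: float = 8004.0
    mt_procedure: float = 15836.0
    mt_physician: float = 2749.0
    acute_90d: Mapping[str, float] = field(
        default_factory=lambda: {"mrs0_2": 14382.0, "mrs3_5": 17879.0, "death": 23498.0}
    )
    longterm_3mo: tuple[float, ...] = (2836.0, 2741.0, 3378.0, 5801.0, 11742.0, 17262.0)
    recurrent_stroke_cost: Mapping[str, float] | None = None

    def __post_init__(self):
        for key in _IMAGING:
            if key not in self.imaging:
                raise ParameterError(f"costs.imaging.{key}", "missing imaging cost")
            _check_nonneg(f"costs.imaging.{key}", self.imaging[key])
        _check_prob("costs.freq_cta_vs_mra", self.freq_cta_vs_mra)
        _check_prob("costs.freq_ctp_vs_mri", self.freq_ctp_vs_mri)
        for name in ("tpa_cost", "mt_procedure", "mt_physician"):
            _check_nonneg(f"costs.{name}", getattr(self, name))
        for key in _ACUTE_TIERS:
            if key not in self.acute_90d:
                raise ParameterError(f"costs.acute_90d.{key}", "missing acute cost tier")
            _check_nonneg(f"costs.acute_90d.{key}", self.acute_90d[key])
        if len(self.longterm_3mo) != N_ALIVE:
            raise ParameterError("costs.longterm_3mo", f"expected {N_ALIVE} values")
        for i, c in enumerate(self.longterm_3mo):
            _check_nonneg(f"costs.longterm_3mo.mrs{i}", c)
        object.__setattr__(self, "imaging", dict(self.imaging))
        object.__setattr__(self, "acute_90d", dict(self.acute_90d))
        object.__setattr__(self, "longterm_3mo", tuple(float(c) for c in self.longterm_3mo))

    def acute_tier(self, mrs: int) -> float:
        """Severity-tiered acute 90-day cost for one mRS outcome."""
        if mrs <= 2:
            return self.acute_90d["mrs0_2"]
        if mrs <= 5:
            return self.acute_90d["mrs3_5"]
        return self.acute_90d["death"]


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities per mRS 0..5 (death = 0), non-increasing in severity."""

    utility: tuple[float, ...] = (0.85, 0.80, 0.70, 0.51, 0.30, 0.15)
    recurrence_utility: Mapping[str, float] | None = None

    def __post_init__(self):
        if len(self.utility) != N_ALIVE:
            raise ParameterError("utilities.utility", f"expected {N_ALIVE} values")
        for i, u in enumerate(self.utility):
            if not (0.0 <= u <= 1.0):
                raise ParameterError(f"utilities.mrs{i}", f"utility out of [0,1]: {u!r}")
        for i in range(1, N_ALIVE):
            if self.utility[i] > self.utility[i - 1] + 1e-12:
                raise ParameterError(
                    f"utilities.mrs{i}", "utilities must be non-increasing in mRS severity"
                )
        object.__setattr__(self, "utility", tuple(float(u) for u in self.utility))

    def full_vector(self) -> np.ndarray:
        """Utilities over all 7 states including death (= 0)."""
        return np.append(np.asarray(self.utility), 0.0)


@dataclass(frozen=True)
class ModelSettings:
    """Global run settings."""

    cycle_length: float = 0.25          # years per Markov cycle
    discount_rate: float = 0.03         # annual, costs and QALYs alike
    cohort_size: int = 1000             # hypothetical cohort (cancels out of per-patient results)
    psa_draws: int = 2000
    max_age: float = 110.0
    wtp_grid: tuple[float, ...] = (0.0, 25_000.0, 50_000.0, 100_000.0, 150_000.0, 200_000.0)
    seed: int = 20_200_825
    accrue_acute_qalys: bool = True     # count 0.25 * 90-day expected utility in lifetime QALYs
    half_cycle_correction: bool = False
    extinction_tol: float = 1e-6

    def __post_init__(self):
        if self.cycle_length <= 0:
            raise ParameterError("settings.cycle_length", "must be > 0")
        if self.discount_rate < 0:
            raise ParameterError("settings.discount_rate", "must be >= 0")
        if self.psa_draws < 1:
            raise ParameterError("settings.psa_draws", "must be >= 1")
        if self.cohort_size < 1:
            raise ParameterError("settings.cohort_size", "must be >= 1")
        object.__setattr__(self, "wtp_grid", tuple(float(w) for w in self.wtp_grid))


# ---------------------------------------------------------------------------
# Strategy arms and subgroups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyArm:
    """One treatment arm of a trial subgroup.

    ``efficacy`` is the resolved 7-category 90-day mRS distribution.
    ``efficacy56`` holds the raw 6-value form (mRS 0..4 plus combined
    mRS 5+6) for inputs published with those categories merged; it is
    resolved against a reference distribution via
    :func:`strokecea.decision_tree.split_mrs56`.
    """

    name: str
    mean_age: float
    n: int
    tpa_frequency: float
    male_fraction: float = 0.5
    efficacy: MrsDistribution | None = None
    efficacy56: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.name not in STRATEGIES:
            raise ParameterError("arm.name", f"must be one of {STRATEGIES}, got {self.name!r}")
        if not (18.0 <= self.mean_age <= 100.0):
            raise ParameterError("arm.mean_age", f"must be in [18, 100] years: {self.mean_age!r}")
        if self.n < 1:
            raise ParameterError("arm.n", f"sample size must be >= 1: {self.n!r}")
        _check_prob("arm.tpa_frequency", self.tpa_frequency)
        _check_prob("arm.male_fraction", self.male_fraction)
        if self.efficacy is None and self.efficacy56 is None:
            raise ParameterError("arm.efficacy", "arm needs an efficacy distribution")
        if self.efficacy56 is not None:
            if len(self.efficacy56) != 6:
                raise ParameterError("arm.efficacy56", "expected 6 values (mRS 0..4 + combined 5/6)")
            total = sum(self.efficacy56)
            if abs(total - 1.0) > 1e-6 or any(v < 0 for v in self.efficacy56):
                raise ParameterError("arm.efficacy56", f"invalid combined distribution (sum {total})")


@dataclass(frozen=True)
class SubgroupDefinition:
    """A trial subgroup with exactly one arm per strategy."""

    trial: str
    label: str
    arms: Mapping[str, StrategyArm]
    needs_mrs56_split: bool = False

    def __post_init__(self):
        if self.trial not in TRIALS:
            raise ParameterError("subgroup.trial", f"must be one of {TRIALS}, got {self.trial!r}")
        if set(self.arms) != set(STRATEGIES):
            raise ParameterError(
                "subgroup.arms", f"need exactly one arm per strategy {STRATEGIES}, got {sorted(self.arms)}"
            )
        object.__setattr__(self, "arms", dict(self.arms))

    @property
    def key(self) -> str:
        return f"{self.trial}:{self.label}"


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

class LifeTable:
    """Annual death probabilities ``qx`` indexed by integer age and sex.

    Ages must be contiguous and both sexes present; lookups beyond the last
    tabulated age clamp to the final row (with a warning).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"age", "sex", "qx"}
        if not required.issubset(table.columns):
            raise ParameterError("life_table", f"needs columns {sorted(required)}")
        t = table.copy()
        t["sex"] = t["sex"].str.lower()
        if set(t["sex"].unique()) != {"male", "female"}:
            raise ParameterError("life_table.sex", "both 'male' and 'female' rows required")
        if ((t["qx"] < 0) | (t["qx"] > 1)).any():
            raise ParameterError("life_table.qx", "qx out of [0,1]")
        pivot = t.pivot_table(index="age", columns="sex", values="qx")
        if pivot.isna().any().any():
            raise ParameterError("life_table", "every age needs both sexes")
        ages = pivot.index.to_numpy()
        if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
            raise ParameterError("life_table.age", "ages must be contiguous integers")
        self.min_age = int(ages[0])
        self.max_age = int(ages[-1])
        self._qx_male = pivot["male"].to_numpy(dtype=float)
        self._qx_female = pivot["female"].to_numpy(dtype=float)
        self._warned = False

    def qx(self, age: float, male_fraction: float = 0.5) -> float:
        """Annual death probability at ``age``, mixed across sexes."""
        i = int(math.floor(age)) - self.min_age
        if i < 0:
            raise ParameterError("life_table.age", f"age {age} below table range {self.min_age}")
        if i >= len(self._qx_male):
            if not self._warned:
                warnings.warn(
                    f"age {age} beyond life table (max {self.max_age}); clamping to last row",
                    stacklevel=2,
                )
                self._warned = True
            i = len(self._qx_male) - 1
        return male_fraction * self._qx_male[i] + (1.0 - male_fraction) * self._qx_female[i]

    def to_frame(self) -> pd.DataFrame:
        ages = np.arange(self.min_age, self.max_age + 1)
        return pd.DataFrame(
            {
                "age": np.concatenate([ages, ages]),
                "sex": ["male"] * len(ages) + ["female"] * len(ages),
                "qx": np.concatenate([self._qx_male, self._qx_female]),
            }
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Parameter set: one complete instantiation of the input table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSet:
    """One complete, validated set of model inputs for a deterministic run.

    ``specs`` maps dotted field paths (e.g. ``"costs.mt_procedure"``,
    ``"utilities.mrs4"``) to the uncertainty distribution used by the
    probabilistic and one-way sensitivity analyses.
    """

    transitions: TransitionInputs
    costs: CostInputs
    utilities: UtilityInputs
    specs: Mapping[str, DistributionSpec] = field(default_factory=dict)
    hr_sampled: tuple[bool, ...] = (False, False, True, True, True, True)
    efficacy_scenarios: Mapping[str, MrsDistribution] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "specs", dict(self.specs))
        object.__setattr__(self, "efficacy_scenarios", dict(self.efficacy_scenarios))

    # -- dotted-path access used by PSA and one-way sensitivity ------------
    def get_value(self, path: str) -> float:
        getter, _ = _FIELD_ACCESSORS[path]
        return getter(self)

    def with_value(self, path: str, value: float) -> "ParameterSet":
        """Return a copy with one scalar input replaced (re-validated)."""
        _, setter = _FIELD_ACCESSORS[path]
        return setter(self, float(value))

    def scalar_paths(self) -> list[str]:
        return [p for p in self.specs if p in _FIELD_ACCESSORS]


def _make_accessors():
    acc: dict[str, tuple] = {}

    def add(path, getter, setter):
        acc[path] = (getter, setter)

    def repl_trans(ps, **kw):
        return replace(ps, transitions=replace(ps.transitions, **kw))

    add("transitions.recurrence_prob",
        lambda ps: ps.transitions.recurrence_prob,
        lambda ps, v: repl_trans(ps, recurrence_prob=v))
    add("transitions.post_recurrence_death",
        lambda ps: ps.transitions.post_recurrence_death,
        lambda ps, v: repl_trans(ps, post_recurrence_death=v))
    for i in range(N_ALIVE):
        add(f"transitions.death_hr.mrs{i}",
            lambda ps, i=i: ps.transitions.death_hr[i],
            lambda ps, v, i=i: repl_trans(
                ps, death_hr=tuple(v if j == i else h for j, h in enumerate(ps.transitions.death_hr))))

    def repl_costs(ps, **kw):
        return replace(ps, costs=replace(ps.costs, **kw))

    for key in _IMAGING:
        add(f"costs.imaging.{key}",
            lambda ps, key=key: ps.costs.imaging[key],
            lambda ps, v, key=key: repl_costs(ps, imaging={**ps.costs.imaging, key: v}))
    for name in ("freq_cta_vs_mra", "freq_ctp_vs_mri", "tpa_cost", "mt_procedure", "mt_physician"):
        add(f"costs.{name}",
            lambda ps, name=name: getattr(ps.costs, name),
            lambda ps, v, name=name: repl_costs(ps, **{name: v}))
    for key in _ACUTE_TIERS:
        add(f"costs.acute_90d.{key}",
            lambda ps, key=key: ps.costs.acute_90d[key],
            lambda ps, v, key=key: repl_costs(ps, acute_90d={**ps.costs.acute_90d, key: v}))
    for i in range(N_ALIVE):
        add(f"costs.longterm_3mo.mrs{i}",
            lambda ps, i=i: ps.costs.longterm_3mo[i],
            lambda ps, v, i=i: repl_costs(
                ps, longterm_3mo=tuple(v if j == i else c for j, c in enumerate(ps.costs.longterm_3mo))))
    for i in range(N_ALIVE):
        add(f"utilities.mrs{i}",
            lambda ps, i=i: ps.utilities.utility[i],
            lambda ps, v, i=i: replace(
                ps, utilities=replace(
                    ps.utilities,
                    utility=tuple(v if j == i else u for j, u in enumerate(ps.utilities.utility)))))
    return acc


_FIELD_ACCESSORS = _make_accessors()


# ---------------------------------------------------------------------------
# Configuration I/O
# ---------------------------------------------------------------------------

def _require(cfg: Mapping, key: str, context: str):
    if key not in cfg:
        raise ParameterError(f"{context}.{key}", "missing required field")
    return cfg[key]


def _scalar_block(cfg: Mapping, context: str) -> tuple[float, DistributionSpec]:
    base = float(_require(cfg, "base", context))
    spec = _spec_from_config(context, base, cfg.get("dist"))
    return base, spec


def load_parameters(config_path: str | Path) -> tuple[ParameterSet, ModelSettings]:
    """Load and validate the full model input bundle from a YAML config."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParameterError("config", "top level must be a mapping")

    specs: dict[str, DistributionSpec] = {}

    # settings -------------------------------------------------------------
    s = cfg.get("settings", {})
    settings = ModelSettings(
        cycle_length=float(s.get("cycle_length", 0.25)),
        discount_rate=float(s.get("discount_rate", 0.03)),
        cohort_size=int(s.get("cohort_size", 1000)),
        psa_draws=int(s.get("psa_draws", 2000)),
        max_age=float(s.get("max_age", 110.0)),
        wtp_grid=tuple(s.get("wtp_grid", (0, 25_000, 50_000, 100_000, 150_000, 200_000))),
        seed=int(s.get("seed", 20_200_825)),
        accrue_acute_qalys=bool(s.get("accrue_acute_qalys", True)),
        half_cycle_correction=bool(s.get("half_cycle_correction", False)),
        extinction_tol=float(s.get("extinction_tol", 1e-6)),
    )

    # transitions ----------------------------------------------------------
    t = _require(cfg, "transitions", "config")
    rec_base, rec_spec = _scalar_block(_require(t, "recurrence_prob", "transitions"),
                                       "transitions.recurrence_prob")
    specs["transitions.recurrence_prob"] = rec_spec
    prd_base, prd_spec = _scalar_block(_require(t, "post_recurrence_death", "transitions"),
                                       "transitions.post_recurrence_death")
    specs["transitions.post_recurrence_death"] = prd_spec
    hr_cfg = _require(t, "death_hr", "transitions")
    hr_base = [float(v) for v in _require(hr_cfg, "base", "transitions.death_hr")]
    if len(hr_base) != N_ALIVE:
        raise ParameterError("transitions.death_hr", f"expected {N_ALIVE} values, got {len(hr_base)}")
    hr_se = [float(v) for v in hr_cfg.get("se", [0.0] * N_ALIVE)]
    hr_sampled = tuple(bool(v) for v in hr_cfg.get("sampled", [False] * N_ALIVE))
    for i in range(N_ALIVE):
        specs[f"transitions.death_hr.mrs{i}"] = DistributionSpec(
            "log_normal", {"base": hr_base[i], "se": hr_se[i]}
        )
    transitions = TransitionInputs(rec_base, prd_base, tuple(hr_base))

    # costs ----------------------------------------------------------------
    c = _require(cfg, "costs", "config")
    imaging = {}
    img_cfg = _require(c, "imaging", "costs")
    for key in _IMAGING:
        base, spec = _scalar_block(_require(img_cfg, key, "costs.imaging"), f"costs.imaging.{key}")
        imaging[key] = base
        specs[f"costs.imaging.{key}"] = spec

    def scalar(name):
        base, spec = _scalar_block(_require(c, name, "costs"), f"costs.{name}")
        specs[f"costs.{name}"] = spec
        return base

    freq_cta = scalar("freq_cta_vs_mra")
    freq_ctp = scalar("freq_ctp_vs_mri")
    tpa = scalar("tpa_cost")
    mt_proc = scalar("mt_procedure")
    mt_phys = scalar("mt_physician")
    acute = {}
    acute_cfg = _require(c, "acute_90d", "costs")
    for key in _ACUTE_TIERS:
        base, spec = _scalar_block(_require(acute_cfg, key, "costs.acute_90d"), f"costs.acute_90d.{key}")
        acute[key] = base
        specs[f"costs.acute_90d.{key}"] = spec
    lt_cfg = _require(c, "longterm_3mo", "costs")
    longterm = []
    for i in range(N_ALIVE):
        base, spec = _scalar_block(_require(lt_cfg, f"mrs{i}", "costs.longterm_3mo"),
                                   f"costs.longterm_3mo.mrs{i}")
        longterm.append(base)
        specs[f"costs.longterm_3mo.mrs{i}"] = spec
    rsc = c.get("recurrent_stroke_cost")
    costs = CostInputs(
        imaging=imaging, freq_cta_vs_mra=freq_cta, freq_ctp_vs_mri=freq_ctp,
        tpa_cost=tpa, mt_procedure=mt_proc, mt_physician=mt_phys,
        acute_90d=acute, longterm_3mo=tuple(longterm),
        recurrent_stroke_cost=dict(rsc) if rsc else None,
    )

    # utilities ------------------------------------------------------------
    u = _require(cfg, "utilities", "config")
    util = []
    for i in range(N_ALIVE):
        base, spec = _scalar_block(_require(u, f"mrs{i}", "utilities"), f"utilities.mrs{i}")
        util.append(base)
        specs[f"utilities.mrs{i}"] = spec
    ru = u.get("recurrence_utility")
    utilities = UtilityInputs(tuple(util), recurrence_utility=dict(ru) if ru else None)

    scenarios = {
        name: validate_mrs_distribution(vec)
        for name, vec in cfg.get("efficacy_scenarios", {}).items()
    }

    params = ParameterSet(
        transitions=transitions, costs=costs, utilities=utilities, specs=specs,
        hr_sampled=hr_sampled, efficacy_scenarios=scenarios,
    )
    return params, settings


def save_parameters(params: ParameterSet, settings: ModelSettings, path: str | Path) -> None:
    """Serialize a parameter bundle back to the YAML layout ``load_parameters`` reads."""

    def scalar_node(path_key: str, base: float) -> dict:
        spec = params.specs.get(path_key, DistributionSpec("fixed", {"value": base}))
        node: dict = {"base": base, "dist": {"family": spec.family, **spec.params}}
        if spec.range is not None:
            node["dist"]["range"] = list(spec.range)
        return node

    t = params.transitions
    cfg = {
        "settings": {
            "cycle_length": settings.cycle_length,
            "discount_rate": settings.discount_rate,
            "cohort_size": settings.cohort_size,
            "psa_draws": settings.psa_draws,
            "max_age": settings.max_age,
            "wtp_grid": list(settings.wtp_grid),
            "seed": settings.seed,
            "accrue_acute_qalys": settings.accrue_acute_qalys,
            "half_cycle_correction": settings.half_cycle_correction,
            "extinction_tol": settings.extinction_tol,
        },
        "transitions": {
            "recurrence_prob": scalar_node("transitions.recurrence_prob", t.recurrence_prob),
            "post_recurrence_death": scalar_node("transitions.post_recurrence_death", t.post_recurrence_death),
            "death_hr": {
                "base": list(t.death_hr),
                "se": [params.specs[f"transitions.death_hr.mrs{i}"].params["se"] for i in range(N_ALIVE)],
                "sampled": list(params.hr_sampled),
            },
        },
        "costs": {
            "imaging": {k: scalar_node(f"costs.imaging.{k}", params.costs.imaging[k]) for k in _IMAGING},
            "freq_cta_vs_mra": scalar_node("costs.freq_cta_vs_mra", params.costs.freq_cta_vs_mra),
            "freq_ctp_vs_mri": scalar_node("costs.freq_ctp_vs_mri", params.costs.freq_ctp_vs_mri),
            "tpa_cost": scalar_node("costs.tpa_cost", params.costs.tpa_cost),
            "mt_procedure": scalar_node("costs.mt_procedure", params.costs.mt_procedure),
            "mt_physician": scalar_node("costs.mt_physician", params.costs.mt_physician),
            "acute_90d": {k: scalar_node(f"costs.acute_90d.{k}", params.costs.acute_90d[k]) for k in _ACUTE_TIERS},
            "longterm_3mo": {
                f"mrs{i}": scalar_node(f"costs.longterm_3mo.mrs{i}", params.costs.longterm_3mo[i])
                for i in range(N_ALIVE)
            },
        },
        "utilities": {
            f"mrs{i}": scalar_node(f"utilities.mrs{i}", params.utilities.utility[i])
            for i in range(N_ALIVE)
        },
    }
    if params.costs.recurrent_stroke_cost:
        cfg["costs"]["recurrent_stroke_cost"] = dict(params.costs.recurrent_stroke_cost)
    if params.utilities.recurrence_utility:
        cfg["utilities"]["recurrence_utility"] = dict(params.utilities.recurrence_utility)
    if params.efficacy_scenarios:
        cfg["efficacy_scenarios"] = {
            name: [float(p) for p in d.p] for name, d in params.efficacy_scenarios.items()
        }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Efficacy CSV
# ---------------------------------------------------------------------------

_EFF_COLS = ["subgroup", "trial", "arm", "mrs0", "mrs1", "mrs2", "mrs3", "mrs4",
             "mrs5", "mrs6", "mrs56", "n", "mean_age"]


def load_efficacy(
    path: str | Path,
    arm_defaults: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None,
) -> list[SubgroupDefinition]:
    """Read 90-day mRS efficacy records into subgroup definitions.

    Each row is one (subgroup, trial, arm).  Separated records fill
    ``mrs0..mrs6``; combined-tail records (mRS 5 and 6 merged, as some
    trial reports publish them) leave ``mrs5``/``mrs6`` blank and fill
    ``mrs56`` instead.  ``arm_defaults[trial][arm]`` supplies
    ``tpa_frequency`` and ``male_fraction``, which efficacy tables do not
    carry.
    """
    return subgroups_from_frame(pd.read_csv(path), arm_defaults)


def subgroups_from_frame(
    df: pd.DataFrame,
    arm_defaults: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None,
) -> list[SubgroupDefinition]:
    """Build subgroup definitions from an efficacy table in memory."""
    missing = {"subgroup", "trial", "arm", "n", "mean_age"} - set(df.columns)
    if missing:
        raise ParameterError("efficacy_csv", f"missing columns {sorted(missing)}")
    arm_defaults = arm_defaults or {}
    subgroups: list[SubgroupDefinition] = []
    for (trial, label), grp in df.groupby(["trial", "subgroup"], sort=False):
        arms: dict[str, StrategyArm] = {}
        needs_split = False
        for _, row in grp.iterrows():
            name = row["arm"]
            defaults = dict(arm_defaults.get(trial, {}).get(name, {}))
            combined = "mrs56" in row and pd.notna(row.get("mrs56"))
            kwargs = dict(
                name=name,
                mean_age=float(row["mean_age"]),
                n=int(row["n"]),
                tpa_frequency=float(row.get("tpa_frequency", defaults.get("tpa_frequency", 0.0))
                                    if pd.notna(row.get("tpa_frequency", np.nan))
                                    else defaults.get("tpa_frequency", 0.0)),
                male_fraction=float(defaults.get("male_fraction", 0.5)),
            )
            if combined:
                needs_split = True
                vec = tuple(float(row[f"mrs{i}"]) for i in range(5)) + (float(row["mrs56"]),)
                arms[name] = StrategyArm(efficacy56=vec, **kwargs)
            else:
                vec = tuple(float(row[f"mrs{i}"]) for i in range(7))
                arms[name] = StrategyArm(efficacy=validate_mrs_distribution(vec), **kwargs)
        subgroups.append(SubgroupDefinition(trial=trial, label=label, arms=arms,
                                            needs_mrs56_split=needs_split))
    return subgroups


def efficacy_to_frame(subgroups: Iterable[SubgroupDefinition]) -> pd.DataFrame:
    """Serialize subgroup efficacy back to the CSV layout ``load_efficacy`` reads."""
    rows = []
    for sg in subgroups:
        for arm in sg.arms.values():
            row = {c: np.nan for c in _EFF_COLS}
            row.update(subgroup=sg.label, trial=sg.trial, arm=arm.name,
                       n=arm.n, mean_age=arm.mean_age)
            if arm.efficacy56 is not None:
                for i in range(5):
                    row[f"mrs{i}"] = arm.efficacy56[i]
                row["mrs56"] = arm.efficacy56[5]
            else:
                for i in range(7):
                    row[f"mrs{i}"] = arm.efficacy.p[i]
            rows.append(row)
    return pd.DataFrame(rows, columns=_EFF_COLS)


# ---------------------------------------------------------------------------
# Whole-study configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Everything one end-to-end run needs."""

    params: ParameterSet
    settings: ModelSettings
    subgroups: list[SubgroupDefinition]
    life_table: LifeTable
    mrs56_reference: MrsDistribution | None = None


def load_study(config_path: str | Path) -> StudyConfig:
    """Load a study config: parameter YAML plus life-table and efficacy CSVs.

    The YAML's ``files`` section points at the CSVs (paths relative to the
    YAML file); ``trial_arms`` supplies per-arm IV-tPA frequency and male
    fraction; ``mrs56_reference`` names the efficacy-scenario entry (or
    inline vector) used to split combined mRS 5+6 inputs.
    """
    config_path = Path(config_path)
    params, settings = load_parameters(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    files = cfg.get("files", {})
    base = config_path.parent
    life_table = LifeTable.from_csv(base / _require(files, "life_table", "files"))
    subgroups = load_efficacy(base / _require(files, "efficacy", "files"),
                              arm_defaults=cfg.get("trial_arms"))
    ref_cfg = cfg.get("mrs56_reference")
    reference = validate_mrs_distribution(ref_cfg) if ref_cfg is not None else None
    return StudyConfig(params=params, settings=settings, subgroups=subgroups,
                       life_table=life_table, mrs56_reference=reference)
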