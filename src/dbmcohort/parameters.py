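"""Typed containers, validation and file I/O for every model input table.

The model classifies a closed cohort of children into three living weight
statuses — underweight (UW), healthy weight (HW), overweight/obese (OWB) —
plus an absorbing death state, and needs six input tables to run:

* population counts by sex and starting age (or 5-year starting-age group),
* weight-status prevalence by sex and single age 5-19,
* annual weight-status transition probabilities by sex and single age,
* all-cause mortality rates by sex and 5-year age group,
* mortality hazard ratios by weight status (adults only),
* utility weights by sex, age band and weight status.

Everything is bundled into a :class:`ParameterSet`, validated on load, and
round-trips through plain CSV files plus a small YAML/JSON config.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "WeightState",
    "STATE_LABELS",
    "SEXES",
    "PopulationTable",
    "PrevalenceTable",
    "TransitionTable",
    "HazardRatios",
    "MortalityGroupTable",
    "UtilityTable",
    "ModelOptions",
    "ParameterSet",
    "Violation",
    "ValidationError",
    "LoadError",
    "validate",
    "load_parameter_set",
    "save_parameter_set",
]

ROW_SUM_TOL = 1e-9


class WeightState(IntEnum):
    """Living weight statuses. Death is an absorbing marker, not a member:
    occupancy vectors and transition matrices are 3-dimensional and death is
    handled by the mortality schedule."""

    UNDERWEIGHT = 0
    HEALTHY = 1
    OVERWEIGHT_OBESE = 2


#: Canonical short labels, in the fixed (UW, HW, OWB) ordering used by every
#: vector and matrix in the package.
STATE_LABELS = ("UW", "HW", "OWB")
_STATE_FROM_LABEL = {
    "UW": WeightState.UNDERWEIGHT,
    "HW": WeightState.HEALTHY,
    "OWB": WeightState.OVERWEIGHT_OBESE,
    "UNDERWEIGHT": WeightState.UNDERWEIGHT,
    "HEALTHY": WeightState.HEALTHY,
    "HEALTHY_WEIGHT": WeightState.HEALTHY,
    "OVERWEIGHT_OBESE": WeightState.OVERWEIGHT_OBESE,
}

SEXES = ("male", "female")
_SEX_INDEX = {"male": 0, "female": 1}

N_STATES = 3
CHILD_AGES = range(5, 20)  # starting ages with prevalence data


class LoadError(ValueError):
    """A file does not conform to its documented schema."""


class ValidationError(ValueError):
    """A loaded table violates a model invariant."""


@dataclass(frozen=True)
class Violation:
    """One machine-readable invariant failure."""

    table: str
    index: tuple
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.table}{list(self.index)}] {self.rule}: {self.message}"


def _state_from_label(label: str) -> WeightState:
    try:
        return _STATE_FROM_LABEL[str(label).strip().upper()]
    except KeyError:
        raise LoadError(f"unknown weight state label {label!r}") from None


def _sex_index(sex: str) -> int:
    try:
        return _SEX_INDEX[sex]
    except KeyError:
        raise KeyError(f"sex must be one of {SEXES}, got {sex!r}") from None


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------


@dataclass
class PopulationTable:
    """Counts of persons by sex and starting age.

    ``counts[sex][age_start]`` — either single ages 5-19 or 5-year group
    starts {5, 10, 15}.  Grouped counts are split across single ages with
    ``split_weights`` (default: even fifths), so the engine always sees a
    single-age cohort size while the printed group totals are preserved.
    """

    counts: dict[str, dict[int, float]]
    split_weights: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)

    @property
    def grouped(self) -> bool:
        ages = sorted(next(iter(self.counts.values())).keys())
        return ages == [5, 10, 15]

    def total(self, sex: str | None = None) -> float:
        if sex is not None:
            return float(sum(self.counts[sex].values()))
        return float(sum(sum(d.values()) for d in self.counts.values()))

    def count_single_age(self, sex: str, age: int) -> float:
        """Cohort size at a single starting age, splitting grouped counts."""
        if age not in CHILD_AGES:
            raise ValueError(f"starting age must be in [5, 19], got {age}")
        d = self.counts[sex]
        if not self.grouped:
            return float(d[age])
        group_start = 5 * (age // 5)
        return float(d[group_start]) * self.split_weights[age - group_start]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sex": sex, "age_start": a, "count": c}
            for sex in SEXES
            for a, c in sorted(self.counts[sex].items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationTable":
        counts: dict[str, dict[int, float]] = {s: {} for s in SEXES}
        for i, row in df.iterrows():
            sex = str(row["sex"])
            if sex not in SEXES:
                raise LoadError(f"population.csv row {i}: unknown sex {sex!r}")
            counts[sex][int(row["age_start"])] = float(row["count"])
        return cls(counts=counts)


# ---------------------------------------------------------------------------
# Dense age × state tables (prevalence, transitions, utilities share bones)
# ---------------------------------------------------------------------------


@dataclass
class PrevalenceTable:
    """Initial weight-status proportions p[sex, age-5, state], ages 5-19.

    ``lo``/``hi`` are optional 95% CI bounds per cell (same shape); absent
    bounds put the table in point-only mode and disable the corresponding
    sensitivity axes.
    """

    value: np.ndarray  # (2, 15, 3)
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    ages: np.ndarray = field(default_factory=lambda: np.arange(5, 20))

    @property
    def has_ci(self) -> bool:
        return self.lo is not None and self.hi is not None

    def get(self, sex: str, age: int) -> np.ndarray:
        return self.value[_sex_index(sex), age - int(self.ages[0])]

    def to_frame(self) -> pd.DataFrame:
        return _dense_to_frame(self, ("sex", "age", "state"))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PrevalenceTable":
        ages = np.arange(5, 20)
        value, lo, hi = _dense_from_frame(df, ages, "prevalence.csv", "age")
        return cls(value=value, lo=lo, hi=hi, ages=ages)


@dataclass
class TransitionTable:
    """Annual weight-status transition probabilities q[sex, age-5, from, to].

    Rows (``from`` slices) are probability distributions over the destination
    state conditional on surviving the year; ages cover every cycle age the
    horizon can reach (5 through horizon-1).
    """

    value: np.ndarray  # (2, n_ages, 3, 3)
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    ages: np.ndarray = field(default_factory=lambda: np.arange(5, 75))

    @property
    def has_ci(self) -> bool:
        return self.lo is not None and self.hi is not None

    def matrix(self, sex: str, age: int) -> np.ndarray:
        return self.value[_sex_index(sex), age - int(self.ages[0])]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for sex in SEXES:
            si = _sex_index(sex)
            for ai, age in enumerate(self.ages):
                for f in range(N_STATES):
                    for t in range(N_STATES):
                        rec = {
                            "sex": sex,
                            "age": int(age),
                            "from": STATE_LABELS[f],
                            "to": STATE_LABELS[t],
                            "value": self.value[si, ai, f, t],
                        }
                        if self.has_ci:
                            rec["lo"] = self.lo[si, ai, f, t]
                            rec["hi"] = self.hi[si, ai, f, t]
                        recs.append(rec)
        return pd.DataFrame(recs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TransitionTable":
        ages = np.arange(int(df["age"].min()), int(df["age"].max()) + 1)
        n = len(ages)
        has_ci = "lo" in df.columns and "hi" in df.columns and df["lo"].notna().all()
        value = np.full((2, n, N_STATES, N_STATES), np.nan)
        lo = np.full_like(value, np.nan) if has_ci else None
        hi = np.full_like(value, np.nan) if has_ci else None
        for i, row in df.iterrows():
            si = _sex_index(str(row["sex"]))
            ai = int(row["age"]) - int(ages[0])
            f = int(_state_from_label(row["from"]))
            t = int(_state_from_label(row["to"]))
            value[si, ai, f, t] = float(row["value"])
            if has_ci:
                lo[si, ai, f, t] = float(row["lo"])
                hi[si, ai, f, t] = float(row["hi"])
        if np.isnan(value).any():
            raise LoadError("transitions.csv: missing (sex, age, from, to) cells")
        return cls(value=value, lo=lo, hi=hi, ages=ages)


@dataclass
class HazardRatios:
    """Multipliers on the all-cause mortality hazard by weight status.

    Applied only from ``min_age_applied`` (default 20) upward; younger ages
    share the baseline schedule regardless of weight status, a deliberately
    conservative choice given the absence of child-specific risk data.
    ``hr[HEALTHY]`` is identically 1.
    """

    hr: np.ndarray  # (3,)
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    min_age_applied: int = 20

    @property
    def has_ci(self) -> bool:
        return self.lo is not None and self.hi is not None

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for s in range(N_STATES):
            rec = {"state": STATE_LABELS[s], "hr": self.hr[s]}
            if self.has_ci:
                rec["lo"] = self.lo[s]
                rec["hi"] = self.hi[s]
            recs.append(rec)
        return pd.DataFrame(recs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, min_age_applied: int = 20) -> "HazardRatios":
        hr = np.ones(N_STATES)
        has_ci = "lo" in df.columns and "hi" in df.columns and df["lo"].notna().all()
        lo = np.ones(N_STATES) if has_ci else None
        hi = np.ones(N_STATES) if has_ci else None
        for _, row in df.iterrows():
            s = int(_state_from_label(row["state"]))
            hr[s] = float(row["hr"])
            if has_ci:
                lo[s] = float(row["lo"])
                hi[s] = float(row["hi"])
        return cls(hr=hr, lo=lo, hi=hi, min_age_applied=min_age_applied)


@dataclass
class MortalityGroupTable:
    """All-cause mortality rates (per person-year) by sex and 5-year group."""

    df: pd.DataFrame  # columns: sex, age_lo, age_hi, rate

    def rates(self, sex: str) -> pd.DataFrame:
        sub = self.df[self.df["sex"] == sex].sort_values("age_lo")
        return sub.reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        return self.df.copy()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MortalityGroupTable":
        need = {"sex", "age_lo", "age_hi", "rate"}
        if not need.issubset(df.columns):
            raise LoadError(f"mortality.csv: columns must include {sorted(need)}")
        out = df.copy()
        out["age_lo"] = out["age_lo"].astype(int)
        out["age_hi"] = out["age_hi"].astype(int)
        out["rate"] = out["rate"].astype(float)
        return cls(df=out.reset_index(drop=True))


@dataclass
class UtilityTable:
    """Utility weights u[sex, age-5, state] resolved to single ages 5-74.

    Structural rules enforced on load:

    * ages 5-17: utility 1.0 for every state (no child utility data exists),
    * ages 18-34: sex/age-specific but identical across weight states,
    * ages 35+: sex/age/state-specific.

    ``bands`` keeps the original age-band rows (sex, age_lo, age_hi, state,
    value[, lo, hi]) so files round-trip exactly; ``state`` may be ``ALL``
    for bands that do not distinguish weight status.
    """

    value: np.ndarray  # (2, n_ages, 3)
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    ages: np.ndarray = field(default_factory=lambda: np.arange(5, 75))
    bands: pd.DataFrame | None = None

    STATE_FREE_MAX_AGE = 34
    CHILD_MAX_AGE = 17

    @property
    def has_ci(self) -> bool:
        return self.lo is not None and self.hi is not None

    def get(self, sex: str, age: int) -> np.ndarray:
        return self.value[_sex_index(sex), age - int(self.ages[0])]

    def to_frame(self) -> pd.DataFrame:
        if self.bands is not None:
            return self.bands.copy()
        recs = []
        for sex in SEXES:
            si = _sex_index(sex)
            for ai, age in enumerate(self.ages):
                for s in range(N_STATES):
                    rec = {
                        "sex": sex,
                        "age_lo": int(age),
                        "age_hi": int(age),
                        "state": STATE_LABELS[s],
                        "value": self.value[si, ai, s],
                    }
                    if self.has_ci:
                        rec["lo"] = self.lo[si, ai, s]
                        rec["hi"] = self.hi[si, ai, s]
                    recs.append(rec)
        return pd.DataFrame(recs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, max_age: int = 74) -> "UtilityTable":
        ages = np.arange(5, max_age + 1)
        n = len(ages)
        has_ci = "lo" in df.columns and "hi" in df.columns and df["lo"].notna().all()
        value = np.full((2, n, N_STATES), np.nan)
        lo = np.full_like(value, np.nan) if has_ci else None
        hi = np.full_like(value, np.nan) if has_ci else None
        for i, row in df.iterrows():
            si = _sex_index(str(row["sex"]))
            a0, a1 = int(row["age_lo"]), int(row["age_hi"])
            label = str(row["state"]).strip().upper()
            states = (
                list(range(N_STATES))
                if label == "ALL"
                else [int(_state_from_label(label))]
            )
            sl = slice(max(a0, 5) - 5, min(a1, max_age) - 5 + 1)
            for s in states:
                value[si, sl, s] = float(row["value"])
                if has_ci:
                    lo[si, sl, s] = float(row["lo"])
                    hi[si, sl, s] = float(row["hi"])
        if np.isnan(value).any():
            missing = np.argwhere(np.isnan(value))[0]
            raise LoadError(
                "utilities.csv: no band covers "
                f"(sex={SEXES[missing[0]]}, age={5 + missing[1]}, "
                f"state={STATE_LABELS[missing[2]]})"
            )
        return cls(value=value, lo=lo, hi=hi, ages=ages, bands=df.copy())


# ---------------------------------------------------------------------------
# Options and the bundle
# ---------------------------------------------------------------------------


@dataclass
class ModelOptions:
    """Switches for conventions the source model leaves unstated.

    calibrate_baseline
        Treat the all-cause rate as a prevalence-weighted mixture and divide
        by sum(prev * hr) so the mixture reproduces the all-cause schedule
        (off: the rate is used directly as the healthy-weight baseline).
    half_cycle
        Accrue person-years as the mean of start- and end-of-cycle occupancy
        instead of full first-of-cycle accrual.
    transition_order
        'death_first' (deaths compete at the state occupied that year, then
        survivors transition) or 'transition_first'.
    mortality_fit
        'global' — one log-linear fit per sex over all groups; 'piecewise' —
        log-linear interpolation between group midpoints.
    """

    calibrate_baseline: bool = False
    half_cycle: bool = False
    transition_order: str = "death_first"
    mortality_fit: str = "global"


@dataclass
class ParameterSet:
    """The complete, validated bundle of inputs for one model run."""

    population: PopulationTable
    prevalence: PrevalenceTable
    transitions: TransitionTable
    mortality: MortalityGroupTable
    hazard_ratios: HazardRatios
    utilities: UtilityTable
    horizon_age: int = 75
    discount_rate: float = 0.03
    start_year: int = 2019
    options: ModelOptions = field(default_factory=ModelOptions)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def replace(self, **kw) -> "ParameterSet":
        return replace(self.copy(), **kw)

    @property
    def start_ages(self) -> range:
        return CHILD_AGES


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check_ci(table: str, value, lo, hi, out: list[Violation]) -> None:
    if lo is None or hi is None:
        return
    bad = np.argwhere(~((np.asarray(lo) <= np.asarray(value) + 1e-12) &
                        (np.asarray(value) <= np.asarray(hi) + 1e-12)))
    for idx in bad[:20]:
        out.append(
            Violation(table, tuple(int(i) for i in idx), "ci_brackets_value",
                      "CI bounds must bracket the point value")
        )


def validate(ps: ParameterSet) -> list[Violation]:
    """Check every model invariant; return [] iff the bundle is runnable.

    Reporting only — never raises.  Each violation names the table, the
    failing index and the rule, so callers (and the CLI) can point at the
    offending row.
    """
    v: list[Violation] = []

    # population
    for sex in SEXES:
        for age, c in ps.population.counts.get(sex, {}).items():
            if c < 0:
                v.append(Violation("population", (sex, age), "nonnegative_count",
                                   f"count {c} < 0"))
    if ps.population.grouped:
        for sex in SEXES:
            if sorted(ps.population.counts[sex]) != [5, 10, 15]:
                v.append(Violation("population", (sex,), "group_starts",
                                   "grouped ages must be exactly {5, 10, 15}"))

    # prevalence
    p = ps.prevalence.value
    if np.any((p < -1e-12) | (p > 1 + 1e-12)):
        for idx in np.argwhere((p < -1e-12) | (p > 1 + 1e-12))[:20]:
            v.append(Violation("prevalence", tuple(map(int, idx)), "in_unit_interval",
                               f"value {p[tuple(idx)]} outside [0,1]"))
    sums = p.sum(axis=-1)
    for idx in np.argwhere(np.abs(sums - 1) > ROW_SUM_TOL):
        si, ai = map(int, idx)
        v.append(Violation("prevalence", (SEXES[si], 5 + ai), "row_sum_one",
                           f"states sum to {sums[si, ai]:.12f}, not 1"))
    _check_ci("prevalence", p, ps.prevalence.lo, ps.prevalence.hi, v)

    # transitions
    q = ps.transitions.value
    if np.any((q < -1e-12) | (q > 1 + 1e-12)):
        for idx in np.argwhere((q < -1e-12) | (q > 1 + 1e-12))[:20]:
            v.append(Violation("transitions", tuple(map(int, idx)), "in_unit_interval",
                               f"value {q[tuple(idx)]} outside [0,1]"))
    qsums = q.sum(axis=-1)
    for idx in np.argwhere(np.abs(qsums - 1) > ROW_SUM_TOL)[:50]:
        si, ai, f = map(int, idx)
        v.append(Violation(
            "transitions",
            (SEXES[si], int(ps.transitions.ages[0]) + ai, STATE_LABELS[f]),
            "row_sum_one", f"row sums to {qsums[si, ai, f]:.12f}, not 1"))
    need_max = ps.horizon_age - 1
    if int(ps.transitions.ages[-1]) < need_max or int(ps.transitions.ages[0]) > 5:
        v.append(Violation("transitions", (), "age_coverage",
                           f"ages must cover [5, {need_max}]"))
    _check_ci("transitions", q, ps.transitions.lo, ps.transitions.hi, v)

    # mortality
    for sex in SEXES:
        sub = ps.mortality.rates(sex)
        if (sub["rate"] <= 0).any():
            for i in sub.index[sub["rate"] <= 0]:
                v.append(Violation("mortality", (sex, int(sub.loc[i, "age_lo"])),
                                   "positive_rate", "rate must be > 0"))
        prev_hi = None
        for _, row in sub.iterrows():
            if row["age_hi"] < row["age_lo"]:
                v.append(Violation("mortality", (sex, int(row["age_lo"])),
                                   "group_order", "age_hi < age_lo"))
            if prev_hi is not None and row["age_lo"] != prev_hi + 1:
                v.append(Violation("mortality", (sex, int(row["age_lo"])),
                                   "contiguous_groups",
                                   "groups must be contiguous and non-overlapping"))
            prev_hi = row["age_hi"]

    # hazard ratios
    hr = ps.hazard_ratios
    for s in range(N_STATES):
        if hr.hr[s] <= 0:
            v.append(Violation("hazard_ratios", (STATE_LABELS[s],), "positive",
                               f"hr {hr.hr[s]} must be > 0"))
    if abs(hr.hr[WeightState.HEALTHY] - 1.0) > 1e-12:
        v.append(Violation("hazard_ratios", ("HW",), "healthy_is_baseline",
                           "hr[HEALTHY] must equal 1"))
    if hr.has_ci:
        for s in range(N_STATES):
            if not (0 < hr.lo[s] <= hr.hr[s] <= hr.hi[s]):
                v.append(Violation("hazard_ratios", (STATE_LABELS[s],),
                                   "ci_brackets_value",
                                   "CI must be positive and bracket the point value"))

    # utilities
    u = ps.utilities.value
    if np.any((u < -1e-12) | (u > 1 + 1e-12)):
        for idx in np.argwhere((u < -1e-12) | (u > 1 + 1e-12))[:20]:
            v.append(Violation("utilities", tuple(map(int, idx)), "in_unit_interval",
                               f"value {u[tuple(idx)]} outside [0,1]"))
    child = u[:, : UtilityTable.CHILD_MAX_AGE - 5 + 1, :]
    for idx in np.argwhere(np.abs(child - 1.0) > 1e-12)[:20]:
        si, ai, s = map(int, idx)
        v.append(Violation("utilities", (SEXES[si], 5 + ai, STATE_LABELS[s]),
                           "children_full_health",
                           "ages 5-17 must have utility 1.0 for all states"))
    young_adult = u[:, 18 - 5: UtilityTable.STATE_FREE_MAX_AGE - 5 + 1, :]
    spread = young_adult.max(axis=-1) - young_adult.min(axis=-1)
    for idx in np.argwhere(spread > 1e-12)[:20]:
        si, ai = map(int, idx)
        v.append(Violation("utilities", (SEXES[si], 18 + ai), "state_free_18_34",
                           "ages 18-34 must share one utility across weight states"))
    _check_ci("utilities", u, ps.utilities.lo, ps.utilities.hi, v)

    # scalars
    if ps.discount_rate < 0:
        v.append(Violation("parameter_set", (), "discount_nonnegative",
                           f"discount_rate {ps.discount_rate} < 0"))
    if ps.horizon_age <= max(CHILD_AGES):
        v.append(Violation("parameter_set", (), "horizon_beyond_start",
                           f"horizon_age {ps.horizon_age} must exceed 19"))
    return v


def _raise_if_invalid(ps: ParameterSet) -> ParameterSet:
    violations = validate(ps)
    if violations:
        msg = "; ".join(str(x) for x in violations[:5])
        raise ValidationError(
            f"{len(violations)} invariant violation(s): {msg}")
    return ps


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "population": "population.csv",
    "prevalence": "prevalence.csv",
    "transitions": "transitions.csv",
    "mortality": "mortality.csv",
    "hazard_ratios": "hazard_ratios.csv",
    "utilities": "utilities.csv",
}


def _dense_to_frame(table, _cols) -> pd.DataFrame:
    recs = []
    for sex in SEXES:
        si = _sex_index(sex)
        for ai, age in enumerate(table.ages):
            for s in range(N_STATES):
                rec = {"sex": sex, "age": int(age), "state": STATE_LABELS[s],
                       "value": table.value[si, ai, s]}
                if table.has_ci:
                    rec["lo"] = table.lo[si, ai, s]
                    rec["hi"] = table.hi[si, ai, s]
                recs.append(rec)
    return pd.DataFrame(recs)


def _dense_from_frame(df, ages, fname, age_col):
    n = len(ages)
    has_ci = "lo" in df.columns and "hi" in df.columns and df["lo"].notna().all()
    value = np.full((2, n, N_STATES), np.nan)
    lo = np.full_like(value, np.nan) if has_ci else None
    hi = np.full_like(value, np.nan) if has_ci else None
    for i, row in df.iterrows():
        try:
            si = _sex_index(str(row["sex"]))
            ai = int(row[age_col]) - int(ages[0])
            s = int(_state_from_label(row["state"]))
        except (KeyError, LoadError) as e:
            raise LoadError(f"{fname} row {i}: {e}") from None
        if not 0 <= ai < n:
            raise LoadError(f"{fname} row {i}: age {row[age_col]} out of range")
        value[si, ai, s] = float(row["value"])
        if has_ci:
            lo[si, ai, s] = float(row["lo"])
            hi[si, ai, s] = float(row["hi"])
    if np.isnan(value).any():
        raise LoadError(f"{fname}: missing (sex, age, state) cells")
    return value, lo, hi


def load_parameter_set(config: str | Path | Mapping) -> ParameterSet:
    """Load and validate a full parameter bundle.

    ``config`` is either a YAML/JSON file (or dict) naming the six table
    files plus the scalars, or a directory containing the conventionally
    named CSVs (population.csv, prevalence.csv, ...).

    Raises :class:`LoadError` on schema problems (naming file/row/column)
    and :class:`ValidationError` if any invariant fails.
    """
    if isinstance(config, (str, Path)):
        path = Path(config)
        if path.is_dir():
            cfg: dict = {"tables_dir": str(path)}
            base = path
        else:
            text = path.read_text()
            cfg = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} \
                else json.loads(text)
            base = path.parent
    else:
        cfg = dict(config)
        base = Path(cfg.get("tables_dir", "."))

    tdir = Path(cfg.get("tables_dir", "."))
    if not tdir.is_absolute():
        tdir = base / tdir

    def _path(key: str) -> Path:
        p = Path(cfg.get(key, _TABLE_FILES[key]))
        return p if p.is_absolute() else tdir / p

    def _read(key: str) -> pd.DataFrame:
        p = _path(key)
        if not p.exists():
            raise LoadError(f"missing input file: {p}")
        try:
            # round_trip parsing keeps load(write(x)) bit-exact
            return pd.read_csv(p, float_precision="round_trip")
        except Exception as e:  # malformed CSV
            raise LoadError(f"{p.name}: {e}") from None

    ps = ParameterSet(
        population=PopulationTable.from_frame(_read("population")),
        prevalence=PrevalenceTable.from_frame(_read("prevalence")),
        transitions=TransitionTable.from_frame(_read("transitions")),
        mortality=MortalityGroupTable.from_frame(_read("mortality")),
        hazard_ratios=HazardRatios.from_frame(
            _read("hazard_ratios"),
            min_age_applied=int(cfg.get("hr_min_age", 20))),
        utilities=UtilityTable.from_frame(
            _read("utilities"), max_age=int(cfg.get("horizon_age", 75)) - 1),
        horizon_age=int(cfg.get("horizon_age", 75)),
        discount_rate=float(cfg.get("discount_rate", 0.03)),
        start_year=int(cfg.get("start_year", 2019)),
        options=ModelOptions(**cfg.get("options", {})),
    )
    if not ps.prevalence.has_ci or not ps.transitions.has_ci:
        warnings.warn(
            "parameter set loaded without CI bounds on prevalence and/or "
            "transitions; the corresponding sensitivity axes are disabled",
            stacklevel=2)
    return _raise_if_invalid(ps)


def save_parameter_set(ps: ParameterSet, out_dir: str | Path,
                       config_name: str = "config.yaml") -> Path:
    """Write the CSV bundle plus a config file; inverse of load_parameter_set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ps.population.to_frame().to_csv(out / "population.csv", index=False)
    ps.prevalence.to_frame().to_csv(out / "prevalence.csv", index=False)
    ps.transitions.to_frame().to_csv(out / "transitions.csv", index=False)
    ps.mortality.to_frame().to_csv(out / "mortality.csv", index=False)
    ps.hazard_ratios.to_frame().to_csv(out / "hazard_ratios.csv", index=False)
    ps.utilities.to_frame().to_csv(out / "utilities.csv", index=False)
    cfg = {
        "tables_dir": ".",
        "horizon_age": ps.horizon_age,
        "discount_rate": ps.discount_rate,
        "start_year": ps.start_year,
        "hr_min_age": ps.hazard_ratios.min_age_applied,
        "options": {
            "calibrate_baseline": ps.options.calibrate_baseline,
            "half_cycle": ps.options.half_cycle,
            "transition_order": ps.options.transition_order,
            "mortality_fit": ps.options.mortality_fit,
        },
    }
    cfg_path = out / config_name
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return cfg_path
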