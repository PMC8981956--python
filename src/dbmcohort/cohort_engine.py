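"""The life-table / Markov cohort simulation.

Each starting (sex, single-age) cohort of children aged 5-19 is classified
into underweight / healthy weight / overweight-obese by the prevalence
table, then evolved in annual cycles to age 75 or death.  Per cycle, in the
default order, state-specific deaths are removed first (so death competes
at the state occupied that year) and the survivors are redistributed by the
annual transition matrix.  Persons alive at the start of a cycle accrue one
life-year, discounted at 1/(1+r)^cycle with the first cycle undiscounted
(t = 0 is the start year for every cohort); QALYs weight that accrual by
the sex/age/state utility.  Deaths are accumulated undiscounted.

Outcomes aggregate into the familiar burden layout: deaths, years of life
lived and QALYs by sex x starting-age-group {5-9, 10-14, 15-19} x weight
state, where life-years and QALYs are attributed to the state occupied in
each cycle and deaths to the state at the start of the death cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mortality import (
    SingleAgeMortality,
    death_probability_array,
    extrapolate_single_age,
)
from .parameters import (
    CHILD_AGES,
    N_STATES,
    ParameterSet,
    SEXES,
    STATE_LABELS,
    _sex_index,
)

__all__ = [
    "CohortTrace",
    "OutcomeSummary",
    "CohortModel",
    "discount_factor",
    "init_cohort",
    "step_cycle",
    "run_cohort",
    "run_population",
]

AGE_GROUPS = ((5, 9), (10, 14), (15, 19))


def discount_factor(cycle, r: float):
    """1/(1+r)^cycle; cycle 0 (the start year) is undiscounted."""
    if r < -1:
        raise ValueError("discount rate must be > -1")
    cycle = np.asarray(cycle)
    if np.any(cycle < 0):
        raise ValueError("cycle must be >= 0")
    out = (1.0 + r) ** (-cycle.astype(float))
    return float(out) if out.ndim == 0 else out


def _age_group(start_age: int) -> str:
    for lo, hi in AGE_GROUPS:
        if lo <= start_age <= hi:
            return f"{lo}-{hi}"
    raise ValueError(f"starting age {start_age} outside [5, 19]")


@dataclass
class CohortTrace:
    """Cycle-by-cycle bookkeeping for one starting (sex, age) cohort.

    ``occupancy[c]`` is persons alive at the start of cycle c (model age
    start_age + c); row ``n_cycles`` holds the survivors at the horizon.
    Deaths are attributed to the state occupied at the start of the cycle
    of death; ly/qaly rows are already discounted.
    """

    sex: str
    start_age: int
    occupancy: np.ndarray   # (n_cycles + 1, 3)
    deaths: np.ndarray      # (n_cycles, 3), undiscounted persons
    ly: np.ndarray          # (n_cycles, 3), discounted person-years
    qaly: np.ndarray        # (n_cycles, 3), discounted QALYs

    @property
    def n_cycles(self) -> int:
        return self.deaths.shape[0]

    def totals(self) -> dict[str, np.ndarray]:
        return {
            "deaths": self.deaths.sum(axis=0),
            "yll": self.ly.sum(axis=0),
            "qaly": self.qaly.sum(axis=0),
        }


class OutcomeSummary:
    """Deaths / years of life lived / QALYs by sex x starting-age-group x state.

    Wraps a tidy frame with columns (sex, age_group, state, deaths, yll,
    qaly); totals are recomputed from the margins on demand so they can
    never drift out of sync.
    """

    OUTCOMES = ("deaths", "yll", "qaly")

    def __init__(self, data: pd.DataFrame):
        self.data = data.reset_index(drop=True)

    def total(self, outcome: str, sex: str | None = None) -> float:
        df = self.data if sex is None else self.data[self.data["sex"] == sex]
        return float(df[outcome].sum())

    def by_sex(self) -> pd.DataFrame:
        out = self.data.groupby("sex", sort=False)[list(self.OUTCOMES)].sum()
        out.loc["total"] = out.sum()
        return out

    def table(self) -> pd.DataFrame:
        """Publication-shaped table: sex panels x age-group rows with totals,
        state columns per outcome."""
        blocks = []
        panels = list(SEXES) + ["both"]
        for sex in panels:
            df = self.data if sex == "both" else self.data[self.data["sex"] == sex]
            piv = df.pivot_table(index="age_group", columns="state",
                                 values=list(self.OUTCOMES), aggfunc="sum",
                                 sort=False)
            piv = piv.reindex(columns=pd.MultiIndex.from_product(
                [self.OUTCOMES, list(STATE_LABELS)]))
            piv[[(o, "Total") for o in self.OUTCOMES]] = pd.concat(
                {o: piv[o].sum(axis=1) for o in self.OUTCOMES}, axis=1)
            piv.loc["Total"] = piv.sum(axis=0)
            piv.index = pd.MultiIndex.from_product([[sex], piv.index],
                                                   names=["sex", "age_group"])
            blocks.append(piv)
        return pd.concat(blocks)

    def to_csv(self, path) -> None:
        self.table().to_csv(path)


# ---------------------------------------------------------------------------
# Precomputed model
# ---------------------------------------------------------------------------


class CohortModel:
    """A ParameterSet compiled into dense arrays, ready to simulate.

    Compiling once (mortality extrapolation, hazard-ratio application,
    utility resolution) makes repeated runs — scenario suites and
    10,000-iteration probabilistic sensitivity analyses — cheap.
    """

    def __init__(self, ps: ParameterSet):
        self.ps = ps
        self.horizon = ps.horizon_age
        self.ages = np.arange(5, self.horizon)      # cycle ages
        self.sam: SingleAgeMortality = extrapolate_single_age(
            ps.mortality, 5, self.horizon - 1, mode=ps.options.mortality_fit)
        self.qdeath = death_probability_array(
            self.sam, ps.hazard_ratios,
            calibrate_baseline=ps.options.calibrate_baseline,
            prevalence=ps.prevalence if ps.options.calibrate_baseline else None,
        )                                           # (2, n_ages, 3)
        a0 = int(ps.transitions.ages[0])
        idx = self.ages - a0
        self.Q = ps.transitions.value[:, idx]       # (2, n_ages, 3, 3)
        u0 = int(ps.utilities.ages[0])
        self.U = ps.utilities.value[:, self.ages - u0]  # (2, n_ages, 3)

    # -- single cohort (readable reference path) ---------------------------

    def init_cohort(self, sex: str, start_age: int) -> np.ndarray:
        if start_age not in CHILD_AGES:
            raise ValueError(f"starting age must be in [5, 19], got {start_age}")
        n = self.ps.population.count_single_age(sex, start_age)
        return n * self.ps.prevalence.get(sex, start_age)

    def step_cycle(self, occupancy: np.ndarray, sex: str, age: int
                   ) -> tuple[np.ndarray, np.ndarray]:
        """One annual cycle; returns (next_occupancy, deaths_by_state)."""
        occupancy = np.asarray(occupancy, dtype=float)
        if np.any(occupancy < 0):
            raise ValueError("occupancy must be non-negative")
        si = _sex_index(sex)
        ai = age - 5
        qd = self.qdeath[si, ai]
        Q = self.Q[si, ai]
        if self.ps.options.transition_order == "death_first":
            deaths = occupancy * qd
            nxt = (occupancy - deaths) @ Q
        else:  # transition_first: move, then die at the destination state
            moved = occupancy @ Q
            deaths = moved * qd
            nxt = moved - deaths
        return nxt, deaths

    def run_cohort(self, sex: str, start_age: int) -> CohortTrace:
        occ = self.init_cohort(sex, start_age)
        n_cycles = self.horizon - start_age
        si = _sex_index(sex)
        r = self.ps.discount_rate
        occupancy = np.empty((n_cycles + 1, N_STATES))
        deaths = np.empty((n_cycles, N_STATES))
        ly = np.empty((n_cycles, N_STATES))
        qaly = np.empty((n_cycles, N_STATES))
        occupancy[0] = occ
        for c in range(n_cycles):
            age = start_age + c
            nxt, d = self.step_cycle(occupancy[c], sex, age)
            occupancy[c + 1] = nxt
            deaths[c] = d
            df = discount_factor(c, r)
            alive = (0.5 * (occupancy[c] + nxt)
                     if self.ps.options.half_cycle else occupancy[c])
            ly[c] = alive * df
            qaly[c] = ly[c] * self.U[si, age - 5]
        return CohortTrace(sex=sex, start_age=start_age, occupancy=occupancy,
                           deaths=deaths, ly=ly, qaly=qaly)

    # -- all cohorts at once (fast path) -----------------------------------

    def _run_all_cohorts(self, sex: str) -> dict[str, np.ndarray]:
        """Evolve the 15 starting-age cohorts of one sex simultaneously,
        stepping by calendar cycle and gathering each cohort's attained-age
        parameters.  Returns per-cohort state totals (15, 3) per outcome."""
        si = _sex_index(sex)
        start_ages = np.array(list(CHILD_AGES))
        n_coh = len(start_ages)
        occ = np.empty((n_coh, N_STATES))
        for i, a in enumerate(start_ages):
            occ[i] = self.init_cohort(sex, int(a))
        deaths_tot = np.zeros((n_coh, N_STATES))
        ly_tot = np.zeros((n_coh, N_STATES))
        qaly_tot = np.zeros((n_coh, N_STATES))
        r = self.ps.discount_rate
        max_cycles = self.horizon - int(start_ages.min())
        death_first = self.ps.options.transition_order == "death_first"
        for c in range(max_cycles):
            ages = start_ages + c
            act = ages < self.horizon
            ai = ages[act] - 5
            qd = self.qdeath[si, ai]                     # (k, 3)
            Q = self.Q[si, ai]                           # (k, 3, 3)
            o = occ[act]
            if death_first:
                d = o * qd
                nxt = np.einsum("ks,kst->kt", o - d, Q)
            else:
                moved = np.einsum("ks,kst->kt", o, Q)
                d = moved * qd
                nxt = moved - d
            df = discount_factor(c, r)
            alive = 0.5 * (o + nxt) if self.ps.options.half_cycle else o
            lyc = alive * df
            deaths_tot[act] += d
            ly_tot[act] += lyc
            qaly_tot[act] += lyc * self.U[si, ai]
            occ[act] = nxt
        return {"deaths": deaths_tot, "yll": ly_tot, "qaly": qaly_tot,
                "survivors": occ, "start_ages": start_ages}

    def run_population(self) -> OutcomeSummary:
        recs = []
        for sex in SEXES:
            res = self._run_all_cohorts(sex)
            for (lo, hi) in AGE_GROUPS:
                mask = (res["start_ages"] >= lo) & (res["start_ages"] <= hi)
                for s in range(N_STATES):
                    recs.append({
                        "sex": sex,
                        "age_group": f"{lo}-{hi}",
                        "state": STATE_LABELS[s],
                        "deaths": res["deaths"][mask, s].sum(),
                        "yll": res["yll"][mask, s].sum(),
                        "qaly": res["qaly"][mask, s].sum(),
                    })
        return OutcomeSummary(pd.DataFrame(recs))


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def init_cohort(ps: ParameterSet, sex: str, start_age: int) -> np.ndarray:
    """Initial occupancy: population(sex, age) x prevalence(sex, age, .)."""
    return CohortModel(ps).init_cohort(sex, start_age)


def step_cycle(occupancy, sex: str, age: int, ps: ParameterSet,
               mortality_model: CohortModel | None = None):
    """One annual cycle on an explicit occupancy vector."""
    model = mortality_model if mortality_model is not None else CohortModel(ps)
    return model.step_cycle(occupancy, sex, age)


def run_cohort(ps: ParameterSet, sex: str, start_age: int) -> CohortTrace:
    """Evolve one starting cohort to the horizon; see CohortTrace."""
    return CohortModel(ps).run_cohort(sex, start_age)


def run_population(ps: ParameterSet) -> OutcomeSummary:
    """Run every sex x starting-age cohort and aggregate the burden table."""
    return CohortModel(ps).run_population()
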