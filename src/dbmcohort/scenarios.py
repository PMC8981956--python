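"""Scenario transformations of a parameter set and the standard suite.

A scenario scales the prevalence of one or both non-healthy weight states
and/or the annual transition probabilities INTO those states by a relative
change (x0.9 for a "10% reduction", x0 for elimination, x1.1 for a 10%
rise).  All probability mass removed from — or added to — a target state is
taken from the healthy-weight cell of the same row, so rows stay exactly
row-stochastic; "everyone healthy weight" is the -100% limiting case.
Reductions are relative (multiplicative), not percentage-point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_engine import OutcomeSummary, run_population
from .parameters import ParameterSet, WeightState

__all__ = ["ScenarioSpec", "apply_scenario", "run_scenario_suite",
           "standard_suite", "suite_frame"]

_UW = int(WeightState.UNDERWEIGHT)
_HW = int(WeightState.HEALTHY)
_OWB = int(WeightState.OVERWEIGHT_OBESE)


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario definition.

    relative_change: -0.10 / -0.20 / -0.50 for reductions, -1.0 for
    elimination, +0.10 for a rise.  applies_to selects whether prevalence,
    inbound transition probabilities, or both (default) are scaled.
    A discount_rate_override leaves all probabilities untouched and only
    re-discounts outcomes.
    """

    name: str
    target_states: tuple[int, ...] = ()
    relative_change: float = 0.0
    applies_to: str = "both"            # 'prevalence' | 'transitions' | 'both'
    discount_rate_override: float | None = None

    def __post_init__(self):
        if self.applies_to not in ("prevalence", "transitions", "both"):
            raise ValueError(f"bad applies_to {self.applies_to!r}")
        for s in self.target_states:
            if int(s) == _HW:
                raise ValueError("HEALTHY cannot be a scenario target")


def _scale_onto_healthy(table, targets, factor: float, label: str) -> None:
    """Scale target-state point values along the last axis in place, moving
    the difference onto the HEALTHY cell.  Errors if healthy mass would go
    negative (an increase too large to absorb).  CI bounds on target cells
    are scaled by the same factor; healthy bounds are shifted with the
    healthy point value, then re-bracketed and clipped to [0, 1]."""
    arr = table.value
    healthy_delta = np.zeros_like(arr[..., _HW])
    for s in targets:
        s = int(s)
        delta = arr[..., s] * (factor - 1.0)
        arr[..., s] += delta
        healthy_delta -= delta
        if table.lo is not None:
            table.lo[..., s] *= factor
            table.hi[..., s] *= factor
    arr[..., _HW] += healthy_delta
    bad = arr[..., _HW] < -1e-12
    if np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(
            f"scenario drives HEALTHY mass negative in {label} at index {idx}")
    np.clip(arr[..., _HW], 0.0, None, out=arr[..., _HW])
    if table.lo is not None:
        table.lo[..., _HW] += healthy_delta
        table.hi[..., _HW] += healthy_delta
        table.lo = np.clip(np.minimum(table.lo, arr), 0.0, 1.0)
        table.hi = np.clip(np.maximum(table.hi, arr), 0.0, 1.0)


def apply_scenario(ps: ParameterSet, spec: ScenarioSpec) -> ParameterSet:
    """Return a new ParameterSet transformed by the scenario (input untouched)."""
    out = ps.copy()
    if spec.discount_rate_override is not None:
        out.discount_rate = float(spec.discount_rate_override)
    factor = 1.0 + spec.relative_change
    if spec.target_states and spec.relative_change != 0.0:
        if factor < 0:
            raise ValueError("relative_change below -1 is not meaningful")
        if spec.applies_to in ("prevalence", "both"):
            _scale_onto_healthy(out.prevalence, spec.target_states, factor,
                                "prevalence")
        if spec.applies_to in ("transitions", "both"):
            _scale_onto_healthy(out.transitions, spec.target_states, factor,
                                "transitions")
    return out


def standard_suite(discount_rates=(0.0, 0.04, 0.05)) -> list[ScenarioSpec]:
    """The canonical scenario list: base case; 10/20/50% reductions and
    elimination of underweight, of overweight/obesity, and of both; a 10%
    rise in overweight/obesity; and alternative discount rates."""
    specs = [ScenarioSpec("base-case")]
    named = {(_UW,): "underweight", (_OWB,): "overweight/obesity",
             (_UW, _OWB): "underweight and overweight/obesity"}
    for targets, label in named.items():
        for rc in (-0.10, -0.20, -0.50):
            specs.append(ScenarioSpec(f"{label} {int(-rc * 100)}% reduction",
                                      targets, rc))
        elim = ("all healthy weight" if len(targets) == 2
                else f"no {label}")
        specs.append(ScenarioSpec(elim, targets, -1.0))
    specs.append(ScenarioSpec("overweight/obesity 10% increase",
                              (_OWB,), +0.10))
    for r in discount_rates:
        specs.append(ScenarioSpec(f"discount rate {r:.0%}",
                                  discount_rate_override=r))
    return specs


def run_scenario_suite(
    ps: ParameterSet,
    specs: list[ScenarioSpec] | None = None,
) -> dict[str, OutcomeSummary]:
    """Run the base case plus every scenario; returns name -> OutcomeSummary."""
    specs = specs if specs is not None else standard_suite()
    return {spec.name: run_population(apply_scenario(ps, spec))
            for spec in specs}


def suite_frame(results: dict[str, OutcomeSummary]) -> pd.DataFrame:
    """Flatten suite results into a deaths/YLL/QALY-by-sex table plus
    percentage differences against the base case (first entry)."""
    rows = []
    for name, summ in results.items():
        row: dict = {"scenario": name}
        for outcome in OutcomeSummary.OUTCOMES:
            for sex in ("male", "female", None):
                key = f"{outcome}_{sex or 'total'}"
                row[key] = summ.total(outcome, sex)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("scenario")
    base = df.iloc[0]
    pct = 100.0 * (df - base) / base
    return df.join(pct.add_prefix("pct_diff_"))
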