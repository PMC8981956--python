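"""Generators for complete, valid parameter sets.

Two entry points:

* :func:`generate_parameter_set` builds a fully synthetic, seeded parameter
  bundle with the statistical structure the model assumes — prevalence rows
  summing to 1 along smooth age curves, row-stochastic transition matrices
  with a dominant diagonal, Gompertz (log-linear in age) mortality, hazard
  ratios above 1 for the non-healthy states with lognormal-style CIs, and
  utilities obeying the three age-band structural rules.  Useful for
  property testing and for exercising every analysis with no data download.

* :func:`vietnam_fixture` reproduces the published 2019 Vietnamese starting
  population (5-year-group census counts) and single-age weight-status
  prevalence for ages 5-19 exactly, and fills the remaining tables
  (transitions, mortality, hazard ratios, utilities) with the documented
  synthetic defaults.  Those defaults are NOT the source study's input
  values — its full input tables live in a supplementary file that is not
  reproduced here — so fixture outputs characterise the model, not the
  published Vietnam estimates.  Callers holding the real input tables can
  pass them in to override the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    HazardRatios,
    MortalityGroupTable,
    N_STATES,
    ParameterSet,
    PopulationTable,
    PrevalenceTable,
    SEXES,
    STATE_LABELS,
    TransitionTable,
    UtilityTable,
    WeightState,
    validate,
)

__all__ = ["SynthConfig", "generate_parameter_set", "vietnam_fixture",
           "VIETNAM_POPULATION", "VIETNAM_PREVALENCE"]

_UW = int(WeightState.UNDERWEIGHT)
_HW = int(WeightState.HEALTHY)
_OWB = int(WeightState.OVERWEIGHT_OBESE)


@dataclass
class SynthConfig:
    """Knobs for the synthetic generator; defaults emulate a population with
    a double burden of malnutrition in children and Vietnam-plausible adult
    mortality.

    mortality_params: per-sex (intercept, slope) of log hazard vs age —
    e.g. (-9.8, 0.088) gives ~5.5e-5 at age 5 rising to ~3.6e-2 at age 74.
    transition_persistence: annual probability of keeping one's weight
    status (diagonal mass); the remainder is split between the other two
    states with most of it flowing to/through healthy weight.
    ci_relative_width: half-width of generated CIs relative to the point
    value for prevalence/transitions.
    """

    seed: int = 0
    horizon_age: int = 75
    uw_level: float = 0.14
    owb_level: float = 0.12
    prevalence_jitter: float = 0.02
    transition_persistence: float = 0.85
    mortality_params: dict = field(default_factory=lambda: {
        "male": (-9.6, 0.088), "female": (-10.1, 0.090)})
    hr_uw: tuple[float, float, float] = (1.50, 1.30, 1.73)
    hr_owb: tuple[float, float, float] = (1.15, 1.04, 1.27)
    utility_decline_per_decade: float = 0.03
    nonhealthy_utility_penalty: float = 0.02
    ci_relative_width: float = 0.10

    def __post_init__(self):
        if not 0 < self.transition_persistence <= 1:
            raise ValueError("transition_persistence must be in (0, 1]")
        if self.uw_level + self.owb_level >= 0.9:
            raise ValueError("non-healthy prevalence levels too large")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _make_prevalence(cfg: SynthConfig, rng: np.random.Generator
                     ) -> PrevalenceTable:
    ages = np.arange(5, 20)
    value = np.empty((2, len(ages), N_STATES))
    for si, sex in enumerate(SEXES):
        # smooth logit curves: UW peaks mid-childhood, OWB declines with age
        bump = _expit((ages - 9) / 2) * _expit((16 - ages) / 2)
        uw = cfg.uw_level * (0.8 + 0.8 * bump)
        owb = cfg.owb_level * (1.4 - 0.05 * (ages - 5))
        if sex == "female":
            owb = owb * 0.6
        uw = np.clip(uw + rng.normal(0, cfg.prevalence_jitter, uw.shape),
                     0.01, 0.45)
        owb = np.clip(owb + rng.normal(0, cfg.prevalence_jitter, owb.shape),
                      0.01, 0.45)
        value[si, :, _UW] = uw
        value[si, :, _OWB] = owb
        value[si, :, _HW] = 1.0 - uw - owb
    w = cfg.ci_relative_width
    lo = np.clip(value * (1 - w), 0, 1)
    hi = np.clip(value * (1 + w), 0, 1)
    # keep rows bracketed: healthy bounds recentred on the residual
    return PrevalenceTable(value=value, lo=np.minimum(lo, value),
                           hi=np.maximum(hi, value), ages=ages)


def _make_transitions(cfg: SynthConfig, rng: np.random.Generator,
                      horizon: int) -> TransitionTable:
    ages = np.arange(5, horizon)
    n = len(ages)
    value = np.empty((2, n, N_STATES, N_STATES))
    stay = cfg.transition_persistence
    off = 1.0 - stay
    for si in range(2):
        for ai in range(n):
            m = np.empty((N_STATES, N_STATES))
            # leavers mostly pass through healthy weight; direct UW<->OWB
            # flips are rare
            m[_UW] = (stay, off * 0.9, off * 0.1)
            m[_OWB] = (off * 0.1, off * 0.9, stay)
            m[_HW] = (off * 0.5, stay, off * 0.5)
            if off > 0:
                jitter = rng.uniform(0.9, 1.1, size=(N_STATES, N_STATES))
                m = m * jitter
                m[np.arange(3), np.arange(3)] = 0.0
                rowoff = m.sum(axis=1)
                np.fill_diagonal(m, 1.0 - rowoff)
            value[si, ai] = m
    w = cfg.ci_relative_width
    lo = np.clip(value * (1 - w), 0, 1)
    hi = np.clip(value * (1 + w), 0, 1)
    return TransitionTable(value=value, lo=np.minimum(lo, value),
                           hi=np.maximum(hi, value), ages=ages)


def _make_mortality(cfg: SynthConfig, horizon: int) -> MortalityGroupTable:
    rows = []
    for sex in SEXES:
        intercept, slope = cfg.mortality_params[sex]
        for lo in range(5, horizon + 5, 5):
            hi = lo + 4
            mid = (lo + hi + 1) / 2.0
            rows.append({"sex": sex, "age_lo": lo, "age_hi": hi,
                         "rate": float(np.exp(intercept + slope * mid))})
    return MortalityGroupTable.from_frame(pd.DataFrame(rows))


def _make_hazard_ratios(cfg: SynthConfig) -> HazardRatios:
    hr = np.ones(N_STATES)
    lo = np.ones(N_STATES)
    hi = np.ones(N_STATES)
    hr[_UW], lo[_UW], hi[_UW] = cfg.hr_uw[0], cfg.hr_uw[1], cfg.hr_uw[2]
    hr[_OWB], lo[_OWB], hi[_OWB] = cfg.hr_owb[0], cfg.hr_owb[1], cfg.hr_owb[2]
    return HazardRatios(hr=hr, lo=lo, hi=hi, min_age_applied=20)


def _make_utilities(cfg: SynthConfig, horizon: int) -> UtilityTable:
    rows = []
    for si, sex in enumerate(SEXES):
        rows.append({"sex": sex, "age_lo": 5, "age_hi": 17, "state": "ALL",
                     "value": 1.0, "lo": 1.0, "hi": 1.0})
        base = 0.96 if sex == "male" else 0.95
        for a0 in (18, 25):
            a1 = 24 if a0 == 18 else 34
            v = base - cfg.utility_decline_per_decade * (a0 - 18) / 10.0
            rows.append({"sex": sex, "age_lo": a0, "age_hi": a1,
                         "state": "ALL", "value": round(v, 4),
                         "lo": round(max(v - 0.03, 0), 4),
                         "hi": round(min(v + 0.03, 1), 4)})
        for a0 in range(35, horizon, 10):
            a1 = min(a0 + 9, horizon - 1)
            v_hw = base - cfg.utility_decline_per_decade * (a0 - 18) / 10.0
            for s, label in enumerate(STATE_LABELS):
                v = v_hw if s == _HW else v_hw - cfg.nonhealthy_utility_penalty
                v = float(np.clip(v, 0.05, 1.0))
                rows.append({"sex": sex, "age_lo": a0, "age_hi": a1,
                             "state": label, "value": round(v, 4),
                             "lo": round(max(v - 0.04, 0), 4),
                             "hi": round(min(v + 0.04, 1), 4)})
    return UtilityTable.from_frame(pd.DataFrame(rows), max_age=horizon - 1)


def _make_population(rng: np.random.Generator) -> PopulationTable:
    counts = {sex: {a: float(rng.integers(500_000, 1_200_000))
                    for a in range(5, 20)}
              for sex in SEXES}
    return PopulationTable(counts=counts)


def generate_parameter_set(cfg: SynthConfig | None = None) -> ParameterSet:
    """Deterministic (seeded) synthetic parameter bundle; always valid."""
    cfg = cfg if cfg is not None else SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    ps = ParameterSet(
        population=_make_population(rng),
        prevalence=_make_prevalence(cfg, rng),
        transitions=_make_transitions(cfg, rng, cfg.horizon_age),
        mortality=_make_mortality(cfg, cfg.horizon_age + 5),
        hazard_ratios=_make_hazard_ratios(cfg),
        utilities=_make_utilities(cfg, cfg.horizon_age),
        horizon_age=cfg.horizon_age,
    )
    violations = validate(ps)
    if violations:  # generator contract: never emit an invalid set
        raise ValueError(f"synthetic generator produced invalid set: "
                         f"{violations[:3]}")
    return ps


# ---------------------------------------------------------------------------
# Published Vietnam starting conditions (2019 census aggregates and
# single-age weight-status prevalence, ages 5-19)
# ---------------------------------------------------------------------------

#: 5-year-group counts, 2019 Viet Nam Population and Housing Census.
VIETNAM_POPULATION = {
    "male": {5: 4_354_887, 10: 3_737_030, 15: 3_352_386},
    "female": {5: 3_977_832, 10: 3_482_807, 15: 3_153_831},
}

#: (age: (UW, HW, OWB)) in percent, boys then girls, as printed to one
#: decimal.  Rows are renormalised onto the healthy cell on load because the
#: printed precision can leave a row at 99.9% or 100.1%.
VIETNAM_PREVALENCE = {
    "male": {
        5: (12.3, 66.9, 20.8), 6: (13.1, 66.3, 20.6), 7: (14.1, 64.8, 21.1),
        8: (15.2, 63.2, 21.7), 9: (16.2, 62.1, 21.7), 10: (17.0, 62.2, 20.8),
        11: (17.6, 63.6, 18.8), 12: (17.7, 65.9, 16.4), 13: (17.6, 68.5, 13.9),
        14: (17.1, 71.3, 11.6), 15: (16.3, 73.9, 9.7), 16: (15.4, 76.3, 8.3),
        17: (14.3, 78.4, 7.3), 18: (13.2, 79.9, 6.9), 19: (14.5, 76.5, 8.9),
    },
    "female": {
        5: (12.9, 76.3, 10.9), 6: (12.7, 76.2, 11.0), 7: (14.2, 74.6, 11.2),
        8: (16.4, 72.4, 11.2), 9: (18.5, 70.5, 11.0), 10: (19.4, 70.1, 10.5),
        11: (18.9, 71.4, 9.8), 12: (17.1, 73.9, 9.0), 13: (14.8, 77.0, 8.2),
        14: (12.2, 80.3, 7.5), 15: (9.9, 83.2, 6.9), 16: (8.0, 85.5, 6.5),
        17: (6.8, 86.8, 6.4), 18: (6.3, 87.1, 6.5), 19: (8.2, 85.1, 6.8),
    },
}


def vietnam_fixture(
    transitions: TransitionTable | None = None,
    mortality: MortalityGroupTable | None = None,
    hazard_ratios: HazardRatios | None = None,
    utilities: UtilityTable | None = None,
    synth_seed: int = 0,
) -> ParameterSet:
    """Vietnam-like parameter set: exact published starting conditions,
    synthetic defaults elsewhere (see module docstring for the caveat)."""
    cfg = SynthConfig(seed=synth_seed)
    rng = np.random.default_rng(cfg.seed)

    population = PopulationTable(
        counts={sex: dict(d) for sex, d in VIETNAM_POPULATION.items()})

    ages = np.arange(5, 20)
    value = np.empty((2, len(ages), N_STATES))
    for si, sex in enumerate(SEXES):
        for ai, age in enumerate(ages):
            uw, hw, owb = (x / 100.0 for x in VIETNAM_PREVALENCE[sex][age])
            value[si, ai] = (uw, 1.0 - uw - owb, owb)  # renormalise onto HW
    w = cfg.ci_relative_width
    prevalence = PrevalenceTable(
        value=value,
        lo=np.minimum(np.clip(value * (1 - w), 0, 1), value),
        hi=np.maximum(np.clip(value * (1 + w), 0, 1), value),
        ages=ages)

    ps = ParameterSet(
        population=population,
        prevalence=prevalence,
        transitions=transitions if transitions is not None
        else _make_transitions(cfg, rng, cfg.horizon_age),
        mortality=mortality if mortality is not None
        else _make_mortality(cfg, cfg.horizon_age + 5),
        hazard_ratios=hazard_ratios if hazard_ratios is not None
        else _make_hazard_ratios(cfg),
        utilities=utilities if utilities is not None
        else _make_utilities(cfg, cfg.horizon_age),
        horizon_age=cfg.horizon_age,
    )
    violations = validate(ps)
    if violations:
        raise ValueError(f"vietnam fixture invalid: {violations[:3]}")
    return ps
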