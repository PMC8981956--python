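"""Single-age, weight-status-specific death probabilities.

All-cause mortality arrives as rates per 5-year age group (a WHO life-table
shape).  Because the cohort engine cycles one year at a time, group rates
are extrapolated to single ages with an exponential (Gompertz-like) curve:
ordinary least squares of log(rate) on the group midpoint age, evaluated at
each integer age.  Hazard ratios by weight status multiply the hazard — not
the probability — before the actuarial conversion q = 1 - exp(-rate), and
only from ``min_age_applied`` (default 20) upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    HazardRatios,
    MortalityGroupTable,
    N_STATES,
    SEXES,
    WeightState,
)

__all__ = [
    "SingleAgeMortality",
    "extrapolate_single_age",
    "rate_to_probability",
    "death_probability",
    "death_probability_array",
]


@dataclass
class SingleAgeMortality:
    """Per-sex single-age hazards plus the log-linear fit that produced them.

    With ``mode='global'`` the rates satisfy rate = exp(intercept + slope*age)
    exactly; with ``mode='piecewise'`` the fit params are per-segment and the
    rates are log-linear interpolations between group midpoints.
    """

    ages: np.ndarray                      # integer ages, age_lo..age_hi
    rate: dict[str, np.ndarray]           # sex -> hazard per person-year
    fit_params: dict[str, tuple[float, float]]  # sex -> (intercept, slope)
    mode: str = "global"

    def get(self, sex: str, age: int) -> float:
        return float(self.rate[sex][age - int(self.ages[0])])


def _midpoint(age_lo: int, age_hi: int) -> float:
    # groups are inclusive integer age ranges: [5, 9] has midpoint 7.5
    return (age_lo + age_hi + 1) / 2.0


def extrapolate_single_age(
    m: MortalityGroupTable,
    age_lo: int,
    age_hi: int,
    mode: str = "global",
) -> SingleAgeMortality:
    """Fit log(rate) ~ age on group midpoints and evaluate at single ages.

    Parameters
    ----------
    m : MortalityGroupTable
        5-year-group all-cause rates; every rate must be positive and at
        least two groups are needed per sex (the fit is underdetermined
        otherwise).
    age_lo, age_hi : int
        Inclusive single-age range to evaluate (e.g. 5 and 74 for a model
        horizon of 75).
    mode : {'global', 'piecewise'}
        'global' fits one line per sex over all groups overlapping the
        requested range; 'piecewise' interpolates log-rates linearly between
        group midpoints (flat beyond the end midpoints).
    """
    ages = np.arange(age_lo, age_hi + 1)
    rates: dict[str, np.ndarray] = {}
    fits: dict[str, tuple[float, float]] = {}
    for sex in SEXES:
        sub = m.rates(sex)
        sub = sub[(sub["age_hi"] >= age_lo) & (sub["age_lo"] <= age_hi)]
        if len(sub) < 2:
            raise ValueError(
                f"need >= 2 mortality age groups for sex={sex!r}; "
                f"got {len(sub)} (fit underdetermined)")
        if (sub["rate"] <= 0).any():
            raise ValueError(f"non-positive mortality rate for sex={sex!r}; "
                             "log-linear fit undefined")
        mids = np.array([_midpoint(a, b) for a, b in
                         zip(sub["age_lo"], sub["age_hi"])])
        logr = np.log(sub["rate"].to_numpy())
        slope, intercept = np.polyfit(mids, logr, 1)
        fits[sex] = (float(intercept), float(slope))
        if mode == "global":
            rates[sex] = np.exp(intercept + slope * ages)
        elif mode == "piecewise":
            rates[sex] = np.exp(np.interp(ages, mids, logr))
        else:
            raise ValueError(f"unknown mortality fit mode {mode!r}")
    return SingleAgeMortality(ages=ages, rate=rates, fit_params=fits, mode=mode)


def rate_to_probability(rate):
    """Actuarial conversion of a constant hazard to an annual probability.

    q = 1 - exp(-rate); maps [0, inf) onto [0, 1) and is monotone, so hazard
    ratios applied upstream can never push a probability past 1.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("hazard rate must be >= 0")
    q = -np.expm1(-rate)
    return float(q) if q.ndim == 0 else q


def death_probability(
    sam: SingleAgeMortality,
    hr: HazardRatios,
    sex: str,
    age: int,
    state: WeightState,
) -> float:
    """Annual death probability for one (sex, age, weight state).

    Below ``hr.min_age_applied`` all weight states share the baseline
    schedule; at and above it the state's hazard ratio multiplies the rate
    before conversion.
    """
    state = WeightState(state)
    rate = sam.get(sex, age)
    if age >= hr.min_age_applied:
        rate = rate * float(hr.hr[state])
    return min(float(rate_to_probability(rate)), 1.0 - 1e-15)


def death_probability_array(
    sam: SingleAgeMortality,
    hr: HazardRatios,
    calibrate_baseline: bool = False,
    prevalence=None,
) -> np.ndarray:
    """Death probabilities for every (sex, age, state) at once.

    Returns an array of shape (2, n_ages, 3) aligned with ``sam.ages``.
    With ``calibrate_baseline`` the all-cause rate is treated as a mixture
    over weight states and the healthy-weight baseline is recovered as
    rate / sum_s prev(s) * hr(s); prevalence weights come from the supplied
    PrevalenceTable (ages past its range reuse its oldest row).
    """
    n = len(sam.ages)
    rates = np.stack([sam.rate[s] for s in SEXES])          # (2, n)
    hr_by_age = np.ones((n, N_STATES))
    adult = sam.ages >= hr.min_age_applied
    hr_by_age[adult] = hr.hr
    hazard = rates[:, :, None] * hr_by_age[None, :, :]      # (2, n, 3)
    if calibrate_baseline:
        if prevalence is None:
            raise ValueError("calibrate_baseline requires a prevalence table")
        weights = np.empty((2, n, N_STATES))
        p_ages = prevalence.ages
        for si in range(2):
            for ai, age in enumerate(sam.ages):
                a = min(max(int(age), int(p_ages[0])), int(p_ages[-1]))
                weights[si, ai] = prevalence.value[si, a - int(p_ages[0])]
        denom = (weights * hr_by_age[None, :, :]).sum(axis=-1)  # (2, n)
        hazard = hazard / denom[:, :, None]
    return np.minimum(rate_to_probability(hazard), 1.0 - 1e-15)


def fitted_curve_frame(sam: SingleAgeMortality):
    """The fitted single-age schedule as a tidy frame (for CSV inspection)."""
    import pandas as pd

    recs = []
    for sex in SEXES:
        intercept, slope = sam.fit_params[sex]
        for ai, age in enumerate(sam.ages):
            recs.append({"sex": sex, "age": int(age),
                         "rate": sam.rate[sex][ai],
                         "fit_intercept": intercept, "fit_slope": slope})
    return pd.DataFrame(recs)
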