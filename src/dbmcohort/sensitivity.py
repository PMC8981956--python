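"""One-way and probabilistic sensitivity analyses.

One-way analysis reruns the model with a whole parameter group (prevalence,
transitions, utilities) pushed to its lower or upper 95% CI bound, the
healthy-weight cell absorbing the residual so rows stay row-stochastic.

The probabilistic sensitivity analysis (PSA) is a second-order Monte Carlo:
each iteration independently redraws every uncertain cell — uniform(lo, hi)
for prevalence and transition probabilities, lognormal for the mortality
hazard ratios (parameterised so the CI bounds are the 2.5/97.5 percentiles),
beta matched by moments for utilities — renormalises rows onto the healthy
cell, reruns the full model, and the mean plus empirical 2.5/97.5
percentiles are reported per outcome and sex.  Cells are sampled
independently (no correlation structure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_engine import CohortModel, OutcomeSummary, run_population
from .parameters import ParameterSet, WeightState

__all__ = ["PsaConfig", "PsaResult", "one_way", "run_psa",
           "sample_parameter_set", "lognormal_params", "beta_params"]

_HW = int(WeightState.HEALTHY)
_NON_HW = [int(WeightState.UNDERWEIGHT), int(WeightState.OVERWEIGHT_OBESE)]
_Z95 = 1.959964  # two-sided 95% normal quantile


@dataclass
class PsaConfig:
    """Monte Carlo settings; defaults follow common health-economics practice
    (10,000 iterations, percentile CIs)."""

    n_iterations: int = 10_000
    seed: int = 0
    keep_draws: bool = False

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class PsaResult:
    """Mean and empirical 95% interval per outcome x sex, plus the flag
    matrix saying whether the interval brackets the mean (checked, not
    assumed)."""

    summary: pd.DataFrame          # index (outcome, sex); mean, lo, hi
    draws: pd.DataFrame | None = None

    def value(self, outcome: str, sex: str = "total", stat: str = "mean") -> float:
        return float(self.summary.loc[(outcome, sex), stat])


# ---------------------------------------------------------------------------
# Distribution parameterisations
# ---------------------------------------------------------------------------


def lognormal_params(value: float, lo: float, hi: float) -> tuple[float, float]:
    """(mu, sigma) with mu = ln(value) and sigma chosen so (lo, hi) are the
    2.5th/97.5th percentiles: sigma = (ln hi - ln lo) / (2 * 1.959964)."""
    if not (0 < lo <= value <= hi):
        raise ValueError(f"invalid lognormal CI ({lo}, {value}, {hi})")
    return float(np.log(value)), float((np.log(hi) - np.log(lo)) / (2 * _Z95))


def beta_params(value: float, lo: float, hi: float) -> tuple[float, float] | None:
    """(alpha, beta) matching mean=value and SD=(hi-lo)/(2*1.959964).

    Returns None for degenerate cells (zero width, or value at 0/1, or an
    implied variance too large for a beta) — those are held fixed.
    """
    if not (0 <= lo <= value <= hi <= 1):
        raise ValueError(f"invalid beta CI ({lo}, {value}, {hi})")
    sd = (hi - lo) / (2 * _Z95)
    if sd <= 0 or value <= 0 or value >= 1:
        return None
    var = sd * sd
    nu = value * (1 - value) / var - 1
    if nu <= 0:
        return None
    return float(value * nu), float((1 - value) * nu)


# ---------------------------------------------------------------------------
# One-way
# ---------------------------------------------------------------------------


def _prevalence_at_bound(ps: ParameterSet, which: str) -> ParameterSet:
    out = ps.copy()
    t = out.prevalence
    bound = t.lo if which == "lo" else t.hi
    for s in _NON_HW:
        t.value[..., s] = bound[..., s]
    t.value[..., _HW] = np.clip(1.0 - t.value[..., _NON_HW].sum(axis=-1), 0, 1)
    _refresh_bounds(t)
    return out


def _transitions_at_bound(ps: ParameterSet, which: str) -> ParameterSet:
    out = ps.copy()
    t = out.transitions
    bound = t.lo if which == "lo" else t.hi
    for s in _NON_HW:
        t.value[..., s] = bound[..., s]
    t.value[..., _HW] = np.clip(1.0 - t.value[..., _NON_HW].sum(axis=-1), 0, 1)
    _refresh_bounds(t)
    return out


def _utilities_at_bound(ps: ParameterSet, which: str) -> ParameterSet:
    out = ps.copy()
    t = out.utilities
    bound = t.lo if which == "lo" else t.hi
    t.value = np.clip(bound.copy(), 0.0, 1.0)
    # structural rule: children stay at full health whatever the bound says
    t.value[:, : t.CHILD_MAX_AGE - 5 + 1, :] = 1.0
    _refresh_bounds(t)
    t.bands = None  # resolved cells no longer match the band file
    return out


def _refresh_bounds(t) -> None:
    if t.lo is not None:
        t.lo = np.minimum(t.lo, t.value)
        t.hi = np.maximum(t.hi, t.value)


_GROUPS = {
    "prevalence": _prevalence_at_bound,
    "transitions": _transitions_at_bound,
    "utilities": _utilities_at_bound,
}


def one_way(ps: ParameterSet,
            groups: tuple[str, ...] = ("prevalence", "transitions", "utilities"),
            ) -> dict[tuple[str, str], OutcomeSummary]:
    """Rerun the model at the lower/upper CI bound of each parameter group.

    Returns {(group, 'lo'|'hi'): OutcomeSummary}; raises if a requested
    group carries no CI bounds.
    """
    for g in groups:
        table = getattr(ps, g if g != "utilities" else "utilities")
        if not table.has_ci:
            raise ValueError(f"one-way analysis needs CI bounds for {g!r}")
    out: dict[tuple[str, str], OutcomeSummary] = {}
    for g in groups:
        for which in ("lo", "hi"):
            out[(g, which)] = run_population(_GROUPS[g](ps, which))
    return out


def one_way_frame(results: dict[tuple[str, str], OutcomeSummary]) -> pd.DataFrame:
    rows = []
    for (group, which), summ in results.items():
        row: dict = {"group": group, "bound": which}
        for outcome in OutcomeSummary.OUTCOMES:
            for sex in ("male", "female", None):
                row[f"{outcome}_{sex or 'total'}"] = summ.total(outcome, sex)
        rows.append(row)
    return pd.DataFrame(rows).set_index(["group", "bound"])


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------


def _check_psa_inputs(ps: ParameterSet) -> None:
    for name in ("prevalence", "transitions", "utilities"):
        if not getattr(ps, name).has_ci:
            raise ValueError(f"PSA needs CI bounds for {name}")
    if not ps.hazard_ratios.has_ci:
        raise ValueError("PSA needs CI bounds for hazard_ratios")
    for t in (ps.prevalence, ps.transitions, ps.utilities):
        if np.any(t.hi < t.lo):
            raise ValueError("invalid CI: hi < lo")


class _Sampler:
    """Precompiled PSA sampling plan for one base parameter set.

    Uniform draws for the non-healthy prevalence cells and non-(into-healthy)
    transition cells, the healthy cell taking the residual (clamped; rows
    rescaled if the non-healthy draws alone exceed 1).  Lognormal hazard
    ratios; beta utilities drawn once per structurally distinct cell
    (children's fixed 1.0 stays fixed, 18-34 rows share one draw across
    states).  Every realisation satisfies every parameter invariant.
    """

    def __init__(self, ps: ParameterSet):
        _check_psa_inputs(ps)
        self.ps = ps
        self.ln_params = {}
        for s in _NON_HW:
            self.ln_params[s] = lognormal_params(
                ps.hazard_ratios.hr[s], ps.hazard_ratios.lo[s],
                ps.hazard_ratios.hi[s])
        # per-cell beta params where non-degenerate; 18-34 rows only state 0
        u = ps.utilities
        shape = u.value.shape
        self.u_alpha = np.full(shape, np.nan)
        self.u_beta = np.full(shape, np.nan)
        a18, a34 = 18 - 5, u.STATE_FREE_MAX_AGE - 5
        it = np.ndindex(shape)
        for idx in it:
            si, ai, s = idx
            if a18 <= ai <= a34 and s != 0:
                continue
            params = beta_params(u.value[idx], u.lo[idx], u.hi[idx])
            if params is not None:
                self.u_alpha[idx], self.u_beta[idx] = params
        self.u_mask = ~np.isnan(self.u_alpha)
        self.state_free = (a18, a34)

    def sample(self, rng: np.random.Generator) -> ParameterSet:
        out = self.ps.copy()
        for t in (out.prevalence, out.transitions):
            draw = rng.uniform(t.lo[..., _NON_HW], t.hi[..., _NON_HW])
            resid = 1.0 - draw.sum(axis=-1)
            neg = resid < 0
            if np.any(neg):
                draw[neg] /= draw[neg].sum(axis=-1, keepdims=True)
                resid[neg] = 0.0
            t.value[..., _NON_HW] = draw
            t.value[..., _HW] = resid
            _refresh_bounds(t)

        hr = out.hazard_ratios
        for s in _NON_HW:
            mu, sigma = self.ln_params[s]
            if sigma > 0:
                hr.hr[s] = float(np.exp(mu + sigma * rng.standard_normal()))
        hr.lo = np.minimum(hr.lo, hr.hr)
        hr.hi = np.maximum(hr.hi, hr.hr)

        u = out.utilities
        if self.u_mask.any():
            u.value[self.u_mask] = rng.beta(self.u_alpha[self.u_mask],
                                            self.u_beta[self.u_mask])
        a18, a34 = self.state_free
        u.value[:, a18:a34 + 1, :] = u.value[:, a18:a34 + 1, :1]
        _refresh_bounds(u)
        u.bands = None
        return out


def sample_parameter_set(ps: ParameterSet, rng: np.random.Generator
                         ) -> ParameterSet:
    """Draw one PSA realisation of the parameter set (see _Sampler)."""
    return _Sampler(ps).sample(rng)


def run_psa(ps: ParameterSet, cfg: PsaConfig) -> PsaResult:
    """Second-order Monte Carlo over all uncertain inputs.

    Fully reproducible for a given seed; every sampled parameter set is a
    valid model input by construction of the sampler.
    """
    sampler = _Sampler(ps)
    rng = np.random.default_rng(cfg.seed)
    records = []
    for _ in range(cfg.n_iterations):
        sampled = sampler.sample(rng)
        summ = CohortModel(sampled).run_population()
        rec = {}
        for outcome in OutcomeSummary.OUTCOMES:
            for sex in ("male", "female", None):
                rec[(outcome, sex or "total")] = summ.total(outcome, sex)
        records.append(rec)
    draws = pd.DataFrame(records)
    draws.columns = pd.MultiIndex.from_tuples(draws.columns,
                                              names=["outcome", "sex"])
    mean = draws.mean()
    lo = draws.quantile(0.025)
    hi = draws.quantile(0.975)
    summary = pd.DataFrame({"mean": mean, "lo": lo, "hi": hi})
    summary["brackets_mean"] = (summary["lo"] <= summary["mean"]) & \
        (summary["mean"] <= summary["hi"])
    summary.index.names = ["outcome", "sex"]
    return PsaResult(summary=summary,
                     draws=draws if cfg.keep_draws else None)
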