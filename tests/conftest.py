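import numpy as np
import pytest

from dbmcohort import (
    SynthConfig,
    generate_parameter_set,
    save_parameter_set,
    vietnam_fixture,
)


@pytest.fixture(scope="session")
def synth_ps():
    """One representative synthetic parameter set (full 75-year horizon)."""
    return generate_parameter_set(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def short_ps():
    """A short-horizon set (age 24) so cohorts starting at 19 run 5 cycles."""
    return generate_parameter_set(SynthConfig(seed=11, horizon_age=24))


@pytest.fixture(scope="session")
def vietnam_ps():
    """Published 2019 Vietnam starting population/prevalence, synthetic
    defaults for the remaining tables."""
    return vietnam_fixture()


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, synth_ps):
    """The synthetic set written out as its CSV bundle + config."""
    out = tmp_path_factory.mktemp("bundle")
    save_parameter_set(synth_ps, out)
    return out


def microsimulate(init_counts, qdeath, Q, rng):
    """Individual-level stochastic counterpart of one cohort run.

    Exact aggregate of simulating each agent: deaths are binomial draws per
    state and the survivors' destinations multinomial draws per row, which
    is distributionally identical to looping over agents one by one.

    Parameters
    ----------
    init_counts : (3,) int array of agents per starting state.
    qdeath : (n_cycles, 3) annual death probabilities.
    Q : (n_cycles, 3, 3) transition matrices among survivors.

    Returns dict with total deaths, per-state cumulative deaths, final
    occupancy and undiscounted person-years (full-year accrual at cycle
    start, matching the engine's convention).
    """
    occ = np.asarray(init_counts, dtype=np.int64).copy()
    n_cycles = qdeath.shape[0]
    deaths = np.zeros(3, dtype=np.int64)
    person_years = np.zeros(3, dtype=np.int64)
    for c in range(n_cycles):
        person_years += occ
        d = rng.binomial(occ, qdeath[c])
        deaths += d
        surv = occ - d
        nxt = np.zeros(3, dtype=np.int64)
        for s in range(3):
            if surv[s] > 0:
                nxt += rng.multinomial(surv[s], Q[c, s])
        occ = nxt
    return {"deaths": deaths, "final": occ, "person_years": person_years}
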