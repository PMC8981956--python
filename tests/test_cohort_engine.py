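import numpy as np
import pytest

from dbmcohort import (
    CohortModel,
    SynthConfig,
    discount_factor,
    generate_parameter_set,
    init_cohort,
    run_cohort,
    run_population,
)
from conftest import microsimulate


class TestDiscountFactor:
    def test_closed_forms(self):
        assert discount_factor(0, 0.03) == 1.0
        assert discount_factor(1, 0.03) == pytest.approx(0.970874, abs=1e-6)
        assert discount_factor(17, 0.0) == 1.0

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -1.5)
        with pytest.raises(ValueError):
            discount_factor(-1, 0.03)


class TestInitCohort:
    def test_published_age5_boys_split(self, vietnam_ps):
        occ = init_cohort(vietnam_ps, "male", 5)
        assert occ.sum() == pytest.approx(4_354_887 / 5)  # 870,977.4
        assert occ[0] == pytest.approx(870_977.4 * 0.123, rel=1e-9)

    def test_degenerate_prevalence_puts_all_mass_in_healthy(self, synth_ps):
        ps = synth_ps.copy()
        ps.prevalence.value[:, :, :] = (0.0, 1.0, 0.0)
        occ = init_cohort(ps, "female", 12)
        assert occ[0] == occ[2] == 0.0
        assert occ[1] == pytest.approx(
            ps.population.count_single_age("female", 12))

    def test_zero_population_gives_zero_vector(self, synth_ps):
        ps = synth_ps.copy()
        ps.population.counts["male"][9] = 0.0
        np.testing.assert_array_equal(init_cohort(ps, "male", 9), 0.0)

    def test_age_out_of_range_rejected(self, synth_ps):
        with pytest.raises(ValueError, match="starting age"):
            init_cohort(synth_ps, "male", 25)


class TestStepCycle:
    def test_no_mortality_identity_transitions_is_a_fixed_point(self, synth_ps):
        ps = synth_ps.copy()
        model = CohortModel(ps)
        model.qdeath[:] = 0.0
        model.Q[:] = np.eye(3)
        occ = np.array([10.0, 20.0, 30.0])
        nxt, deaths = model.step_cycle(occ, "male", 30)
        np.testing.assert_allclose(nxt, occ)
        np.testing.assert_array_equal(deaths, 0.0)

    def test_hand_computed_single_step(self, synth_ps):
        model = CohortModel(synth_ps.copy())
        model.qdeath[:] = 0.0
        model.qdeath[0, 30 - 5, 0] = 0.1           # UW death prob at age 30
        model.Q[0, 30 - 5] = np.eye(3)
        model.Q[0, 30 - 5, 0] = (0.0, 1.0, 0.0)    # UW -> HW surely
        nxt, deaths = model.step_cycle(np.array([100.0, 0, 0]), "male", 30)
        np.testing.assert_allclose(deaths, [10.0, 0, 0])
        np.testing.assert_allclose(nxt, [0.0, 90.0, 0.0])

    def test_mass_conserved_each_step(self, synth_ps):
        model = CohortModel(synth_ps)
        occ = np.array([50.0, 900.0, 50.0])
        nxt, deaths = model.step_cycle(occ, "female", 60)
        assert nxt.sum() + deaths.sum() == pytest.approx(occ.sum(), rel=1e-12)

    def test_negative_occupancy_rejected(self, synth_ps):
        model = CohortModel(synth_ps)
        with pytest.raises(ValueError, match="non-negative"):
            model.step_cycle(np.array([-1.0, 0, 0]), "male", 30)


class TestRunCohort:
    def test_zero_discount_unit_utilities_make_qaly_equal_ly(self, synth_ps):
        ps = synth_ps.copy()
        ps.discount_rate = 0.0
        ps.utilities.value[:] = 1.0
        trace = run_cohort(ps, "male", 10)
        assert trace.qaly.sum() == pytest.approx(trace.ly.sum(), rel=1e-12)

    def test_deaths_do_not_depend_on_discount_rate(self, synth_ps):
        totals = []
        for r in (0.0, 0.03, 0.05):
            ps = synth_ps.copy()
            ps.discount_rate = r
            totals.append(run_cohort(ps, "female", 15).deaths.sum())
        assert totals[0] == totals[1] == totals[2]

    def test_certain_death_in_first_cycle_accrues_one_full_year(self, synth_ps):
        ps = synth_ps.copy()
        ps.population.counts["male"] = {a: 1.0 for a in range(5, 20)}
        ps.prevalence.value[0, 19 - 5] = (0.0, 1.0, 0.0)
        model = CohortModel(ps)
        model.qdeath[0, :, :] = 1.0 - 1e-15
        trace = model.run_cohort("male", 19)
        assert trace.deaths.sum() == pytest.approx(1.0)
        assert trace.ly[0].sum() == pytest.approx(1.0)      # cycle 0 undiscounted
        assert trace.ly.sum() == pytest.approx(1.0, abs=1e-12)
        u0 = model.U[0, 19 - 5, 1]
        assert trace.qaly.sum() == pytest.approx(u0, abs=1e-12)

    def test_conservation_to_horizon(self, synth_ps):
        trace = run_cohort(synth_ps, "male", 5)
        initial = trace.occupancy[0].sum()
        assert trace.deaths.sum() + trace.occupancy[-1].sum() == \
            pytest.approx(initial, rel=1e-9)

    def test_qaly_never_exceeds_ly(self, synth_ps):
        for sex in ("male", "female"):
            trace = run_cohort(synth_ps, sex, 8)
            assert (trace.qaly <= trace.ly + 1e-12).all()

    def test_discounted_ly_strictly_decreasing_in_rate(self, synth_ps):
        lys = []
        for r in (0.0, 0.03, 0.05):
            ps = synth_ps.copy()
            ps.discount_rate = r
            lys.append(run_cohort(ps, "male", 10).ly.sum())
        assert lys[0] > lys[1] > lys[2]


class TestRunPopulation:
    def test_fast_path_matches_per_cohort_reference(self, synth_ps):
        summ = run_population(synth_ps)
        model = CohortModel(synth_ps)
        for sex in ("male", "female"):
            ref = {"deaths": 0.0, "yll": 0.0, "qaly": 0.0}
            for age in range(5, 20):
                t = model.run_cohort(sex, age).totals()
                for k in ref:
                    ref[k] += t[k].sum()
            for k, v in ref.items():
                assert summ.total(k, sex) == pytest.approx(v, rel=1e-12)

    def test_margins_resum_to_totals(self, synth_ps):
        summ = run_population(synth_ps)
        tab = summ.table()
        both = tab.loc[("both", "Total")]
        for outcome in ("deaths", "yll", "qaly"):
            assert both[(outcome, "Total")] == pytest.approx(
                summ.total(outcome), rel=1e-9)
            assert both[(outcome, "Total")] == pytest.approx(
                sum(both[(outcome, s)] for s in ("UW", "HW", "OWB")), rel=1e-9)

    def test_no_mortality_gives_annuity_life_years(self, synth_ps):
        ps = synth_ps.copy()
        model = CohortModel(ps)
        model.qdeath[:] = 0.0
        summ = model.run_population()
        assert summ.total("deaths") == 0.0
        r = ps.discount_rate
        expected = sum(
            ps.population.count_single_age(sex, a)
            * sum(discount_factor(c, r) for c in range(ps.horizon_age - a))
            for sex in ("male", "female") for a in range(5, 20))
        assert summ.total("yll") == pytest.approx(expected, rel=1e-9)

    def test_alternative_cycle_order_still_conserves_mass(self, synth_ps):
        ps = synth_ps.copy()
        ps.options.transition_order = "transition_first"
        summ = run_population(ps)
        model = CohortModel(ps)
        survivors = sum(model._run_all_cohorts(s)["survivors"].sum()
                        for s in ("male", "female"))
        assert summ.total("deaths") + survivors == pytest.approx(
            ps.population.total(), rel=1e-9)

    def test_half_cycle_accrues_less_than_full_cycle(self, synth_ps):
        full = run_population(synth_ps).total("yll")
        ps = synth_ps.copy()
        ps.options.half_cycle = True
        half = run_population(ps).total("yll")
        assert half < full


class TestLifeTableLimit:
    def test_single_state_no_hr_matches_classical_life_table(self):
        """With one populated state, identity hazard ratios and r = 0 the
        engine must reproduce the abridged life table computed directly
        from the single-age death probabilities."""
        ps = generate_parameter_set(SynthConfig(seed=3))
        ps.discount_rate = 0.0
        ps.hazard_ratios.hr[:] = 1.0
        ps.prevalence.value[:, :, :] = (0.0, 1.0, 0.0)
        ps.utilities.value[:] = 1.0
        model = CohortModel(ps)
        start_age = 10
        trace = model.run_cohort("male", start_age)
        # classical survivorship: l_{x+1} = l_x * (1 - q_x), full-year accrual
        qx = model.qdeath[0, :, 1]
        l = model.init_cohort("male", start_age).sum()
        person_years = 0.0
        for age in range(start_age, ps.horizon_age):
            person_years += l
            l *= 1.0 - qx[age - 5]
        assert trace.ly.sum() == pytest.approx(person_years, rel=1e-12)
        assert trace.occupancy[-1].sum() == pytest.approx(l, rel=1e-12)


class TestMicrosimulationOracle:
    def test_cohort_expectations_match_agent_level_simulation(self, short_ps):
        """The deterministic engine must agree with an individual-level
        stochastic simulation (1e6 agents in 10 replicates) within 3
        Monte-Carlo standard errors on a 3-state, 5-cycle instance."""
        ps = short_ps
        model = CohortModel(ps)
        start_age = 19                       # 5 cycles to the age-24 horizon
        trace = model.run_cohort("male", start_age)
        exp_total = trace.occupancy[0].sum()

        n_agents = 100_000
        n_rep = 10
        scale = exp_total / n_agents
        ages = np.arange(start_age, ps.horizon_age) - 5
        qdeath = model.qdeath[0, ages]
        Q = model.Q[0, ages]
        p0 = trace.occupancy[0] / exp_total

        rng = np.random.default_rng(2024)
        reps = {"deaths": [], "final": [], "py": []}
        for _ in range(n_rep):
            init = rng.multinomial(n_agents, p0)
            out = microsimulate(init, qdeath, Q, rng)
            reps["deaths"].append(out["deaths"].sum() * scale)
            reps["final"].append(out["final"] * scale)
            reps["py"].append(out["person_years"].sum() * scale)

        def check(observed, expected):
            obs = np.asarray(observed, dtype=float)
            se = obs.std(axis=0, ddof=1) / np.sqrt(n_rep)
            assert np.all(np.abs(obs.mean(axis=0) - expected) <=
                          3 * se + 1e-9), (obs.mean(axis=0), expected, se)

        check(reps["deaths"], trace.deaths.sum())
        check(reps["final"], trace.occupancy[-1])
        # undiscounted person-years: rerun the engine at r = 0
        ps0 = ps.copy()
        ps0.discount_rate = 0.0
        trace0 = CohortModel(ps0).run_cohort("male", start_age)
        check(reps["py"], trace0.ly.sum())
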