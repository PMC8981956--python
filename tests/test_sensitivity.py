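import numpy as np
import pytest

from dbmcohort import (
    PsaConfig,
    one_way,
    run_population,
    run_psa,
    sample_parameter_set,
    validate,
)
from dbmcohort.sensitivity import beta_params, lognormal_params, one_way_frame


def _degenerate_ci(ps):
    """Collapse every CI to its point value."""
    out = ps.copy()
    for t in (out.prevalence, out.transitions, out.utilities):
        t.lo = t.value.copy()
        t.hi = t.value.copy()
    out.hazard_ratios.lo = out.hazard_ratios.hr.copy()
    out.hazard_ratios.hi = out.hazard_ratios.hr.copy()
    return out


class TestParameterisations:
    def test_lognormal_sigma_from_percentiles(self):
        mu, sigma = lognormal_params(1.5, 1.2, 1.875)
        assert mu == pytest.approx(np.log(1.5))
        assert sigma == pytest.approx(
            (np.log(1.875) - np.log(1.2)) / (2 * 1.959964))

    def test_lognormal_median_converges_to_point_value(self):
        mu, sigma = lognormal_params(1.5, 1.2, 1.875)
        rng = np.random.default_rng(5)
        draws = np.exp(mu + sigma * rng.standard_normal(200_000))
        assert np.median(draws) == pytest.approx(1.5, rel=0.01)

    def test_beta_moments_match_mean_and_ci_sd(self):
        a, b = beta_params(0.9, 0.86, 0.94)
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert mean == pytest.approx(0.9)
        assert np.sqrt(var) == pytest.approx((0.94 - 0.86) / (2 * 1.959964),
                                             rel=1e-6)

    def test_degenerate_beta_cells_are_held_fixed(self):
        assert beta_params(1.0, 1.0, 1.0) is None
        assert beta_params(0.9, 0.9, 0.9) is None


class TestOneWay:
    def test_zero_width_cis_reproduce_base_case(self, synth_ps):
        ps = _degenerate_ci(synth_ps)
        base = run_population(ps)
        results = one_way(ps)
        for key, summ in results.items():
            for outcome in ("deaths", "yll", "qaly"):
                assert summ.total(outcome) == pytest.approx(
                    base.total(outcome), rel=1e-12), (key, outcome)

    def test_lower_transition_bounds_reduce_deaths(self, vietnam_ps):
        """Fewer inflows into the risky states with hazard ratios >= 1 must
        mean fewer deaths and more (discounted) life-years."""
        base = run_population(vietnam_ps)
        results = one_way(vietnam_ps, groups=("transitions",))
        lo = results[("transitions", "lo")]
        assert lo.total("deaths") < base.total("deaths")
        assert lo.total("yll") > base.total("yll")

    def test_utility_bounds_touch_only_qalys(self, vietnam_ps):
        base = run_population(vietnam_ps)
        results = one_way(vietnam_ps, groups=("utilities",))
        for which in ("lo", "hi"):
            summ = results[("utilities", which)]
            assert summ.total("deaths") == base.total("deaths")
            assert summ.total("yll") == base.total("yll")
            assert summ.total("qaly") != base.total("qaly")
        assert results[("utilities", "lo")].total("qaly") < \
            results[("utilities", "hi")].total("qaly")

    def test_missing_cis_raise_naming_the_group(self, synth_ps):
        ps = synth_ps.copy()
        ps.prevalence.lo = None
        ps.prevalence.hi = None
        with pytest.raises(ValueError, match="prevalence"):
            one_way(ps)

    def test_frame_has_all_six_runs(self, synth_ps):
        df = one_way_frame(one_way(synth_ps))
        assert len(df) == 6
        assert set(df.index.get_level_values("group")) == {
            "prevalence", "transitions", "utilities"}


class TestPsa:
    def test_degenerate_bounds_equal_deterministic_run(self, synth_ps):
        ps = _degenerate_ci(synth_ps)
        base = run_population(ps)
        res = run_psa(ps, PsaConfig(n_iterations=5, seed=1))
        for outcome in ("deaths", "yll", "qaly"):
            assert res.value(outcome, "total", "mean") == pytest.approx(
                base.total(outcome), rel=1e-12)
            assert res.value(outcome, "total", "hi") - \
                res.value(outcome, "total", "lo") == pytest.approx(0, abs=1e-6)

    def test_same_seed_is_bit_reproducible(self, synth_ps):
        a = run_psa(synth_ps, PsaConfig(n_iterations=20, seed=42))
        b = run_psa(synth_ps, PsaConfig(n_iterations=20, seed=42))
        assert a.summary[["mean", "lo", "hi"]].equals(
            b.summary[["mean", "lo", "hi"]])

    def test_different_seeds_differ(self, synth_ps):
        a = run_psa(synth_ps, PsaConfig(n_iterations=20, seed=1))
        b = run_psa(synth_ps, PsaConfig(n_iterations=20, seed=2))
        assert not a.summary["mean"].equals(b.summary["mean"])

    def test_every_sampled_set_is_valid(self, synth_ps):
        rng = np.random.default_rng(9)
        for _ in range(25):
            assert validate(sample_parameter_set(synth_ps, rng)) == []

    def test_mean_close_to_deterministic_under_narrow_symmetric_cis(
            self, synth_ps):
        """With narrow symmetric uncertainty the PSA mean must approach the
        deterministic result (500 iterations, 3 SE tolerance)."""
        ps = synth_ps.copy()
        for t in (ps.prevalence, ps.transitions):
            half = 0.002
            t.lo = np.clip(t.value - half, 0, 1)
            t.hi = np.clip(t.value + half, 0, 1)
        ps.hazard_ratios.lo = ps.hazard_ratios.hr * 0.995
        ps.hazard_ratios.hi = ps.hazard_ratios.hr / 0.995
        u = ps.utilities
        interior = (u.value > 0.05) & (u.value < 0.999)
        u.lo = np.where(interior, np.clip(u.value - 0.002, 0, 1), u.value)
        u.hi = np.where(interior, np.clip(u.value + 0.002, 0, 1), u.value)
        base = run_population(ps)
        n = 500
        res = run_psa(ps, PsaConfig(n_iterations=n, seed=123, keep_draws=True))
        for outcome in ("deaths", "yll", "qaly"):
            draws = res.draws[(outcome, "total")]
            se = draws.std(ddof=1) / np.sqrt(n)
            assert abs(draws.mean() - base.total(outcome)) <= 3 * se

    def test_interval_brackets_mean(self, vietnam_ps):
        res = run_psa(vietnam_ps, PsaConfig(n_iterations=60, seed=8))
        assert res.summary["brackets_mean"].all()

    def test_missing_hr_cis_rejected_before_sampling(self, synth_ps):
        ps = synth_ps.copy()
        ps.hazard_ratios.lo = None
        ps.hazard_ratios.hi = None
        with pytest.raises(ValueError, match="hazard_ratios"):
            run_psa(ps, PsaConfig(n_iterations=2, seed=0))
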