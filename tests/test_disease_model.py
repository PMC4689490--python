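"""Illness-death solver, consistency fit, smoothing and Monte-Carlo propagation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiburden.bands import DEFAULT_BANDS, AgeBand, validate_partition
from epiburden.disease_model import (
    HazardSchedule,
    UncertaintySpec,
    fit_consistent,
    propagate_uncertainty,
    smooth_schedule,
    solve_forward,
)

from conftest import NB, single_sex_rates

CONST = lambda v: np.full(NB, v)  # noqa: E731


class TestSolveForward:
    def test_cumulative_incidence_closed_form(self):
        """With r=f=0 prevalence is 1-exp(-i*a); background mortality cancels."""
        sch = HazardSchedule(DEFAULT_BANDS, CONST(1e-3), CONST(0.0), CONST(0.0), CONST(0.02))
        sol = solve_forward(sch)
        exact = 1.0 - np.exp(-1e-3 * sol.ages)
        mask = sol.ages > 0
        assert np.max(np.abs(sol.prevalence[mask] - exact[mask]) / exact[mask]) < 1e-4

    def test_constant_hazard_sojourn_time(self, constant_schedule):
        """Expected duration in the disease state is 1/(r+m+f) for constant exit hazard."""
        sol = solve_forward(constant_schedule)
        assert sol.duration == pytest.approx(1.0 / 0.06, rel=1e-4)

    def test_no_disease_degenerate(self):
        """i=0 from a disease-free start keeps prevalence at zero; SMR=(m+f)/m."""
        sch = HazardSchedule(DEFAULT_BANDS, CONST(0.0), CONST(0.0), CONST(0.01), CONST(0.01))
        sol = solve_forward(sch)
        assert np.all(sol.prevalence == 0.0)
        assert np.all(sol.smr == 2.0)

    def test_smr_is_unity_without_excess_mortality(self):
        sch = HazardSchedule(DEFAULT_BANDS, CONST(1e-4), CONST(0.05), CONST(0.0), CONST(0.01))
        assert np.all(solve_forward(sch).smr == 1.0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            HazardSchedule(DEFAULT_BANDS, CONST(-1e-4), CONST(0.0), CONST(0.0), CONST(0.01))
        sch = HazardSchedule(DEFAULT_BANDS, CONST(1e-4), CONST(0.0), CONST(0.0), CONST(0.01))
        with pytest.raises(ValueError):
            solve_forward(sch, age_grid=[0.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            solve_forward(sch, initial_prevalence=1.5)

    def test_nonuniform_grid_matches_uniform(self, constant_schedule):
        grid = np.concatenate([np.arange(0, 50, 0.1), np.arange(50, 100.05, 0.05)])
        sol_nu = solve_forward(constant_schedule, age_grid=grid)
        sol_u = solve_forward(constant_schedule)
        at = np.arange(0.0, 100.0, 5.0)
        p_nu = np.interp(at, sol_nu.ages, sol_nu.prevalence)
        p_u = np.interp(at, sol_u.ages, sol_u.prevalence)
        assert p_nu == pytest.approx(p_u, abs=1e-8)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(0.0, 0.05), min_size=NB, max_size=NB),
        st.lists(st.floats(0.0, 0.5), min_size=NB, max_size=NB),
        st.lists(st.floats(0.0, 0.2), min_size=NB, max_size=NB),
        st.lists(st.floats(1e-4, 0.1), min_size=NB, max_size=NB),
        st.floats(0.0, 1.0),
    )
    def test_state_fractions_stay_physical(self, i, r, f, m, p0):
        """Random hazard schedules keep W,C >= 0 and prevalence inside [0,1]."""
        sch = HazardSchedule(DEFAULT_BANDS, i, r, f, m)
        sol = solve_forward(sch, initial_prevalence=p0)
        assert np.all(sol.well >= 0) and np.all(sol.cases >= 0)
        assert np.all((sol.prevalence >= 0) & (sol.prevalence <= 1))
        assert np.all(sol.duration >= 0)

    def test_stationary_population_identity(self):
        """Under age-constant hazards, P ~= i * D in a stationary age structure."""
        # m large enough that the age-100 integration cap covers essentially
        # the whole stationary age distribution
        i, r, m = 2e-4, 0.04, 0.05
        sch = HazardSchedule(DEFAULT_BANDS, CONST(i), CONST(r), CONST(0.0), CONST(m))
        sol = solve_forward(sch)
        weights = np.exp(-m * sol.ages)  # stationary age density under mortality m
        P = np.sum(sol.prevalence * weights) / np.sum(weights)
        D = 1.0 / (r + m)
        assert P == pytest.approx(i * D, rel=0.02)


class TestFitConsistent:
    def test_noise_free_round_trip(self, cohort_spec, noise_free_rates):
        """Observations generated by the forward model return the generating hazards."""
        for sex in ("male", "female"):
            obs, mortality = single_sex_rates(noise_free_rates, sex)
            fit = fit_consistent(obs, mortality)
            true = cohort_spec.hazards[sex]
            assert fit.converged
            assert fit.schedule.i == pytest.approx(true.i, rel=0.01)
            assert fit.schedule.f == pytest.approx(true.f, rel=0.01, abs=1e-8)
            assert fit.schedule.r == pytest.approx(true.r, rel=0.01, abs=1e-4)

    def test_underdetermined_rejected(self, noise_free_rates):
        obs, mortality = single_sex_rates(noise_free_rates, "male")
        with pytest.raises(ValueError, match="underdetermined"):
            fit_consistent(obs[["prevalence", "incidence"]], mortality)

    def test_empty_disease_flagged_unidentified(self):
        obs = pd.DataFrame(
            {
                "prevalence": np.zeros(NB),
                "incidence": np.zeros(NB),
                "cause_mortality": np.zeros(NB),
            }
        )
        fit = fit_consistent(obs, CONST(0.01))
        assert "unidentified" in fit.flags
        assert np.all(fit.schedule.i == 0) and np.all(fit.schedule.r == 0)
        assert np.all(fit.schedule.f == 0)

    def test_reported_discrepancy_is_zero_for_consistent_inputs(self, noise_free_rates):
        obs, mortality = single_sex_rates(noise_free_rates, "female")
        fit = fit_consistent(obs, mortality)
        assert fit.discrepancy == pytest.approx(0.0, abs=1e-6)


class TestSmoothing:
    @pytest.mark.parametrize("method", ["piecewise-linear", "moving-average", "cubic-spline"])
    def test_constant_preserved(self, method):
        fn = smooth_schedule(CONST(3.7), method)
        ages = np.linspace(0, 99, 23)
        assert fn(ages) == pytest.approx(np.full_like(ages, 3.7))

    def test_piecewise_linear_between_midpoints(self):
        bands = (AgeBand(0, 6), AgeBand(6, 12))
        fn = smooth_schedule([3.0, 9.0], "piecewise-linear", bands)
        assert fn(0.5 * (3.0 + 9.0)) == pytest.approx(6.0)

    def test_moving_average_window_three(self):
        bands = (AgeBand(0, 6), AgeBand(6, 13), AgeBand(13, 19))
        fn = smooth_schedule([1.0, 4.0, 1.0], "moving-average", bands)
        assert fn(bands[1].midpoint()) == pytest.approx(2.0)

    def test_spline_reproduces_midpoint_values(self):
        vals = np.array([1.0, 4.0, 2.0, 5.0, 3.0, 2.5])
        fn = smooth_schedule(vals, "cubic-spline")
        mids = [b.midpoint(100.0) for b in DEFAULT_BANDS]
        assert fn(np.array(mids)) == pytest.approx(vals)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown smoothing method"):
            smooth_schedule(CONST(1.0), "loess")


class TestPropagateUncertainty:
    @staticmethod
    def _passthrough(df):
        return {"q": float(df["q"].iloc[0])}

    def test_zero_se_degenerate_interval(self):
        obs = pd.DataFrame({"q": [10.0], "q_se": [0.0]})
        out = propagate_uncertainty(obs, None, UncertaintySpec(iterations=50), model=self._passthrough)
        assert out.loc["q", "lo"] == out.loc["q", "hi"] == out.loc["q", "value"] == 10.0

    def test_deterministic_under_fixed_seed(self):
        obs = pd.DataFrame({"q": [10.0], "q_se": [1.0]})
        spec = UncertaintySpec(iterations=300, seed=11)
        a = propagate_uncertainty(obs, None, spec, model=self._passthrough)
        b = propagate_uncertainty(obs, None, spec, model=self._passthrough)
        pd.testing.assert_frame_equal(a, b)

    def test_normal_passthrough_matches_analytic_quantiles(self):
        """Resampled N(10,1) quantity has 95% interval ~= (8.04, 11.96)."""
        obs = pd.DataFrame({"q": [10.0], "q_se": [1.0]})
        out = propagate_uncertainty(
            obs, None, UncertaintySpec(iterations=10000, seed=2), model=self._passthrough
        )
        assert out.loc["q", "lo"] == pytest.approx(10 - 1.96, abs=0.1)
        assert out.loc["q", "hi"] == pytest.approx(10 + 1.96, abs=0.1)

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            UncertaintySpec(iterations=0)


def test_partition_validation_rejects_gaps():
    with pytest.raises(ValueError):
        validate_partition((AgeBand(0, 6), AgeBand(7, 13)))
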