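"""DALY arithmetic: YLD both ways, life-table YLL, assembly, method comparison."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiburden.bands import AgeBand
from epiburden.burden import (
    assemble_daly,
    burden_total,
    compare_methods,
    yld_incidence,
    yld_prevalence,
    yll,
)
from epiburden.life_table import LifeTable, load_life_table


class TestYld:
    def test_prevalence_based_published_inputs(self):
        """Prevalent cases x DW on the all-ages aggregate inputs."""
        assert yld_prevalence(39313, 2.6e-3, 0.346) == pytest.approx(35.4, abs=0.05)
        assert yld_prevalence(42443, 2.4e-3, 0.346) == pytest.approx(35.2, abs=0.05)

    def test_incidence_based_published_inputs(self):
        """Incident cases x duration x DW on the all-ages aggregate inputs."""
        assert yld_incidence(39313, 19.4e-5, 21.5, 0.346) == pytest.approx(56.7, abs=0.05)
        assert yld_incidence(42443, 17.2e-5, 19.7, 0.346) == pytest.approx(49.8, abs=0.05)

    def test_zero_weight_and_zero_duration(self):
        assert yld_prevalence(10000, 0.01, 0.0) == 0.0
        assert yld_incidence(10000, 1e-4, 0.0, 0.5) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            yld_prevalence(-1, 0.01, 0.3)
        with pytest.raises(ValueError):
            yld_incidence(100, -1e-4, 10, 0.3)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.floats(1.0, 1e6),
        st.floats(0.0, 1.0),
        st.floats(0.01, 0.99),
        st.floats(1.1, 4.0),
    )
    def test_linear_in_population_and_weight(self, pop, prev, dw, scale):
        base = yld_prevalence(pop, prev, dw)
        assert yld_prevalence(pop * scale, prev, dw) == pytest.approx(base * scale, rel=1e-12)
        if dw * scale < 1.0:
            assert yld_prevalence(pop, prev, dw * scale) == pytest.approx(base * scale, rel=1e-12)

    def test_methods_agree_in_stationary_limit(self):
        """When prevalence = incidence x duration the two YLD conventions coincide."""
        pop, inc, dur, dw = 50000.0, 2.1e-4, 18.0, 0.346
        prev = inc * dur
        assert yld_prevalence(pop, prev, dw) == pytest.approx(
            yld_incidence(pop, inc, dur, dw), rel=1e-14
        )


class TestYll:
    def test_empty_and_birth_death(self):
        table = load_life_table("gbd2010_standard")
        assert yll([], table) == 0.0
        assert yll([(0.0, 1.0)], table) == pytest.approx(86.02)

    def test_hand_summed_deaths(self):
        table = LifeTable(
            np.array([0.0, 10.0, 20.0, 50.0, 100.0]),
            np.array([80.0, 72.0, 64.0, 36.0, 1.0]),
        )
        assert yll([(10.0, 2.0), (50.0, 1.0)], table) == pytest.approx(2 * 72 + 36)

    def test_band_deaths_follow_age_convention(self):
        table = LifeTable(np.array([0.0, 100.0]), np.array([100.0, 0.5]))
        band = AgeBand(20, 30)
        mid = yll([(band, 1.0)], table, convention="midpoint")
        lo = yll([(band, 1.0)], table, convention="lower")
        hi = yll([(band, 1.0)], table, convention="upper")
        assert lo > mid > hi

    def test_negative_counts_rejected(self):
        table = LifeTable(np.array([0.0, 100.0]), np.array([80.0, 1.0]))
        with pytest.raises(ValueError):
            yll([(10.0, -1.0)], table)


class TestAssembly:
    @staticmethod
    def cells():
        return pd.DataFrame(
            {
                "sex": ["male", "male", "female", "female"],
                "age_lo": [0.0, 50.0, 0.0, 50.0],
                "age_hi": [50.0, np.nan, 50.0, np.nan],
                "population": [10000.0, 5000.0, 11000.0, 6000.0],
                "yll": [30.0, 55.0, 20.0, 26.0],
                "yld": [12.0, 6.0, 14.0, 7.0],
            }
        )

    def test_daly_is_yll_plus_yld_every_row(self):
        out = assemble_daly(self.cells())
        assert np.allclose(out["daly"], out["yll"] + out["yld"])

    def test_totals_equal_band_sums_and_rates_invert(self):
        out = assemble_daly(self.cells())
        total = burden_total(out)
        assert total["daly"] == pytest.approx(30 + 55 + 20 + 26 + 12 + 6 + 14 + 7)
        back = out["daly_per_1000"] * out["population"] / 1000.0
        assert np.allclose(back, out["daly"])

    def test_zero_burden_is_zero_everywhere(self):
        cells = self.cells().assign(yll=0.0, yld=0.0)
        out = assemble_daly(cells)
        assert (out[["yll", "yld", "daly", "daly_per_1000"]] == 0).all().all()

    def test_mismatched_strata_rejected(self):
        bad = self.cells().drop(columns=["population"])
        with pytest.raises(ValueError, match="lack columns"):
            assemble_daly(bad)
        dup = pd.concat([self.cells()] * 2, ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            assemble_daly(dup)


class TestCompareMethods:
    def test_published_all_ages_differences(self):
        male = compare_methods(35.37, 56.74, 151.6)
        female = compare_methods(35.24, 49.76, 95.7)
        assert round(male["pct_diff_yld"]) == 38
        assert round(female["pct_diff_yld"]) == 29

    def test_identical_methods_give_zero(self):
        out = compare_methods(40.0, 40.0, 100.0)
        assert out["pct_diff_yld"] == 0.0 and out["pct_diff_daly"] == 0.0

    def test_zero_incidence_yld_rejected(self):
        with pytest.raises(ValueError):
            compare_methods(10.0, 0.0, 100.0)
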