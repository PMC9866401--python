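"""Individual-based simulator: draws, totals, windows, total-rate curve."""

import numpy as np
import pytest

import stemtherm as st
from stemtherm.errors import ConfigurationError, EmptyWindowError

from oracles import deterministic_window, failure_probability_numeric


@pytest.fixture
def settings():
    return st.SimulationSettings(n_individuals=5000, deadline_days=182.0, seed=42)


class TestDrawIndividualRates:
    def test_cv_zero_is_degenerate(self, fixture_models, settings):
        model = fixture_models["busseola_fusca"].with_cv(0.0)
        rates = st.draw_individual_rates(model, 20.0, settings)
        tau = model.stage_rates(20.0)
        assert rates.shape == (5000, 3)
        np.testing.assert_array_equal(rates, np.broadcast_to(tau, rates.shape))

    def test_null_stage_rate_gives_zero_column(self, fixture_models, settings):
        # at 12 °C the C. partellus larval curve (CTmin 13.5) predicts no development
        model = fixture_models["chilo_partellus"]
        rates = st.draw_individual_rates(model, 12.0, settings)
        assert np.all(rates[:, 1] == 0.0)
        assert np.all(rates[:, 0] > 0.0)  # egg stage (CTmin 10.4) does develop

    def test_sample_mean_matches_tau(self, fixture_models, settings):
        model = fixture_models["busseola_fusca"]  # cv = 0.15
        tau = 0.1
        curve = st.TPCParameterSet(
            st.get_model("kontodimas_04"), {"a": 1.0, "CTmin": 0.1, "CTmax": 45.0}
        )
        # build a one-off model whose larval tau at 20 °C is exactly 0.1
        a = tau / st.evaluate_rate(curve, 20.0)
        curve = st.TPCParameterSet(
            st.get_model("kontodimas_04"), {"a": a, "CTmin": 0.1, "CTmax": 45.0}
        )
        model = st.SpeciesDevelopmentModel(
            "synthetic", {"egg": curve, "larva": curve, "pupa": curve}, cv=0.15
        )
        rates = st.draw_individual_rates(model, 20.0, settings)
        se = 0.15 * tau / np.sqrt(5000)
        assert abs(rates[:, 1].mean() - tau) < 3 * se

    def test_negative_cv_rejected(self, fixture_models):
        with pytest.raises(ConfigurationError):
            fixture_models["busseola_fusca"].with_cv(-0.1)

    def test_draws_deterministic_under_seed(self, fixture_models, settings):
        model = fixture_models["busseola_fusca"]
        a = st.draw_individual_rates(model, 20.0, settings)
        b = st.draw_individual_rates(model, 20.0, settings)
        np.testing.assert_array_equal(a, b)


class TestSimulateDevTimes:
    def test_cv_zero_total_equals_deterministic_sum(self, fixture_models, settings):
        model = fixture_models["busseola_fusca"].with_cv(0.0)
        dist = st.simulate_dev_times(model, 15.2, settings)
        expected = float((1.0 / model.stage_rates(15.2)).sum())
        assert dist.mean == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(181.4, abs=0.05)

    def test_all_fail_below_every_ctmin(self, fixture_models, settings):
        dist = st.simulate_dev_times(fixture_models["chilo_partellus"], 5.0, settings)
        assert dist.failure_fraction == 1.0
        assert np.isinf(dist.times).all()

    def test_failure_fraction_near_half_at_published_t50min(
        self, fixture_models, settings
    ):
        dist = st.simulate_dev_times(fixture_models["busseola_fusca"], 15.2, settings)
        assert dist.failure_fraction == pytest.approx(0.5, abs=0.05)

    def test_quantiles_ordered(self, fixture_models, settings):
        dist = st.simulate_dev_times(fixture_models["busseola_fusca"], 25.0, settings)
        assert dist.q2_5 <= dist.mean <= dist.q97_5

    def test_failure_nonincreasing_in_deadline(self, fixture_models):
        model = fixture_models["busseola_fusca"]
        fracs = []
        for deadline in (100.0, 150.0, 182.0, 250.0):
            s = st.SimulationSettings(n_individuals=2000, deadline_days=deadline, seed=7)
            fracs.append(st.simulate_dev_times(model, 16.0, s).failure_fraction)
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_median_close_to_deterministic_sum(self, fixture_models, settings):
        model = fixture_models["chilo_partellus"]
        for T in (20.0, 25.0, 30.0):
            tau = model.stage_rates(T)
            assert np.all(tau > 0.01)
            det = float((1.0 / tau).sum())
            med = float(np.median(st.simulate_dev_times(model, T, settings).times))
            assert med == pytest.approx(det, rel=0.02)

    def test_failure_fraction_matches_numeric_integration(self, fixture_models, settings):
        model = fixture_models["busseola_fusca"]
        for T in (15.0, 15.5, 16.0, 25.0, 32.5):
            sim = st.simulate_dev_times(model, T, settings).failure_fraction
            oracle = failure_probability_numeric(model, T, 182.0)
            assert sim == pytest.approx(oracle, abs=0.02), T


class TestTotalRateCurve:
    def test_spot_value(self, fixture_models):
        r = st.total_rate_curve(fixture_models["chilo_partellus"], [25.0])[0]
        assert r == pytest.approx(0.02206, abs=2e-5)
        assert 1.0 / r == pytest.approx(45.34, abs=0.05)

    def test_zero_outside_common_domain(self, fixture_models):
        model = fixture_models["chilo_partellus"]
        # larval domain (13.5, 37.1) is the binding constraint
        assert st.total_rate_curve(model, [13.0, 37.5, 5.0, 45.0]).tolist() == [0] * 4

    def test_harmonic_bound(self, fixture_models):
        model = fixture_models["busseola_fusca"]
        grid = np.linspace(0, 50, 101)
        total = st.total_rate_curve(model, grid)
        tau = model.stage_rates(grid)
        assert np.all(total <= tau.min(axis=-1) + 1e-12)


class TestRmax:
    def test_argmax_between_stage_optima(self, fixture_models):
        for model in fixture_models.values():
            topts = [
                st.thermal_traits(model.stage_curves[s]).Topt for s in st.STAGES
            ]
            _, argmax = st.rmax(model)
            assert min(topts) - 1e-9 <= argmax <= max(topts) + 1e-9

    def test_homogeneity(self, fixture_models):
        model = fixture_models["busseola_fusca"]
        doubled_curves = {}
        for stage, params in model.stage_curves.items():
            values = dict(params.values)
            values[params.model.scale_param] *= 2.0
            doubled_curves[stage] = st.TPCParameterSet(params.model, values)
        doubled = st.SpeciesDevelopmentModel("scaled", doubled_curves, cv=model.cv)
        r1, t1 = st.rmax(model)
        r2, t2 = st.rmax(doubled)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)
        assert t2 == t1


class TestThermalWindow:
    def test_cv_zero_window_matches_deterministic_crossings(self, fixture_models):
        model = fixture_models["busseola_fusca"].with_cv(0.0)
        s = st.SimulationSettings(n_individuals=1, deadline_days=182.0, seed=0)
        win = st.thermal_window(model, s)
        lo, hi = deterministic_window(model)
        assert win.t50min == pytest.approx(lo, abs=0.06)
        assert win.t50max == pytest.approx(hi, abs=0.06)

    def test_window_within_stage_thresholds(self, fixture_models):
        model = fixture_models["chilo_partellus"]
        s = st.SimulationSettings(n_individuals=2000, seed=3)
        win = st.thermal_window(model, s)
        ctmins = [model.stage_curves[s_].ctmin for s_ in st.STAGES]
        ctmaxs = [model.stage_curves[s_].ctmax for s_ in st.STAGES]
        assert win.t50min >= max(ctmins)
        assert win.t50max <= min(ctmaxs)

    def test_doubling_cohort_barely_moves_bounds(self, fixture_models):
        model = fixture_models["busseola_fusca"]
        # fine bisection tolerance so the comparison measures sampling noise,
        # not the bisection grid
        w5 = st.thermal_window(
            model, st.SimulationSettings(n_individuals=5000, seed=9), tol=0.005
        )
        w10 = st.thermal_window(
            model, st.SimulationSettings(n_individuals=10000, seed=9), tol=0.005
        )
        assert abs(w5.t50min - w10.t50min) < 0.05
        assert abs(w5.t50max - w10.t50max) < 0.05

    def test_empty_window_when_nothing_develops(self, fixture_models):
        # a 14-day season is shorter than any total development time here
        model = fixture_models["busseola_fusca"]
        s = st.SimulationSettings(n_individuals=200, deadline_days=14.0, seed=0)
        with pytest.raises(EmptyWindowError):
            st.thermal_window(model, s)
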