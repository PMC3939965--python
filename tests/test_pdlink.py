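"""Effect-compartment link, sigmoid-Emax model, hysteresis, and PD fitting."""

from dataclasses import replace

import numpy as np
import pytest

from methapop import (
    DoseRegimen,
    PDParameters,
    ce_steady_state,
    conc_steady_state,
    effect_steady_state,
    fit_pd_individual,
    fit_pd_population,
    hysteresis_loop_area,
    sows_effect,
    suppression_loop_area,
)
from methapop.pdlink import PDFitResult

from .conftest import ode_profiles, random_pk_params


@pytest.fixture(scope="module")
def pd_pop_params() -> PDParameters:
    return PDParameters(e0=25.0, emax=0.3198, ec50=413.47, n=1.0, ke0=0.5)


class TestEffectSite:
    def test_instantaneous_equilibration_limit(self, pop_mean_params, regimen60):
        t = np.linspace(0.0, 24.0, 25)
        cp = conc_steady_state(pop_mean_params, regimen60, t)
        ce = ce_steady_state(pop_mean_params, 1e4, regimen60, t)
        assert np.max(np.abs(ce - cp) / cp) < 5e-3

    def test_zero_dose(self, pop_mean_params):
        t = np.linspace(0.0, 24.0, 5)
        assert np.all(ce_steady_state(pop_mean_params, 0.5, DoseRegimen(0.0), t) == 0.0)

    def test_matches_ode_integration(self, pop_mean_params, regimen60):
        t = np.array([0.0, 1.0, 2.0, 4.0, 6.0, 10.0, 16.0, 23.9])
        ce = ce_steady_state(pop_mean_params, 0.5, regimen60, t)
        _, ce_ode = ode_profiles(pop_mean_params, regimen60, t, ke0=0.5, n_intervals=60)
        assert np.max(np.abs(ce - ce_ode) / ce_ode) < 1e-5

    def test_periodicity(self, pop_mean_params, regimen60):
        t = np.linspace(0.0, 24.0, 9)
        a = ce_steady_state(pop_mean_params, 0.5, regimen60, t)
        b = ce_steady_state(pop_mean_params, 0.5, regimen60, t + 24.0)
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestSowsEffect:
    def test_zero_concentration_gives_baseline(self, pd_pop_params):
        assert sows_effect(pd_pop_params, 0.0) == pd_pop_params.e0

    def test_half_maximum_at_ec50(self):
        pd = PDParameters(e0=30.0, emax=0.3198, ec50=413.47)
        assert sows_effect(pd, pd.ec50) == pytest.approx(25.203, abs=1e-3)

    def test_plateau(self, pd_pop_params):
        val = sows_effect(pd_pop_params, 1e12)
        assert val == pytest.approx(pd_pop_params.e0 * (1 - pd_pop_params.emax), rel=1e-6)

    def test_monotone_and_bounded(self, pd_pop_params):
        ce = np.linspace(0.0, 5000.0, 400)
        e = sows_effect(pd_pop_params, ce)
        assert np.all(np.diff(e) <= 0)
        assert np.all(e <= pd_pop_params.e0)
        assert np.all(e >= pd_pop_params.e0 * (1 - pd_pop_params.emax))

    def test_effect_profile_periodicity(self, pop_mean_params, pd_pop_params, regimen60):
        pred0 = effect_steady_state(pop_mean_params, pd_pop_params, regimen60, 0.0)
        pred24 = effect_steady_state(pop_mean_params, pd_pop_params, regimen60, 24.0)
        assert pred0.e[0] == pytest.approx(pred24.e[0], rel=1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            PDParameters(e0=70.0, emax=0.3, ec50=400.0)
        with pytest.raises(ValueError):
            PDParameters(e0=25.0, emax=1.2, ec50=400.0)
        with pytest.raises(ValueError):
            PDParameters(e0=25.0, emax=0.3, ec50=-5.0)


class TestHysteresis:
    square_t = [0.0, 1.0, 2.0, 3.0]

    def test_unit_square_counter_clockwise(self):
        x = [0.0, 1.0, 1.0, 0.0]
        y = [0.0, 0.0, 1.0, 1.0]
        assert hysteresis_loop_area(self.square_t, x, y) == pytest.approx(1.0)

    def test_unit_square_clockwise(self):
        x = [0.0, 0.0, 1.0, 1.0]
        y = [0.0, 1.0, 1.0, 0.0]
        assert hysteresis_loop_area(self.square_t, x, y) == pytest.approx(-1.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            hysteresis_loop_area([0, 1, 2], [0, 1, 0], [0, 1, 1])

    def test_unordered_times_rejected(self):
        with pytest.raises(ValueError):
            hysteresis_loop_area([0, 2, 1, 3], [0, 1, 1, 0], [0, 0, 1, 1])

    def test_suppression_loop_counter_clockwise_and_ke0_collapse(
        self, pop_mean_params, pd_pop_params, regimen60
    ):
        t = np.linspace(0.0, 24.0, 241)[:-1]
        cp = conc_steady_state(pop_mean_params, regimen60, t)
        areas = {}
        for ke0 in (0.1, 0.5, 2.0, 10.0, 1e4):
            pd = replace(pd_pop_params, ke0=ke0)
            e = sows_effect(pd, ce_steady_state(pop_mean_params, ke0, regimen60, t))
            areas[ke0] = suppression_loop_area(t, cp, e, pd.e0)
        # effect lags plasma: counter-clockwise loop for every finite ke0
        assert all(a > 0 for a in areas.values())
        # the loop collapses once equilibration is fast relative to the interval
        assert areas[0.5] > areas[2.0] > areas[10.0] > areas[1e4]
        assert areas[1e4] < 1e-2 * areas[0.5]


class TestPDFitting:
    def _ce_builder(self, pk, regimen, times):
        return lambda ke0: ce_steady_state(pk, ke0, regimen, times)

    def test_noise_free_recovery(self, pop_mean_params, regimen60):
        times = np.linspace(0.0, 24.0, 25)
        builder = self._ce_builder(pop_mean_params, regimen60, times)
        truth = PDParameters(e0=28.0, emax=0.45, ec50=350.0)
        sows = sows_effect(truth, builder(truth.ke0))
        init = PDParameters(e0=25.0, emax=0.3, ec50=400.0)
        fit = fit_pd_individual(builder, times, sows, init)
        assert fit.success and fit.identified
        assert fit.params.ec50 == pytest.approx(truth.ec50, rel=0.02)
        assert fit.params.emax == pytest.approx(truth.emax, rel=0.02)

    def test_constant_sows_gives_no_drug_effect(self, pop_mean_params, regimen60):
        times = np.linspace(0.0, 24.0, 25)
        builder = self._ce_builder(pop_mean_params, regimen60, times)
        init = PDParameters(e0=25.0, emax=0.3, ec50=400.0)
        fit = fit_pd_individual(builder, times, np.full(25, 20.0), init)
        assert fit.success
        assert fit.params.emax <= 0.01

    def test_too_few_observations(self, pop_mean_params, regimen60):
        times = np.array([0.0, 6.0, 12.0])
        builder = self._ce_builder(pop_mean_params, regimen60, times)
        with pytest.raises(ValueError):
            fit_pd_individual(builder, times, np.array([20.0, 18.0, 19.0]),
                              PDParameters(e0=25.0, emax=0.3, ec50=400.0))


class TestPDPopulation:
    @staticmethod
    def _fit(ec50, emax=0.3, e0=25.0, identified=True):
        return PDFitResult(
            PDParameters(e0=e0, emax=emax, ec50=ec50),
            success=True, identified=identified, sse=0.0, n_obs=7,
        )

    def test_identical_fits(self):
        summ = fit_pd_population([self._fit(400.0)] * 5)
        assert summ["ec50"].sd == 0.0
        assert summ["ec50"].fold_change == pytest.approx(1.0)
        assert summ["emax_pct"].mean == pytest.approx(30.0)

    def test_fold_change(self):
        summ = fit_pd_population([self._fit(200.0), self._fit(600.0)])
        assert summ["ec50"].fold_change == pytest.approx(3.0)

    def test_non_identified_excluded_from_summary(self):
        fits = [self._fit(300.0), self._fit(500.0), self._fit(5000.0, identified=False)]
        summ = fit_pd_population(fits)
        assert summ["ec50"].max == 500.0
        assert summ["ec50"].n == 2

    def test_requires_two_identified_fits(self):
        with pytest.raises(ValueError):
            fit_pd_population([self._fit(300.0)])
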