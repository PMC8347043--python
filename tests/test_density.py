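"""Calibrated densitometry from transmission plateaus and diffraction
backgrounds, plus the AFGA discrepancy series and transition bracketing."""

import numpy as np
import pytest

from glassprobe import density as den
from glassprobe import synthetic as syn
from glassprobe.afga import default_afga_model, total_sigma, window_integral
from glassprobe.density import (
    DensityEstimate,
    afga_discrepancy,
    background_integral,
    density_from_diffraction,
    density_from_transmission,
    detect_transition,
    scattering_power,
    transmission_to_sigma,
)
from glassprobe.synthetic import density_at, gen_diffraction, gen_transmission

CAL = (-20.0, 1.3)


def _transmission_series(stoich, model, schedule, E, noise, seed0):
    return [gen_transmission(stoich, model, density_at(schedule, T), 0.3, E,
                             noise, seed0 + i, temperature=T)
            for i, T in enumerate(schedule.temperatures)]


def _diffraction_series(schedule, d_grid, noise, seed0):
    return [gen_diffraction(density_at(schedule, T), 500.0, 100.0, d_grid,
                            noise, seed0 + i, temperature=T)
            for i, T in enumerate(schedule.temperatures)]


class TestScatteringPower:
    def test_unit_transmission_gives_zero(self):
        E = np.geomspace(5.0, 200.0, 40)
        c = syn.TransmissionCurve(E, np.ones(E.size), 25.0, 0.3)
        s, _ = scattering_power(c)
        assert s == 0.0

    def test_inverse_of_exponential(self):
        E = np.geomspace(10.0, 100.0, 40)
        c = syn.TransmissionCurve(E, np.full(E.size, np.exp(-0.389)), 25.0, 0.3)
        s, _ = scattering_power(c)
        assert s == pytest.approx(0.389, rel=1e-12)

    def test_synthetic_curve_matches_nds_oracle(self, stoich, afga_model, energy_grid):
        c = gen_transmission(stoich, afga_model, 1.3, 0.3, energy_grid, 0.0, 0)
        s, _ = scattering_power(c)
        nd = syn.number_density(1.3, stoich.molar_mass) * 0.3 * 1e-24
        from glassprobe.afga import free_sigma_per_formula_unit

        assert s == pytest.approx(nd * free_sigma_per_formula_unit(stoich), rel=3e-3)

    def test_sparse_window_rejected(self):
        E = np.geomspace(1.0, 5.0, 30)
        c = syn.TransmissionCurve(E, np.full(E.size, 0.5), 25.0, 0.3)
        with pytest.raises(ValueError):
            scattering_power(c)


class TestTransmissionToSigma:
    def test_round_trip_recovers_generating_curve(self, stoich, afga_model, energy_grid):
        c = gen_transmission(stoich, afga_model, 1.3, 0.3, energy_grid, 0.0, 0,
                             temperature=25.0)
        sigma = transmission_to_sigma(c, 1.3, stoich)
        truth = total_sigma(energy_grid, afga_model, 25.0)
        np.testing.assert_allclose(sigma.sigma_total, truth.sigma_total, rtol=1e-10)

    def test_inverse_density_scaling(self, stoich, afga_model, energy_grid):
        c = gen_transmission(stoich, afga_model, 1.3, 0.3, energy_grid, 0.0, 0)
        s_full = transmission_to_sigma(c, 1.3, stoich).sigma_total
        s_half = transmission_to_sigma(c, 0.65, stoich).sigma_total
        np.testing.assert_allclose(s_half, 2.0 * s_full, rtol=1e-12)

    def test_area_density_constant_oracle(self, stoich):
        # n_fu d = rho N_A / M d = 1.291e-3 per barn at rho 1.3, d 0.3 cm
        nd = syn.number_density(1.3, 181.96) * 0.3 * 1e-24
        assert nd == pytest.approx(1.291e-3, abs=2e-6)


class TestCalibratedEstimators:
    def test_exact_at_calibration_point(self, stoich, afga_model, schedule, energy_grid):
        series = _transmission_series(stoich, afga_model, schedule, energy_grid, 0.005, 10)
        est = density_from_transmission(series, CAL)
        at_ref = [e for e in est if e.temperature == -20.0][0]
        assert at_ref.density == 1.3

    def test_transmission_and_diffraction_agree_noise_free(
            self, stoich, afga_model, schedule, energy_grid):
        d_grid = np.arange(0.8, 4.0, 0.005)
        ts = _transmission_series(stoich, afga_model, schedule, energy_grid, 0.0, 0)
        ds = _diffraction_series(schedule, d_grid, 0.0, 0)
        et = density_from_transmission(ts, CAL)
        ed = density_from_diffraction(ds, CAL)
        # agreement is limited only by the residual effective-temperature
        # dependence of the epithermal plateau (~2e-5 g/cm^3), far below
        # any counting noise; the diffraction estimator is exactly linear
        for a, b in zip(et, ed):
            assert a.density == pytest.approx(b.density, abs=1e-4)

    def test_diffraction_noise_free_recovery_exact(self, schedule):
        d_grid = np.arange(0.8, 4.0, 0.005)
        ds = _diffraction_series(schedule, d_grid, 0.0, 0)
        est = density_from_diffraction(ds, CAL)
        # the calibration pins -20 C to 1.3 exactly; the schedule's glassy
        # plateau differs from 1.3 only by the 1e-7 sigmoid tail there
        for e in est:
            assert e.density == pytest.approx(density_at(schedule, e.temperature),
                                              rel=1e-5)

    def test_end_to_end_recovery_under_noise(self, stoich, afga_model, schedule,
                                             energy_grid):
        d_grid = np.arange(0.8, 4.0, 0.005)
        max_err_t, max_err_d = [], []
        for seed in range(20):
            ts = _transmission_series(stoich, afga_model, schedule, energy_grid,
                                      0.005, 1000 * seed)
            ds = _diffraction_series(schedule, d_grid, 0.65, 1000 * seed + 500)
            et = density_from_transmission(ts, CAL)
            ed = density_from_diffraction(ds, CAL)
            truth = [density_at(schedule, T) for T in schedule.temperatures]
            max_err_t.append(max(abs(e.density - r) for e, r in zip(et, truth)))
            max_err_d.append(max(abs(e.density - r) for e, r in zip(ed, truth)))
        assert np.median(max_err_t) < 0.02
        assert np.median(max_err_d) < 0.02

    def test_missing_reference_temperature_rejected(self, schedule):
        d_grid = np.arange(0.8, 4.0, 0.01)
        ds = _diffraction_series(schedule, d_grid, 0.0, 0)
        with pytest.raises(ValueError):
            density_from_diffraction(ds, (-40.0, 1.3))


class TestBackgroundWindow:
    def test_flat_pattern_unit_window(self):
        d = np.linspace(2.5, 3.5, 101)
        p = syn.DiffractionPattern(d, np.full(d.size, 130.0), 25.0)
        integral, _ = background_integral(p, (2.5, 3.5))
        assert integral == pytest.approx(130.0, rel=1e-9)

    def test_default_window_clears_all_reflections(self):
        d = np.linspace(0.8, 4.0, 500)
        p = syn.DiffractionPattern(d, np.ones(d.size), 25.0)
        background_integral(p, (2.5, 3.5))  # largest allowed d is 2.338 A

    def test_window_over_bragg_peak_names_reflection(self):
        d = np.linspace(0.8, 4.0, 500)
        p = syn.DiffractionPattern(d, np.ones(d.size), 25.0)
        with pytest.raises(ValueError, match=r"\(1, 1, 1\)"):
            background_integral(p, (2.2, 3.0))


class TestAfgaDiscrepancy:
    def test_self_consistent_scenario_is_flat_zero(self, stoich, afga_model,
                                                   schedule, energy_grid):
        ts = _transmission_series(stoich, afga_model, schedule, energy_grid, 0.0, 0)
        measured = [transmission_to_sigma(c, density_at(schedule, c.temperature), stoich)
                    for c in ts]
        rows = afga_discrepancy(measured, afga_model)
        for _, delta, _ in rows:
            assert abs(delta) < 1e-6

    def test_mode_softening_departs_above_injection(self, stoich, schedule, energy_grid):
        # soften the OH torsional mode above 40 C only; the discrepancy
        # series must leave zero exactly there
        base = default_afga_model(stoich)
        measured = []
        for T in schedule.temperatures:
            model_T = (default_afga_model(stoich, modes={"OH": [(420.0, 1.0), (200.0, 1.0), (55.0, 1.0)]})
                       if T > 40.0 else base)
            measured.append(total_sigma(energy_grid, model_T, T))
        rows = afga_discrepancy(measured, base)
        below = [abs(d) for T, d, _ in rows if T <= 40.0]
        above = [abs(d) for T, d, _ in rows if T > 40.0]
        assert max(below) < 1e-6
        assert min(above) > 10.0 * max(below + [1e-12])


class TestDetectTransition:
    def _estimates(self, temps, rhos):
        return [DensityEstimate(t, r, 0.0, "transmission")
                for t, r in zip(temps, rhos)]

    def test_step_series_bracketed(self):
        est = self._estimates([0, 20, 40, 60, 80], [1.3, 1.3, 1.3, 1.1, 1.1])
        assert detect_transition(est) == (40.0, 60.0)

    def test_linear_series_has_no_transition(self):
        est = self._estimates([0, 20, 40, 60, 80], [1.3, 1.25, 1.2, 1.15, 1.1])
        assert detect_transition(est) is None

    def test_sigmoid_on_study_grid(self, schedule):
        temps = schedule.temperatures
        est = self._estimates(temps, [density_at(schedule, T) for T in temps])
        assert detect_transition(est) == (40.0, 60.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_transition(self._estimates([0, 20, 40], [1.3, 1.2, 1.1]))
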