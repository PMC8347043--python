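"""Inverse-geometry recoil kinematics, y-scaling and partitioned NCS fits."""

import numpy as np
import pytest

from glassprobe import compton as nc
from glassprobe.compton import (
    DetectorGeometry,
    aggregate_detectors,
    compare_widths_to_afga,
    recoil_incident_energy,
    solve_intensities,
    tof_of,
    varpro_fit_detector,
    visible_masses,
    y_of_tof,
    y_transform,
)
from glassprobe.synthetic import gen_ncs_spectra

WIDTHS = {1: 5.0, 12: 14.0, 16: 12.0}


class TestKinematics:
    def test_heavy_mass_limit_is_elastic(self):
        e0 = recoil_incident_energy(60.0, 4897.0, 1e6)
        assert e0 == pytest.approx(4897.0, rel=1e-4)

    def test_hydrogen_closed_form_at_60_degrees(self):
        # for A = 1 exactly, E0 = E1 / cos^2(theta)
        assert recoil_incident_energy(60.0, 4897.0, 1.0) == pytest.approx(
            4897.0 / 0.25, rel=1e-12)
        # numeric root of the conservation equations for the proton ratio
        e0 = recoil_incident_energy(60.0, 4897.0, 1.0072765 / 1.0086649)
        assert e0 == pytest.approx(19669.0, abs=1.0)

    def test_hydrogen_unreachable_in_backscattering(self):
        with pytest.raises(ValueError):
            recoil_incident_energy(135.0, 4897.0, 1.0)
        with pytest.raises(ValueError):
            recoil_incident_energy(135.0, 4897.0, 1.0072765 / 1.0086649)

    def test_backscattering_fitter_never_sees_hydrogen(self):
        for theta in (90.0, 110.0, 130.0, 150.0, 170.0):
            vis = visible_masses([1, 12, 16, 27], DetectorGeometry(theta=theta))
            assert 1 not in vis
            assert {12, 16, 27} <= set(vis)

    def test_tof_arithmetic_oracle(self):
        g = DetectorGeometry(theta=60.0, L0=11.0, L1=0.7, E1=4897.0)
        # 11 m / (437.39 sqrt(19588)) + 0.7 m / (437.39 sqrt(4897)), in us
        assert tof_of(19588.0, g) == pytest.approx(202.6, abs=0.1)

    def test_tof_strictly_decreasing_in_energy(self):
        g = DetectorGeometry(theta=60.0)
        E = np.linspace(3000.0, 40000.0, 50)
        t = np.array([tof_of(e, g) for e in E])
        assert np.all(np.diff(t) < 0)

    def test_recoil_peak_maps_to_y_zero(self):
        g = DetectorGeometry(theta=60.0)
        for mass in (1, 12, 16, 27):
            A = nc._mass_ratio(mass)
            t_c = tof_of(recoil_incident_energy(g.theta, g.E1, A), g)
            assert abs(y_of_tof(t_c, g, mass)) < 1e-8


class TestYTransform:
    def test_unit_normalization(self, stoich):
        det = DetectorGeometry(theta=60.0)
        spectra = gen_ncs_spectra(stoich, {1: 5.0}, [det], baseline=0.0)
        y, J = y_transform(spectra[0], 1)
        assert np.trapezoid(J, y) == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_round_trip_width(self, stoich):
        det = DetectorGeometry(theta=60.0, resolution_width=0.5)
        spectra = gen_ncs_spectra(stoich, {1: 5.0}, [det], baseline=0.0)
        y, J = y_transform(spectra[0], 1)
        sel = np.abs(y) < 20.0
        mu = np.trapezoid(y[sel] * J[sel], y[sel]) / np.trapezoid(J[sel], y[sel])
        var = np.trapezoid((y[sel] - mu) ** 2 * J[sel], y[sel]) / np.trapezoid(J[sel], y[sel])
        expected = np.sqrt(5.0**2 + 0.5**2)  # NMD plus resolution, in quadrature
        assert np.sqrt(var) == pytest.approx(expected, rel=0.02)


class TestVarproFit:
    def test_single_mass_noise_free_exact(self, stoich):
        det = DetectorGeometry(theta=60.0)
        spectra = gen_ncs_spectra(stoich, {12: 14.0}, [det], counts_scale=5e3,
                                  baseline=2.0)
        fit = varpro_fit_detector(spectra[0], [12], {12: 18.0})
        assert fit.widths[12] == pytest.approx(14.0, rel=1e-6)
        assert fit.baseline == pytest.approx(2.0, rel=1e-6)

    def test_intensities_match_linear_algebra_oracle(self, stoich):
        det = DetectorGeometry(theta=60.0)
        spectra = gen_ncs_spectra(stoich, WIDTHS, [det], counts_scale=2e4,
                                  baseline=5.0, noise_scale=1.0, seed=3)
        sp = spectra[0]
        intens, base, _ = solve_intensities(sp, list(WIDTHS), WIDTHS)
        # independent oracle: unconstrained normal equations (interior
        # solution, so the non-negativity constraint is inactive)
        w = 1.0 / sp.errors
        cols = [nc.peak_profile(sp.tof, sp.geometry, m, WIDTHS[m]) for m in WIDTHS]
        cols.append(np.ones_like(sp.tof))
        A = np.column_stack(cols) * w[:, None]
        direct = np.linalg.solve(A.T @ A, A.T @ (sp.counts * w))
        np.testing.assert_allclose(np.append(intens, base), direct, rtol=1e-8)

    def test_three_mass_width_recovery_under_noise(self, stoich):
        det = DetectorGeometry(theta=60.0)
        rel_err = {m: [] for m in WIDTHS}
        for seed in range(20):
            spectra = gen_ncs_spectra(stoich, WIDTHS, [det], counts_scale=2e4,
                                      baseline=5.0, noise_scale=1.0, seed=seed)
            fit = varpro_fit_detector(spectra[0], list(WIDTHS),
                                      {m: 1.2 * w for m, w in WIDTHS.items()})
            for m in WIDTHS:
                rel_err[m].append(abs(fit.widths[m] / WIDTHS[m] - 1.0))
        for m in WIDTHS:
            assert np.median(rel_err[m]) < 0.05, (m, np.median(rel_err[m]))


class TestAggregation:
    def _spectra(self, stoich, seed=0, noise=1.0):
        dets = [DetectorGeometry(theta=t) for t in (50.0, 60.0, 70.0, 135.0, 150.0)]
        widths = {**WIDTHS, 27: 15.0}
        from glassprobe.afga import build_stoichiometry
        from glassprobe.gordon_taylor import MoistureValue

        st_al = build_stoichiometry(MoistureValue(0.1069, "wet"), include_al=4.0)
        return gen_ncs_spectra(st_al, widths, dets, counts_scale=2e4,
                               baseline=5.0, noise_scale=noise, seed=seed), widths

    def test_identical_detectors_equal_single_fit(self, stoich):
        det = DetectorGeometry(theta=60.0)
        sp = gen_ncs_spectra(stoich, WIDTHS, [det], counts_scale=2e4,
                             baseline=5.0, noise_scale=1.0, seed=1)[0]
        single = varpro_fit_detector(sp, list(WIDTHS),
                                     {m: 1.15 * w for m, w in WIDTHS.items()})
        agg = aggregate_detectors([sp, sp], list(WIDTHS),
                                  {m: 1.15 * w for m, w in WIDTHS.items()},
                                  n_iterations=1)
        for m in WIDTHS:
            assert agg.widths[m] == pytest.approx(single.widths[m], rel=1e-6)

    def test_relative_intensities_sum_to_one(self, stoich):
        spectra, widths = self._spectra(stoich, seed=2)
        res = aggregate_detectors(spectra, list(widths),
                                  {m: 1.15 * w for m, w in widths.items()},
                                  n_iterations=3)
        assert sum(res.relative_intensities.values()) == pytest.approx(1.0, abs=1e-12)

    def test_constant_composition_across_temperatures(self, stoich):
        # same stoichiometry at each temperature: fitted relative
        # intensities must track the generator's cross-section-weighted
        # atom shares and stay constant across the series
        from glassprobe.afga import build_stoichiometry, free_cross_section
        from glassprobe.constants import MASS_RATIO, SIGMA_BOUND
        from glassprobe.compton import MASS_TO_ELEMENT
        from glassprobe.gordon_taylor import MoistureValue

        st_al = build_stoichiometry(MoistureValue(0.1069, "wet"), include_al=4.0)
        fracs = []
        for i, T in enumerate((-20.0, 20.0, 80.0)):
            spectra, widths = self._spectra(stoich, seed=100 + i)
            res = aggregate_detectors(spectra, list(widths),
                                      {m: 1.15 * w for m, w in widths.items()},
                                      n_iterations=2)
            fracs.append([res.relative_intensities[m] for m in sorted(widths)])
        fracs = np.array(fracs)
        weights = {m: getattr(st_al, MASS_TO_ELEMENT[m]) *
                   free_cross_section(SIGMA_BOUND[MASS_TO_ELEMENT[m]],
                                      MASS_RATIO[MASS_TO_ELEMENT[m]])
                   for m in (1, 12, 16, 27)}
        total = sum(weights.values())
        truth = np.array([weights[m] / total for m in sorted(weights)])
        assert np.all(np.abs(fracs - truth) < 0.02)
        assert np.all(fracs.std(axis=0) < 0.01)


class TestWidthComparison:
    def test_self_consistent_widths_give_zero_delta(self, stoich, afga_model):
        from glassprobe.afga import hydrogen_nmd_width
        from glassprobe.compton import NMDResult

        results = []
        for T in (-20.0, 40.0, 80.0):
            w = hydrogen_nmd_width(afga_model, T)
            results.append(NMDResult(masses=[1], widths={1: w},
                                     width_errors={1: 0.01},
                                     relative_intensities={1: 1.0},
                                     intensity_errors={1: 0.0}, temperature=T))
        rows = compare_widths_to_afga(results, afga_model)
        for _, s_exp, s_mod, delta in rows:
            assert delta == pytest.approx(0.0, abs=1e-12)
            assert s_exp == s_mod

    def test_afga_line_flat_within_two_percent(self, afga_model):
        from glassprobe.afga import hydrogen_nmd_width

        ws = [hydrogen_nmd_width(afga_model, T) for T in (-20.0, 0.0, 20.0, 40.0, 60.0, 80.0)]
        assert (max(ws) - min(ws)) / min(ws) < 0.02
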