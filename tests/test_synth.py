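"""Synthetic generators: determinism, zero-noise identities, scenario shape."""

import numpy as np
import pytest

from hydromp.dielectric import (FrequencyGrid, eval_model, fit_pure_water,
                                fit_solution, water_parameters)
from hydromp.dsc import CycleProtocol, DH_FUS_ICE, integrate_endotherm
from hydromp.ftir import fit_oh_band
from hydromp.hydration import hydration_number, water_volume_fraction
from hydromp.synth import (GroundTruth, bsa13, cd_basis_curves, gen_cd_series,
                           gen_dsc_cycles, gen_oh_band,
                           gen_solution_dielectric, gen_water_dielectric,
                           solution_delta_eps1)


class TestDeterminism:
    def test_same_seed_same_output(self, truth):
        for gen in (lambda s: gen_water_dielectric(25.0, noise=0.01, seed=s).eps_imag,
                    lambda s: gen_solution_dielectric(25.0, truth, seed=s).eps_imag,
                    lambda s: gen_dsc_cycles(truth, seed=s)[1].heat_flow,
                    lambda s: gen_oh_band(np.array([0.8, 0.15, 0.05]),
                                          seed=s).absorbance,
                    lambda s: gen_cd_series(truth, seed=s)[0].ellipticity):
            assert np.array_equal(gen(11), gen(11))
            assert not np.array_equal(gen(11), gen(12))


class TestWaterGenerator:
    def test_zero_noise_equals_model(self):
        grid = FrequencyGrid(np.linspace(0.3, 2.5, 20))
        spec = gen_water_dielectric(40.0, grid=grid, noise=0.0)
        model = eval_model(water_parameters(40.0), grid)
        assert np.array_equal(spec.eps_imag, model.eps_imag)
        assert np.array_equal(spec.eps_real, model.eps_real)

    def test_temperature_out_of_table_rejected(self):
        with pytest.raises(ValueError):
            gen_water_dielectric(10.0)

    def test_slow_strength_decreases_with_temperature(self):
        vals = [water_parameters(t).delta_eps1 for t in np.arange(25, 56, 5)]
        assert np.all(np.diff(vals) < 0)


class TestSolutionGenerator:
    def test_zero_hydration_is_scaled_water(self, truth):
        """With n = 0 and the water fast strength, the solution spectrum is
        the c-scaled water susceptibility plus the offset."""
        t0 = GroundTruth(
            temperatures=np.array([25.0]), n_hyd_true=np.array([0.0]),
            n_unfreezable_true=np.array([0.0]),
            oh_fractions_true=np.array([[0.8, 0.15, 0.05]]),
            helix_series_true=truth.helix_series_true,
            composition=truth.composition)
        grid = FrequencyGrid(np.linspace(0.3, 2.5, 15))
        pw = water_parameters(25.0)
        sol = gen_solution_dielectric(25.0, t0, grid=grid, noise=0.0,
                                      delta_eps2_sol=pw.delta_eps2)
        wat = eval_model(pw, grid)
        c = water_volume_fraction(truth.composition, 25.0)
        assert np.allclose(sol.eps_imag, c * wat.eps_imag, rtol=1e-12)
        assert np.allclose(sol.eps_real - pw.eps_inf,
                           c * (wat.eps_real - pw.eps_inf), rtol=1e-12)

    def test_noiseless_pipeline_identity(self, truth, water25):
        """analysis(generation(n)) = n at machine precision, zero noise."""
        c = water_volume_fraction(truth.composition, 25.0)
        w = gen_water_dielectric(25.0, noise=0.0)
        s = gen_solution_dielectric(25.0, truth, noise=0.0)
        est = hydration_number(fit_pure_water(w, water25),
                               fit_solution(s, c, water25), truth.alpha, c)
        assert est.n_hyd == pytest.approx(truth.n_hyd_at(25.0), rel=1e-6)

    def test_unencodable_hydration_rejected(self, truth):
        bad = GroundTruth(
            temperatures=np.array([25.0]),
            n_hyd_true=np.array([24000.0]),  # implies negative slow strength
            n_unfreezable_true=np.array([0.0]),
            oh_fractions_true=np.array([[0.8, 0.15, 0.05]]),
            helix_series_true=truth.helix_series_true,
            composition=truth.composition)
        with pytest.raises(ValueError, match="not encodable"):
            solution_delta_eps1(bad, 25.0)

    def test_step_in_truth_reproduced(self, truth):
        """The scenario's upward jump at 60 degC appears in the encoded
        slow-relaxation strengths (lower strength = more hydration)."""
        de55 = solution_delta_eps1(truth, 55.0)
        de60 = solution_delta_eps1(truth, 60.0)
        # higher n at 60 -> lower solution strength relative to its own water
        s55 = de55 / water_parameters(55.0).delta_eps1
        s60 = de60 / water_parameters(60.0).delta_eps1
        assert s60 < s55


class TestDSCGenerator:
    def test_melt_area_closed_form_zero_noise(self, truth):
        cycles = gen_dsc_cycles(truth, CycleProtocol.default(T0=75.0),
                                seed=0, noise=0.0)
        heat1 = [t for t in cycles if t.direction == "heating"][0]
        melt = integrate_endotherm(heat1, (-10.0, 10.0))
        m_water = 10e-3 * (1 - truth.composition.solute_wt_fraction)
        expect = DH_FUS_ICE * m_water * (1.0 - 2000.0 / truth.alpha)
        assert melt.enthalpy == pytest.approx(expect, rel=1e-9)

    def test_constant_truth_unity_ratio(self, truth):
        t0 = GroundTruth(
            temperatures=truth.temperatures,
            n_hyd_true=truth.n_hyd_true,
            n_unfreezable_true=np.full_like(truth.temperatures, 2000.0),
            oh_fractions_true=truth.oh_fractions_true,
            helix_series_true=truth.helix_series_true,
            composition=truth.composition)
        cycles = gen_dsc_cycles(t0, CycleProtocol.default(T0=75.0), seed=4)
        heats = [t for t in cycles if t.direction == "heating"]
        h1 = integrate_endotherm(heats[0], (-8.0, 8.0)).enthalpy
        h2 = integrate_endotherm(heats[1], (-8.0, 8.0)).enthalpy
        assert h2 / h1 == pytest.approx(1.0, abs=0.02)


class TestOHGenerator:
    def test_noiseless_round_trip(self):
        spec = gen_oh_band(np.array([0.7, 0.2, 0.1]), noise=0.0)
        _, fr = fit_oh_band(spec)
        assert np.allclose(fr.as_tuple(), (0.7, 0.2, 0.1), atol=1e-6)

    def test_default_scenario_is_pure_water_decomposition(self, truth):
        assert np.allclose(truth.oh_fractions_at(25.0), (0.80, 0.15, 0.05))

    def test_total_area_conserved_across_fractions(self):
        x = np.arange(2800.0, 3801.0, 2.0)
        areas = []
        for fr in ([0.8, 0.15, 0.05], [0.5, 0.3, 0.2]):
            spec = gen_oh_band(np.array(fr), noise=0.0)
            base = 0.05 + 2e-5 * (spec.wavenumber - 3400.0)
            areas.append(np.trapezoid(spec.absorbance - base, spec.wavenumber))
        assert areas[0] == pytest.approx(areas[1], rel=1e-3)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            gen_oh_band(np.array([0.9, 0.2, -0.1]))
        with pytest.raises(ValueError):
            gen_oh_band(np.array([0.5, 0.3, 0.1]))


class TestCDGenerator:
    def test_basis_pinned_at_222(self):
        wl = np.arange(190.0, 251.0, 1.0)
        from hydromp.cd import HelixConstants
        h, c = cd_basis_curves(wl, HelixConstants())
        i = np.argmin(np.abs(wl - 222.0))
        assert h[i] == pytest.approx(-32640.0, rel=1e-12)
        assert c[i] == pytest.approx(-2340.0, rel=1e-12)

    def test_default_truth_plateaus(self, truth):
        f_nat, f_den, t_mid, _ = truth.helix_series_true
        assert (f_nat, f_den, t_mid) == (0.66, 0.16, 59.0)
        assert truth.helix_fraction_at(25.0) == f_nat
        assert truth.helix_fraction_at(85.0) == f_den

    def test_recovered_fraction_calibrated_across_seeds(self, truth):
        """f_H recovered at 50 degC is within 3 standard errors of truth
        over 100 seeds at the default noise."""
        from hydromp.cd import helix_series_from_spectra
        vals = []
        for seed in range(100):
            spec = gen_cd_series(truth, seed=seed,
                                 temperatures=np.array([50.0]))[0]
            vals.append(helix_series_from_spectra([spec]).f_H[0])
        f_true = truth.helix_fraction_at(50.0)
        se = np.std(vals) / 10.0
        assert abs(np.mean(vals) - f_true) < 3.0 * se + 1e-4

    def test_grid_must_contain_222(self, truth):
        with pytest.raises(ValueError, match="222"):
            gen_cd_series(truth, wavelength=np.arange(190.5, 250.0, 1.0))


class TestGroundTruthValidation:
    def test_physical_bounds_enforced(self, truth):
        with pytest.raises(ValueError, match="alpha"):
            GroundTruth(
                temperatures=np.array([25.0]),
                n_hyd_true=np.array([1e6]),
                n_unfreezable_true=np.array([0.0]),
                oh_fractions_true=np.array([[0.8, 0.15, 0.05]]),
                helix_series_true=truth.helix_series_true,
                composition=truth.composition)
        with pytest.raises(ValueError, match="sum to 1"):
            GroundTruth(
                temperatures=np.array([25.0]),
                n_hyd_true=np.array([3300.0]),
                n_unfreezable_true=np.array([2000.0]),
                oh_fractions_true=np.array([[0.8, 0.3, 0.05]]),
                helix_series_true=truth.helix_series_true,
                composition=truth.composition)

    def test_off_grid_temperature_rejected(self, truth):
        with pytest.raises(ValueError, match="grid"):
            truth.n_hyd_at(26.0)
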