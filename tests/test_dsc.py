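"""DSC endotherm integration, unfreezable water, and peak detection."""

import numpy as np
import pytest

from hydromp.dsc import (CycleProtocol, DH_FUS_ICE, Thermogram,
                         detect_denaturation_peak, enthalpy_ratio,
                         has_anomaly_below_zero, integrate_endotherm,
                         unfreezable_water)
from hydromp.hydration import SolutionComposition, total_water_per_solute
from hydromp.synth import gen_dsc_cycles


def _gaussian_trace(area_j, center=0.0, sd=1.5, baseline=(0.2, 0.01),
                    t_range=(-20.0, 20.0), dT=0.05, ramp=2.0):
    T = np.arange(t_range[0], t_range[1] + dT / 2, dT)
    rate_per_s = ramp / 60.0
    hf = (baseline[0] + baseline[1] * T
          + area_j * rate_per_s * 1e3
          * np.exp(-0.5 * ((T - center) / sd) ** 2) / (sd * np.sqrt(2 * np.pi)))
    return Thermogram(T, hf, ramp, "heating")


class TestIntegration:
    def test_flat_trace_zero_enthalpy(self):
        T = np.arange(-20.0, 20.0, 0.1)
        tg = Thermogram(T, np.full_like(T, 0.3), 2.0, "heating")
        peak = integrate_endotherm(tg, (-10.0, 10.0))
        assert peak.enthalpy == pytest.approx(0.0, abs=1e-12)

    def test_known_area_on_sloped_baseline(self):
        tg = _gaussian_trace(2.5)
        peak = integrate_endotherm(tg, (-10.0, 10.0))
        assert peak.enthalpy == pytest.approx(2.5, rel=0.005)
        assert peak.T_peak == pytest.approx(0.0, abs=0.2)

    def test_additivity_of_disjoint_windows(self):
        """Splitting at a quiet point, the sub-integrals sum to the whole."""
        tg = _gaussian_trace(2.5, center=0.0, sd=1.0, t_range=(-15.0, 25.0))
        full = integrate_endotherm(tg, (-10.0, 20.0)).enthalpy
        left = integrate_endotherm(tg, (-10.0, 12.0)).enthalpy
        right = integrate_endotherm(tg, (12.0, 20.0)).enthalpy
        assert left + right == pytest.approx(full, abs=1e-9)

    def test_cooling_trace_rejected(self):
        T = np.arange(20.0, -20.0, -0.1)
        tg = Thermogram(T, np.zeros_like(T), 2.0, "cooling")
        with pytest.raises(ValueError, match="heating"):
            integrate_endotherm(tg, (-10.0, 10.0))

    def test_anchor_on_peak_warns(self):
        tg = _gaussian_trace(2.5, sd=4.0)
        with pytest.warns(UserWarning, match="baseline"):
            integrate_endotherm(tg, (-4.0, 4.0))

    def test_resampling_invariance(self):
        a = integrate_endotherm(_gaussian_trace(2.5, dT=0.1), (-10, 10)).enthalpy
        b = integrate_endotherm(_gaussian_trace(2.5, dT=0.05), (-10, 10)).enthalpy
        assert b == pytest.approx(a, rel=1e-3)


class TestUnfreezable:
    comp = SolutionComposition(0.13, 66000.0)

    def _melt(self, enthalpy):
        return integrate_endotherm(_gaussian_trace(enthalpy), (-10.0, 10.0))

    def test_all_water_freezes(self):
        m_water = 10e-3 * 0.87
        n, clamped = unfreezable_water(self._melt(m_water * DH_FUS_ICE),
                                       self.comp, 10.0)
        assert n == pytest.approx(0.0, abs=2.0)

    def test_nothing_freezes(self):
        n, _ = unfreezable_water(self._melt(0.0), self.comp, 10.0)
        alpha = total_water_per_solute(self.comp)
        assert n == pytest.approx(alpha, rel=1e-3)

    def test_closed_form_generator_arithmetic(self):
        """10 mg of 13 wt % solution, 2000 unfreezable waters per solute."""
        alpha = total_water_per_solute(self.comp)
        enthalpy = DH_FUS_ICE * 0.0087 * (1.0 - 2000.0 / alpha)
        n, _ = unfreezable_water(self._melt(enthalpy), self.comp, 10.0)
        assert n == pytest.approx(2000.0, rel=0.01)

    def test_affine_decreasing_in_enthalpy(self):
        ns = [unfreezable_water(self._melt(h), self.comp, 10.0)[0]
              for h in (0.5, 1.0, 1.5, 2.0)]
        diffs = np.diff(ns)
        assert np.all(diffs < 0)
        assert np.allclose(diffs, diffs[0], rtol=1e-6)

    def test_overfull_enthalpy_rejected(self):
        m_water = 10e-3 * 0.87
        with pytest.raises(ValueError, match="calibration"):
            unfreezable_water(self._melt(1.05 * m_water * DH_FUS_ICE),
                              self.comp, 10.0)

    def test_round_trip_recovery_at_default_noise(self, truth):
        """Generated cycles analyzed back to the truth within 2 %."""
        ns = []
        for seed in range(30):
            cycles = gen_dsc_cycles(truth, CycleProtocol.default(T0=75.0),
                                    seed=seed)
            heat1 = [t for t in cycles if t.direction == "heating"][0]
            melt = integrate_endotherm(heat1, (-8.0, 8.0))
            n, _ = unfreezable_water(melt, truth.composition,
                                     heat1.sample_mass)
            ns.append(n)
        assert np.mean(ns) == pytest.approx(2000.0, rel=0.02)


class TestRatio:
    def _melt(self, enthalpy):
        return integrate_endotherm(_gaussian_trace(enthalpy), (-10.0, 10.0))

    def test_identical_gives_unity(self):
        r = enthalpy_ratio(self._melt(2.0), self._melt(2.0))
        assert r.second_over_first == pytest.approx(1.0, rel=1e-6)
        assert r.first_over_second == pytest.approx(1.0, rel=1e-6)

    def test_both_orientations(self):
        r = enthalpy_ratio(self._melt(2.0), self._melt(2.2))
        assert r.second_over_first == pytest.approx(1.1, rel=1e-3)
        assert r.first_over_second == pytest.approx(1 / 1.1, rel=1e-3)

    def test_imposed_post_denaturation_ratio(self, truth):
        """A measured 0.92 second/first melt ratio can be emulated directly."""
        cycles = gen_dsc_cycles(truth, CycleProtocol.default(T0=75.0),
                                seed=0, second_melt_scale=0.92)
        heats = [t for t in cycles if t.direction == "heating"]
        m1 = integrate_endotherm(heats[0], (-8.0, 8.0))
        m2 = integrate_endotherm(heats[1], (-8.0, 8.0))
        assert enthalpy_ratio(m1, m2).second_over_first == pytest.approx(
            0.92, abs=0.02)

    def test_zero_denominator_rejected(self):
        flat = integrate_endotherm(
            Thermogram(np.arange(-20, 20, 0.1),
                       np.zeros(400), 2.0, "heating"), (-10, 10))
        with pytest.raises(ZeroDivisionError):
            enthalpy_ratio(flat, self._melt(2.0))


class TestDenaturationPeak:
    def test_broad_endotherm_located(self, truth):
        """Peak of the synthetic denaturation endotherm found near 61 degC."""
        peaks = []
        for seed in range(10):
            cycles = gen_dsc_cycles(
                truth, CycleProtocol.default(T0=85.0, room=25.0), seed=seed)
            heat1 = [t for t in cycles if t.direction == "heating"][0]
            pk = detect_denaturation_peak(heat1, (40.0, 85.0))
            assert pk is not None
            peaks.append(pk.T_peak)
        assert np.mean(peaks) == pytest.approx(61.0, abs=0.5)

    def test_flat_trace_is_no_transition(self, rng):
        T = np.arange(25.0, 85.0, 0.1)
        hf = 0.005 * rng.standard_normal(len(T))
        tg = Thermogram(T, hf, 2.0, "heating")
        assert detect_denaturation_peak(tg, (40.0, 80.0)) is None

    def test_irreversibility_across_cycles(self, truth):
        """Endotherm present in the first heating, absent in the second."""
        cycles = gen_dsc_cycles(truth,
                                CycleProtocol.default(T0=85.0, room=25.0),
                                seed=7)
        heats = [t for t in cycles if t.direction == "heating"]
        assert detect_denaturation_peak(heats[0], (40.0, 85.0)) is not None
        assert detect_denaturation_peak(heats[1], (40.0, 85.0)) is None

    def test_no_intermediate_water_anomaly(self, truth):
        """Default cycles show no anomaly between -75 and 0 degC (besides
        the melt onset region excluded by the screen's upper bound)."""
        cycles = gen_dsc_cycles(truth, CycleProtocol.default(T0=75.0), seed=1)
        heat1 = [t for t in cycles if t.direction == "heating"][0]
        assert not has_anomaly_below_zero(heat1, (-24.0, -5.0))


def test_protocol_validation():
    with pytest.raises(ValueError, match="alternate"):
        CycleProtocol(steps=(("cooling", 20.0, -25.0), ("cooling", -25.0, -30.0)))
    with pytest.raises(ValueError, match="increase"):
        CycleProtocol(steps=(("heating", 20.0, -25.0),))
    proto = CycleProtocol.default(T0=60.0)
    assert proto.steps[1] == ("heating", -25.0, 60.0)
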