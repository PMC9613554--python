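import math

import numpy as np
import pytest

from alkaquant.chromatogram import Chromatogram
from alkaquant.peaks import (Peak, TraceError, detect_peak, estimate_baseline,
                             integrate_window, resolution, signal_to_noise,
                             tailing_factor)
from alkaquant.simulate import (MatrixRecoveryModel, emg_profile,
                                simulate_injection)


def _trace(panel, y, center=15.1, half=1.0):
    t = np.linspace(center - half, center + half, len(y))
    return Chromatogram(panel.quantifier("At"), t, y)


def _peak(**kwargs):
    defaults = dict(apex_rt=10.0, area=100.0, height=300.0, baseline_level=0.0,
                    noise_sd=10.0, w_base=0.2, w_5pct=0.15, front_5pct=0.075,
                    snr=30.0)
    defaults.update(kwargs)
    return Peak(**defaults)


class TestBaseline:
    def test_flat_trace(self, panel):
        tr = _trace(panel, np.full(361, 100.0))
        assert estimate_baseline(tr, 15.1) == (100.0, 0.0)

    def test_robust_to_peak_in_exclusion_zone(self, panel):
        y = np.full(361, 100.0)
        y[180] = 1e6
        tr = _trace(panel, y)
        assert estimate_baseline(tr, 15.1) == (100.0, 0.0)

    def test_recovers_gaussian_noise_sd(self, panel, rng):
        y = 1000.0 + rng.normal(0, 5.0, 361)
        tr = _trace(panel, y)
        level, noise = estimate_baseline(tr, 15.1)
        assert level == pytest.approx(1000.0, abs=2.0)
        assert noise == pytest.approx(5.0, abs=1.0)

    def test_exclusion_zone_covering_trace_rejected(self, panel):
        tr = _trace(panel, np.full(361, 1.0))
        with pytest.raises(TraceError):
            estimate_baseline(tr, 15.1, exclude_halfwidth=5.0)


class TestDetectPeak:
    @pytest.mark.parametrize("tau", [0.0, 0.018, 0.05])
    def test_noiseless_area_recovered(self, panel, tau):
        t = np.linspace(14.1, 16.1, 361)
        y = emg_profile(t, 15.1, 0.03, tau, 5000.0)
        p = detect_peak(Chromatogram(panel.quantifier("At"), t, y), 15.1)
        assert p.area == pytest.approx(5000.0, rel=0.01)
        # the EMG mode sits at most O(tau) to the right of the Gaussian centre
        assert 15.1 - 0.01 <= p.apex_rt <= 15.1 + 2 * tau + 0.01

    def test_blank_returns_none(self, panel, rng):
        y = 1000.0 + rng.normal(0, 50.0, 361)
        assert detect_peak(_trace(panel, y), 15.1) is None

    def test_acceptance_threshold_three_sigma(self, panel, rng):
        noise = rng.normal(0, 50.0, 361)
        t = np.linspace(14.1, 16.1, 361)
        small = emg_profile(t, 15.1, 0.03, 0.0, 1.0)  # height ~13 << 3 sigma
        tr = Chromatogram(panel.quantifier("At"), t, 1000 + noise + small)
        assert detect_peak(tr, 15.1) is None

    @pytest.mark.parametrize("target_first", [True, False])
    def test_doublet_apex_assigned_to_nearest(self, panel, target_first):
        """Isomers sharing a transition are disambiguated by retention time."""
        t = np.linspace(14.1, 16.1, 361)
        y = (emg_profile(t, 15.0, 0.03, 0.0, 1000.0)
             + emg_profile(t, 15.2, 0.03, 0.0, 1500.0))
        tr = Chromatogram(panel.quantifier("At"), t, y)
        expected = 15.0 if target_first else 15.2
        p = detect_peak(tr, expected)
        assert p.apex_rt == pytest.approx(expected, abs=0.02)

    def test_area_linear_in_concentration(self, small_panel, clean_model):
        """Noiseless 7-level series: detected area vs conc has R^2 > 0.999."""
        levels = [0.1, 0.5, 1.25, 2.5, 5.0, 10.0, 15.0]
        areas = []
        for i, c in enumerate(levels):
            inj = simulate_injection(small_panel, {"At": c / 2.727272727},
                                     clean_model, seed=i)
            areas.append(detect_peak(inj.trace("At"), 15.1).area)
        r = np.corrcoef(levels, areas)[0, 1]
        assert r ** 2 > 0.999


class TestForcedIntegration:
    def test_matches_trapezoid_on_noiseless_peak(self, panel):
        t = np.linspace(14.1, 16.1, 361)
        y = 500.0 + emg_profile(t, 15.1, 0.03, 0.018, 5000.0)
        tr = Chromatogram(panel.quantifier("At"), t, y)
        assert integrate_window(tr, 15.1) == pytest.approx(5000.0, rel=0.01)

    def test_blank_areas_are_zero_mean(self, panel, rng):
        areas = []
        for _ in range(200):
            y = 1000.0 + rng.normal(0, 50.0, 361)
            areas.append(integrate_window(_trace(panel, y), 15.1))
        # sd of the forced blank area ~ noise * sqrt(n_window) * dt ~ 2.1
        assert abs(np.mean(areas)) < 0.5
        assert np.std(areas) == pytest.approx(2.1, rel=0.4)


class TestResolution:
    def test_coeluting_peaks_give_zero(self):
        p = _peak()
        assert resolution(p, _peak()) == 0.0

    def test_hand_arithmetic(self):
        # RT 11.2/11.4 min with both baseline widths 0.2 min
        p1 = _peak(apex_rt=11.2, w_base=0.2)
        p2 = _peak(apex_rt=11.4, w_base=0.2)
        assert resolution(p1, p2) == pytest.approx(1.0)
        # widths 0.1/0.3 and separation 0.3 -> the printed final-method 1.5
        p3 = _peak(apex_rt=11.2, w_base=0.1)
        p4 = _peak(apex_rt=11.5, w_base=0.3)
        assert resolution(p3, p4) == pytest.approx(1.5)

    def test_symmetric_in_argument_order(self):
        p1 = _peak(apex_rt=11.2, w_base=0.15)
        p2 = _peak(apex_rt=11.5, w_base=0.25)
        assert resolution(p1, p2) == resolution(p2, p1)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            resolution(_peak(w_base=0.0), _peak(w_base=0.0))

    def test_gaussian_closed_form_agreement(self, panel):
        """For equal-sigma Gaussians the measured-width resolution agrees
        with delta_rt / (4 sigma) scaled by the measured/4-sigma width."""
        t = np.linspace(14.1, 16.1, 721)
        sigma = 0.04
        pa = detect_peak(Chromatogram(
            panel.quantifier("At"), t,
            emg_profile(t, 14.9, sigma, 0.0, 1000.0)), 14.9)
        pb = detect_peak(Chromatogram(
            panel.quantifier("At"), t,
            emg_profile(t, 15.3, sigma, 0.0, 1000.0)), 15.3)
        measured = resolution(pa, pb)
        closed_form = (15.3 - 14.9) / (4 * sigma) * (4 * sigma / pa.w_base)
        assert measured == pytest.approx(closed_form, rel=0.05)


class TestTailingFactor:
    def test_symmetric_peak(self):
        assert tailing_factor(_peak(w_5pct=0.15, front_5pct=0.075)) == 1.0

    @pytest.mark.parametrize("w_x, f, expected", [
        (0.2, 0.0625, 1.6),   # acidic-condition atropine
        (0.22, 0.05, 2.2),    # alkaline 150-mm column atropine
    ])
    def test_hand_arithmetic(self, w_x, f, expected):
        assert tailing_factor(_peak(w_5pct=w_x, front_5pct=f)) == pytest.approx(
            expected)

    def test_degenerate_front_rejected(self):
        with pytest.raises(ValueError):
            tailing_factor(_peak(front_5pct=0.0))

    def test_invariant_under_scaling_and_translation(self, panel):
        t = np.linspace(14.1, 16.1, 361)
        y = emg_profile(t, 15.1, 0.03, 0.04, 1000.0)
        base = tailing_factor(detect_peak(
            Chromatogram(panel.quantifier("At"), t, y), 15.1))
        scaled = tailing_factor(detect_peak(
            Chromatogram(panel.quantifier("At"), t, 7.3 * y), 15.1))
        shifted = tailing_factor(detect_peak(
            Chromatogram(panel.quantifier("At"), t + 0.4, y), 15.5))
        assert scaled == pytest.approx(base, rel=1e-6)
        assert shifted == pytest.approx(base, rel=1e-3)


class TestSignalToNoise:
    def test_plain_ratio(self):
        assert signal_to_noise(_peak(height=300.0, noise_sd=10.0)) == 30.0

    def test_noiseless_sentinel(self):
        assert signal_to_noise(_peak(noise_sd=0.0)) == math.inf

    def test_response_boost_scales_snr(self, small_panel):
        """A 3.3-fold response gain yields a 3.3-fold S/N at fixed noise,
        as observed when switching to alkaline solvent conditions."""
        def snr_at(response):
            model = MatrixRecoveryModel(recovery=1.0, suppression=0.0,
                                        response_factor=response,
                                        noise_sd=300.0)
            snrs = []
            for seed in range(8):
                inj = simulate_injection(small_panel, {"At": 5.0 / 2.727},
                                         model, seed=seed)
                p = detect_peak(inj.trace("At"), 15.1)
                snrs.append(p.snr)
            return np.mean(snrs)

        ratio = snr_at(3.3e3) / snr_at(1.0e3)
        assert ratio == pytest.approx(3.3, rel=0.10)
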