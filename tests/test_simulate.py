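import numpy as np
import pytest

from alkaquant.chromatogram import Chromatogram
from alkaquant.peaks import detect_peak, tailing_factor
from alkaquant.simulate import (MatrixRecoveryModel, emg_profile,
                                generate_calibration_batch,
                                generate_limits_series,
                                generate_spike_experiment, simulate_injection)

DT = 1.0 / 180.0  # sampling step, minutes (3 points per second)


def _grid(center=15.1, half=1.0):
    return np.linspace(center - half, center + half, 361)


class TestEmgProfile:
    @pytest.mark.parametrize("sigma, tau", [
        (0.02, 0.0), (0.03, 0.0), (0.03, 0.018), (0.03, 0.05),
        (0.05, 0.1), (2 * DT, 0.02),
    ])
    def test_area_conservation(self, sigma, tau):
        t = _grid()
        y = emg_profile(t, 15.1, sigma, tau, 1234.5)
        assert np.trapezoid(y, t) == pytest.approx(1234.5, rel=0.01)

    def test_zero_area_gives_flat_profile(self):
        assert not emg_profile(_grid(), 15.1, 0.03, 0.02, 0.0).any()

    def test_gaussian_limit_is_symmetric(self, panel):
        t = _grid()
        y = emg_profile(t, 15.1, 0.03, 0.0, 1000.0)
        tr = Chromatogram(panel.quantifier("At"), t, y)
        assert tailing_factor(detect_peak(tr, 15.1)) == pytest.approx(1.0,
                                                                      abs=0.02)

    def test_tau_by_bisection_reaches_final_method_tailing(self, panel):
        """A tail constant exists for which the measured T equals the 1.5
        observed for atropine on the final column; found by bisection."""
        t = _grid()

        def measured_t(tau):
            y = emg_profile(t, 15.1, 0.03, tau, 27270.0)
            tr = Chromatogram(panel.quantifier("At"), t, y)
            return tailing_factor(detect_peak(tr, 15.1))

        lo, hi = 0.0, 0.2
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if measured_t(mid) < 1.5:
                lo = mid
            else:
                hi = mid
        tau = 0.5 * (lo + hi)
        assert tau > 0
        assert measured_t(tau) == pytest.approx(1.5, abs=0.02)

    @pytest.mark.parametrize("bad", [
        {"sigma": 0.0}, {"sigma": -1.0}, {"tau": -0.1}, {"area": -5.0},
        {"apex_rt": float("nan")},
    ])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = {"apex_rt": 15.1, "sigma": 0.03, "tau": 0.0, "area": 1.0}
        kwargs.update(bad)
        with pytest.raises(ValueError):
            emg_profile(_grid(), **kwargs)


class TestSimulateInjection:
    def test_blank_noiseless_is_flat(self, small_panel, unit_model):
        inj = simulate_injection(small_panel, {}, unit_model, seed=0)
        for tr in inj.traces.values():
            assert not tr.intensities.any()

    def test_quantifier_area_follows_prep_factor(self, small_panel, unit_model):
        """1 ug/L milk -> 2.727 ng/mL extract -> area 2.727 at unit response."""
        inj = simulate_injection(small_panel, {"At": 1.0}, unit_model,
                                 in_matrix=False, seed=0)
        tr = inj.trace("At")
        assert np.trapezoid(tr.intensities, tr.times) == pytest.approx(
            2.727, rel=0.01)

    def test_ion_ratio_by_construction(self, small_panel, unit_model):
        inj = simulate_injection(small_panel, {"At": 1.0}, unit_model, seed=0)
        qn = inj.trace("At", "quantifier")
        ql = inj.trace("At", "qualifier")
        ratio = (np.trapezoid(ql.intensities, ql.times)
                 / np.trapezoid(qn.intensities, qn.times))
        assert ratio == pytest.approx(small_panel.ion_ratio("At"), rel=0.01)

    def test_doubling_concentration_doubles_area(self, small_panel, unit_model):
        one = simulate_injection(small_panel, {"Ec": 1.0}, unit_model, seed=0)
        two = simulate_injection(small_panel, {"Ec": 2.0}, unit_model, seed=0)
        np.testing.assert_allclose(two.trace("Ec").intensities,
                                   2 * one.trace("Ec").intensities)

    def test_suppression_and_recovery_scale_area(self, small_panel):
        model = MatrixRecoveryModel(recovery=0.9, suppression=0.4,
                                    response_factor=1.0, noise_sd=0.0,
                                    baseline_level=0.0)
        inj = simulate_injection(small_panel, {"At": 1.0}, model,
                                 in_matrix=True, seed=0)
        tr = inj.trace("At")
        assert np.trapezoid(tr.intensities, tr.times) == pytest.approx(
            2.727 * 0.9 * 0.6, rel=0.01)

    def test_determinism(self, small_panel):
        model = MatrixRecoveryModel.default()
        a = simulate_injection(small_panel, {"At": 0.5}, model, seed=42)
        b = simulate_injection(small_panel, {"At": 0.5}, model, seed=42)
        c = simulate_injection(small_panel, {"At": 0.5}, model, seed=43)
        for key in a.traces:
            np.testing.assert_array_equal(a.traces[key].intensities,
                                          b.traces[key].intensities)
        assert (a.trace("At").intensities != c.trace("At").intensities).any()

    def test_unknown_analyte_rejected(self, small_panel, unit_model):
        with pytest.raises(ValueError, match="not in panel"):
            simulate_injection(small_panel, {"Xx": 1.0}, unit_model, seed=0)

    def test_negative_concentration_rejected(self, small_panel, unit_model):
        with pytest.raises(ValueError, match="negative"):
            simulate_injection(small_panel, {"At": -1.0}, unit_model, seed=0)

    def test_window_covers_expected_rt(self, small_panel, unit_model):
        inj = simulate_injection(small_panel, {}, unit_model, seed=0)
        for (aid, _), tr in inj.traces.items():
            assert tr.covers(small_panel.expected_rt(aid))
            assert tr.times[-1] - tr.times[0] == pytest.approx(2.0)


class TestBatchGenerators:
    def test_calibration_batch_default_levels(self, small_panel, clean_model):
        batch = generate_calibration_batch(small_panel, model=clean_model,
                                           seed=1)
        assert len(batch) == 7
        levels = [e["level_ng_mL"] for e in batch.manifest["injections"]]
        assert levels == [0.0, 0.1, 0.5, 1.25, 2.5, 5.0, 10.0]

    def test_zero_level_is_blank(self, small_panel, clean_model):
        batch = generate_calibration_batch(small_panel, model=clean_model,
                                           seed=1)
        blank = batch.injections[0]
        assert not blank.trace("At").intensities.any()

    def test_same_seed_identical_batches(self, small_panel):
        model = MatrixRecoveryModel.default()
        a = generate_calibration_batch(small_panel, model=model, seed=5)
        b = generate_calibration_batch(small_panel, model=model, seed=5)
        assert a.manifest == b.manifest
        for ia, ib in zip(a.injections, b.injections):
            for key in ia.traces:
                np.testing.assert_array_equal(ia.traces[key].intensities,
                                              ib.traces[key].intensities)

    def test_too_few_nonzero_levels_rejected(self, small_panel, clean_model):
        with pytest.raises(ValueError, match="3 distinct nonzero"):
            generate_calibration_batch(small_panel, [0.0, 1.0, 2.0],
                                       model=clean_model, seed=1)

    def test_limit_grids_equidistant_with_exact_endpoints(self, small_panel,
                                                          clean_model):
        batch = generate_limits_series(small_panel, model=clean_model, seed=1)
        low = np.array(batch.manifest["low_grid_ng_mL"])
        high = np.array(batch.manifest["high_grid_ng_mL"])
        np.testing.assert_allclose(np.diff(low), 0.01)
        np.testing.assert_allclose(np.diff(high), 0.1)
        assert (low[0], low[-1]) == (0.01, 0.12) and len(low) == 12
        assert (high[0], high[-1]) == (0.2, 1.2) and len(high) == 11

    def test_spike_experiment_design(self, small_panel):
        model = MatrixRecoveryModel.default()
        batch = generate_spike_experiment(small_panel, model=model, seed=1)
        assert len(batch) == 15  # 3 levels x 5 replicates
        entries = batch.manifest["injections"]
        lowest = [e for e in entries if e["level_ugL"] == 0.05]
        assert len(lowest) == 5
        # replicate noise realisations differ
        reps = [inj for inj in batch.injections
                if inj.injection_id.startswith("spike_0.05")]
        assert (reps[0].trace("At").intensities
                != reps[1].trace("At").intensities).any()

    def test_spike_flags_levels_below_loq(self, panel):
        model = MatrixRecoveryModel.default()
        batch = generate_spike_experiment(panel.subset(["Jl", "At"]),
                                          model=model, seed=1)
        entry = next(e for e in batch.manifest["injections"]
                     if e["level_ugL"] == 0.05)
        # jacoline's LOQ (0.056 ug/L) exceeds the lowest spike level
        assert "Jl" in entry["below_loq_analytes"]
        assert "At" not in entry["below_loq_analytes"]
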