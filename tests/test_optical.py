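"""ROI extraction, normalization, optical kinetic fits, QC checks."""

import numpy as np
import pytest

from synaptoquant import optical as opt
from synaptoquant import synthetic as syn
from synaptoquant.core import ImageStack, ROITimeSeries, StimProtocol


def stim10():
    return StimProtocol(n_stimuli=50, frequency=10.0, onset=8.0)


class TestROIExtraction:
    def test_uniform_frames(self):
        ft = np.arange(0, 10, 0.5)
        stack = ImageStack(frames=np.full((len(ft), 16, 16), 100.0), frame_times=ft)
        series = opt.extract_roi_timeseries(stack, opt.ROISet(rois=[(8, 8)]))
        assert np.all(series[0].F == 100.0)

    def test_out_of_bounds_roi(self):
        ft = np.arange(0, 10, 0.5)
        stack = ImageStack(frames=np.zeros((len(ft), 16, 16)), frame_times=ft)
        with pytest.raises(ValueError):
            opt.extract_roi_timeseries(stack, opt.ROISet(rois=[(1, 8)]))

    def test_gaussian_bouton_tracks_timecourse(self):
        ft = np.arange(0, 20, 0.5)
        tc = np.where(ft >= 8.0, 40.0 * np.exp(-(ft - 8.0) / 5.0), 0.0)
        stack = syn.simulate_bouton_stack((32, 32), [(16, 16)], [tc], ft,
                                          noise_sd=0.5, seed=4)
        s = opt.extract_roi_timeseries(stack, opt.ROISet(rois=[(16, 16)]),
                                       stim=stim10())[0]
        r = np.corrcoef(s.F - s.F0, tc)[0, 1]
        assert r > 0.99

    def test_background_subtraction(self):
        ft = np.arange(0, 10, 0.5)
        frames = np.full((len(ft), 16, 16), 100.0) + np.arange(len(ft))[:, None, None]
        stack = ImageStack(frames=frames, frame_times=ft)
        bg = np.zeros((16, 16), bool)
        bg[0:4, 0:4] = True
        s = opt.extract_roi_timeseries(stack, opt.ROISet(rois=[(8, 8)]),
                                       background_roi=bg)[0]
        assert np.allclose(s.F, 0.0)


class TestIGluSnFRROIs:
    def test_blob_area_rule(self):
        ft = np.arange(0, 20, 0.5)
        m20 = np.zeros((64, 64), bool); m20[10:14, 10:15] = True
        m5 = np.zeros((64, 64), bool); m5[40:45, 40] = True
        stack = syn.simulate_response_stack((64, 64), [(m20, 30.0), (m5, 30.0)],
                                            ft, stim10(), noise_sd=1.0, seed=1)
        rois = opt.detect_iglusnfr_rois(stack, stim10())
        assert len(rois) == 1
        assert rois.rois[0].sum() > 10

    def test_no_false_rois_on_noise(self):
        ft = np.arange(0, 20, 0.5)
        for seed in range(20):
            stack = syn.simulate_response_stack((64, 64), [], ft, stim10(),
                                                noise_sd=1.0, seed=seed)
            assert len(opt.detect_iglusnfr_rois(stack, stim10())) == 0

    def test_requires_pre_and_post(self):
        ft = np.arange(10.0, 20, 0.5)  # no pre-stimulus frames
        stack = syn.simulate_response_stack((32, 32), [], ft, stim10(), noise_sd=0.0)
        with pytest.raises(ValueError):
            opt.detect_iglusnfr_rois(stack, stim10())


class TestNormalization:
    def series(self, f, f0=100.0):
        t = np.arange(len(f), dtype=float)
        return ROITimeSeries(time=t, F=np.asarray(f, float),
                             stim=StimProtocol(n_stimuli=1, frequency=1, onset=2.0),
                             F0=f0)

    def test_peak_is_one(self):
        s = self.series([100, 100, 150, 200, 150])
        n = opt.normalize_response(s, "dF_over_dFmax")
        assert n.F.max() == pytest.approx(1.0)

    def test_df_over_f0(self):
        s = self.series([100, 100, 150, 200, 150])
        n = opt.normalize_response(s, "dF_over_F0")
        assert n.F.max() == pytest.approx(1.0)  # dFmax == F0 here by construction

    def test_flat_series_zeros(self):
        s = self.series([100.0] * 5)
        assert np.all(opt.normalize_response(s, "dF_over_F0").F == 0)

    def test_zero_f0_rejected(self):
        s = self.series([0.0, 0, 1, 2], f0=0.0)
        with pytest.raises(ValueError):
            opt.normalize_response(s, "dF_over_F0")

    def test_idempotent(self):
        s = self.series([100, 100, 150, 200, 150])
        n1 = opt.normalize_response(s, "dF_over_dFmax")
        n2 = opt.normalize_response(n1, "dF_over_dFmax")
        assert np.array_equal(n1.F, n2.F)

    def test_cross_mode_renormalization_rejected(self):
        s = self.series([100, 100, 150, 200, 150])
        n1 = opt.normalize_response(s, "dF_over_dFmax")
        with pytest.raises(ValueError):
            opt.normalize_response(n1, "dF_over_F0")


class TestEndocyticTau:
    def test_noiseless_exact(self):
        stim = StimProtocol(n_stimuli=100, frequency=20, onset=10.0)
        cfg = syn.SimConfig(duration=100.0, sampling_rate=1.0, noise_sd=0.0)
        ser, _ = syn.simulate_phluorin_series(20.0, stim, cfg)
        fit = opt.fit_endocytic_tau(opt.normalize_response(ser, "dF_over_dFmax"))
        assert fit.valid
        assert fit.tau == pytest.approx(20.0, rel=1e-3)

    def test_flat_series_flagged(self):
        stim = StimProtocol(n_stimuli=100, frequency=20, onset=10.0)
        cfg = syn.SimConfig(duration=100.0, sampling_rate=1.0, noise_sd=0.0)
        ser, _ = syn.simulate_phluorin_series(np.inf, stim, cfg)
        fit = opt.fit_endocytic_tau(opt.normalize_response(ser, "dF_over_dFmax"))
        assert not fit.valid

    def test_unbiased_across_tau_range(self):
        """|bias| < 2% on noiseless decays for tau from 1 to 60 s."""
        stim = StimProtocol(n_stimuli=20, frequency=20, onset=5.0)
        for tau in (1.0, 5.0, 20.0, 60.0):
            cfg = syn.SimConfig(duration=max(30.0, 4 * tau), sampling_rate=2.0,
                                noise_sd=0.0)
            ser, _ = syn.simulate_phluorin_series(tau, stim, cfg)
            fit = opt.fit_endocytic_tau(opt.normalize_response(ser, "dF_over_dFmax"))
            assert abs(fit.tau - tau) / tau < 0.02


class TestReacidification:
    def test_rate_recovery(self):
        stim = StimProtocol(n_stimuli=100, frequency=20, onset=5.0)
        cfg = syn.SimConfig(duration=60.0, sampling_rate=5.0, noise_sd=0.0)
        reac = syn.ReacidSchedule(acid_windows=[(15.0, 27.0)], tau_reacid=4.0)
        ser, _ = syn.simulate_phluorin_series(5.0, stim, cfg, reacid=reac)
        rate = opt.fit_reacidification(ser, (15.0, 27.0))
        assert rate == pytest.approx(0.25, rel=0.02)

    def test_window_too_short(self):
        stim = StimProtocol(n_stimuli=100, frequency=20, onset=5.0)
        cfg = syn.SimConfig(duration=60.0, sampling_rate=5.0, noise_sd=0.0)
        reac = syn.ReacidSchedule(acid_windows=[(15.0, 27.0)], tau_reacid=4.0)
        ser, _ = syn.simulate_phluorin_series(5.0, stim, cfg, reacid=reac)
        with pytest.raises(ValueError):
            opt.fit_reacidification(ser, (15.0, 15.6))


class TestCaTransient:
    def make_ca(self, peak=0.8, tau=0.6, fs=50.0, onset=2.0, noise=0.0, seed=0):
        t = np.arange(0, 10, 1 / fs)
        f0 = 100.0
        f = np.full_like(t, f0)
        f[t >= onset] += peak * f0 * np.exp(-(t[t >= onset] - onset) / tau)
        if noise:
            f += np.random.default_rng(seed).normal(0, noise, len(t))
        ser = ROITimeSeries(time=t, F=f, F0=f0,
                            stim=StimProtocol(n_stimuli=1, frequency=20, onset=onset))
        return opt.normalize_response(ser, "dF_over_F0")

    def test_peak_recovery(self):
        assert opt.peak_transient(self.make_ca()) == pytest.approx(0.8, rel=1e-6)

    def test_decay_tau(self):
        fit = opt.fit_ca_decay(self.make_ca(), post_stim=2.0)
        assert fit.tau == pytest.approx(0.6, rel=0.01)

    def test_flat_peak_zero(self):
        assert opt.peak_transient(self.make_ca(peak=0.0)) == pytest.approx(0.0, abs=1e-9)

    def test_requires_df_f0(self):
        ser = ROITimeSeries(time=np.arange(5.0), F=np.ones(5),
                            stim=StimProtocol(n_stimuli=1, frequency=1, onset=1.0))
        with pytest.raises(ValueError):
            opt.peak_transient(ser)


class TestFuraAndBleach:
    def test_equal_channels(self):
        assert np.allclose(opt.fura_ratio([1.0, 2.0], [1.0, 2.0]), 1.0)

    def test_double_ratio(self):
        assert np.allclose(opt.fura_ratio([2.0, 4.0], [1.0, 2.0]), 2.0)

    def test_gain_invariance(self):
        f340 = np.array([1.0, 2.0, 3.0])
        f380 = np.array([2.0, 2.0, 1.0])
        assert np.allclose(opt.fura_ratio(f340, f380),
                           opt.fura_ratio(3.7 * f340, 3.7 * f380))

    def test_nonpositive_f380_masked(self):
        out = opt.fura_ratio([1.0, 1.0], [1.0, 0.0])
        assert np.isfinite(out[0]) and np.isnan(out[1])

    def test_ca_step_doubles_ratio(self):
        f380 = np.full(20, 50.0)
        f340 = np.where(np.arange(20) < 10, 50.0, 100.0)
        r = opt.fura_ratio(f340, f380)
        assert np.allclose(r[:10], 1.0) and np.allclose(r[10:], 2.0)

    @pytest.mark.parametrize("decline,keep", [(0.01, True), (0.05, False),
                                              (0.02, True)])
    def test_photobleach_threshold(self, decline, keep):
        t = np.arange(0, 100, 1.0)
        f = 100.0 * (1 - decline * t / t[-1])
        ser = ROITimeSeries(time=t, F=f, F0=100.0,
                            stim=StimProtocol(n_stimuli=0, frequency=1, onset=200.0))
        assert opt.photobleach_check(ser) is keep
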