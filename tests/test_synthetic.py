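"""Forward-model generators: contracts, identities, determinism."""

import numpy as np
import pytest

from synaptoquant import synthetic as syn
from synaptoquant.core import StimProtocol


class TestSimConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            syn.SimConfig(sampling_rate=0)
        with pytest.raises(ValueError):
            syn.SimConfig(duration=-1)
        with pytest.raises(ValueError):
            syn.SimConfig(noise_sd=-1e-12)
        with pytest.raises(ValueError):
            syn.SimConfig(lockin_frequency=0)

    def test_determinism_bit_identical(self):
        ev = [syn.PoreEventSpec(t_start=0.5, direction="endocytic", cv=1e-15)]
        cfg = syn.SimConfig(seed=42, duration=1.0, noise_sd=5e-12)
        t1, _ = syn.simulate_fission_trace(ev, cfg)
        t2, _ = syn.simulate_fission_trace(ev, cfg)
        assert np.array_equal(t1.Re, t2.Re) and np.array_equal(t1.Im, t2.Im)


class TestFissionTrace:
    def test_instant_endocytic_step_is_pure_im(self):
        """Gp -> inf limit: a closed instantaneous step moves only Im, by wCv."""
        ev = syn.PoreEventSpec(t_start=0.5, direction="endocytic", cv=1e-15)
        cfg = syn.SimConfig(duration=1.0, noise_sd=0.0)
        tr, _ = syn.simulate_fission_trace([ev], cfg, apply_filter=False)
        assert np.allclose(tr.Re, 0.0)
        step = tr.Im[0] - tr.Im[-1]
        assert step == pytest.approx(tr.omega * 1e-15, rel=1e-12)

    def test_constant_pore_admittance_identity(self):
        """(Re^2+Im^2)/Re of the event admittance equals Gp at every sample."""
        gp = 300e-12
        ev = syn.PoreEventSpec(t_start=0.3, direction="endocytic", cv=1e-15,
                               pore_duration=0.2, gp_profile=syn.constant_pore(gp))
        cfg = syn.SimConfig(duration=1.0, noise_sd=0.0)
        tr, _ = syn.simulate_fission_trace([ev], cfg, apply_filter=False)
        sel = (tr.time >= 0.31) & (tr.time < 0.49)
        est = (tr.Re[sel] ** 2 + tr.Im[sel] ** 2) / tr.Re[sel]
        assert np.allclose(est, gp, rtol=1e-9)

    def test_empty_events_constant_baseline(self):
        cfg = syn.SimConfig(duration=0.5, noise_sd=0.0)
        tr, _ = syn.simulate_fission_trace([], cfg, baseline_re=1e-9, baseline_im=2e-10)
        assert np.ptp(tr.Re) == 0 and np.ptp(tr.Im) == 0

    def test_overlapping_events_rejected(self):
        evs = [
            syn.PoreEventSpec(t_start=0.3, direction="endocytic", cv=1e-15,
                              pore_duration=0.1, gp_profile=syn.constant_pore(1e-9)),
            syn.PoreEventSpec(t_start=0.35, direction="endocytic", cv=1e-15),
        ]
        with pytest.raises(ValueError, match="overlap"):
            syn.simulate_fission_trace(evs, syn.SimConfig(duration=1.0))

    def test_capacitance_conservation_any_pore_duration(self):
        """Total Im change of a completed endocytic event is -wCv regardless
        of how long the pore takes to close."""
        cfg = syn.SimConfig(duration=2.0, noise_sd=0.0)
        for dur in (0.0, 0.02, 0.1):
            prof = syn.linear_closure(2e-9, dur) if dur else None
            ev = syn.PoreEventSpec(t_start=0.5, direction="endocytic", cv=1e-15,
                                   pore_duration=dur, gp_profile=prof)
            tr, _ = syn.simulate_fission_trace([ev], cfg)
            drop = np.mean(tr.Im[:int(0.3 * 10_000)]) - np.mean(tr.Im[-int(0.3 * 10_000):])
            assert drop == pytest.approx(tr.omega * 1e-15, rel=1e-6)


class TestPatchCurrent:
    def test_ohmic_symmetry(self):
        cfg = syn.SimConfig(duration=1.0, sampling_rate=5000, noise_sd=0.0)
        tr_p, tp = syn.simulate_patch_current(0.04, lambda V: 50e-12, 0.5, 0.0, cfg)
        tr_n, tn_ = syn.simulate_patch_current(-0.04, lambda V: 50e-12, 0.5, 0.0, cfg)
        di_p = tp.events[0]["delta_i"]
        di_n = tn_.events[0]["delta_i"]
        assert di_p == -di_n and di_p == pytest.approx(2e-12)

    def test_rectifying_arithmetic(self):
        g = lambda V: 50e-12 if V > 0 else 5e-12
        cfg = syn.SimConfig(duration=1.0, sampling_rate=5000, noise_sd=0.0)
        _, tp = syn.simulate_patch_current(0.04, g, 0.5, 0.0, cfg)
        _, tn_ = syn.simulate_patch_current(-0.04, g, 0.5, 0.0, cfg)
        assert abs(tp.events[0]["delta_i"]) == pytest.approx(2.0e-12)
        assert abs(tn_.events[0]["delta_i"]) == pytest.approx(0.2e-12)

    def test_zero_conductance_flat(self):
        cfg = syn.SimConfig(duration=1.0, sampling_rate=5000, noise_sd=0.0)
        tr, _ = syn.simulate_patch_current(0.04, lambda V: 0.0, 0.5, 1e-12, cfg,
                                           filter_hz=None)
        slope = np.polyfit(tr.time, tr.I, 1)[0]
        assert slope == pytest.approx(1e-12, rel=1e-9)
        assert np.max(np.abs(tr.I - np.polyval(np.polyfit(tr.time, tr.I, 1), tr.time))) < 1e-18


class TestAmperometricTrace:
    def test_instant_rise_charge_identity(self):
        """A*tau: the integral of a footless instant-rise spike."""
        cfg = syn.SimConfig(duration=1.0, sampling_rate=50_000, noise_sd=0.0)
        sp = syn.SpikeSpec(t=0.3, peak=50e-12, tau_decay=2e-3)
        tr, _ = syn.simulate_amperometric_trace([sp], cfg, stim_time=0.1)
        q = np.trapezoid(tr.I, tr.time)
        assert q == pytest.approx(0.1e-12, rel=5e-3)

    def test_foot_plateau_precedes_rise(self):
        cfg = syn.SimConfig(duration=1.0, sampling_rate=50_000, noise_sd=0.0)
        sp = syn.SpikeSpec(t=0.3, peak=50e-12, tau_decay=2e-3, rise_time=0.3e-3,
                           foot_amp=5e-12, foot_duration=2e-3)
        tr, _ = syn.simulate_amperometric_trace([sp], cfg, stim_time=0.1)
        sel = (tr.time >= 0.2985) & (tr.time < 0.2998)
        assert np.allclose(tr.I[sel], 5e-12)

    def test_empty_spike_list(self):
        cfg = syn.SimConfig(duration=1.0, sampling_rate=10_000, noise_sd=0.0)
        tr, _ = syn.simulate_amperometric_trace([], cfg, stim_time=0.5)
        assert np.all(tr.I == 0)

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            syn.SpikeSpec(t=0.1, peak=-1e-12, tau_decay=1e-3)


class TestPhluorin:
    def test_monoexponential_decay_by_construction(self):
        stim = StimProtocol(n_stimuli=100, frequency=20, onset=10.0)
        cfg = syn.SimConfig(duration=120.0, sampling_rate=2.0, noise_sd=0.0)
        ser, _ = syn.simulate_phluorin_series(20.0, stim, cfg, f0=100.0, delta_fmax=50.0)
        t_off = stim.end
        post = ser.time > t_off + 1
        expected = 100.0 + 50.0 * np.exp(-(ser.time[post] - t_off) / 20.0)
        assert np.allclose(ser.F[post], expected, rtol=1e-12)

    def test_infinite_tau_flat_plateau(self):
        stim = StimProtocol(n_stimuli=100, frequency=20, onset=10.0)
        cfg = syn.SimConfig(duration=60.0, sampling_rate=2.0, noise_sd=0.0)
        ser, _ = syn.simulate_phluorin_series(np.inf, stim, cfg)
        post = ser.time > stim.end
        assert np.ptp(ser.F[post]) == 0

    def test_acid_window_trapped_decay_rate(self):
        """In-window trapped decay carries exactly 1/tau_reacid."""
        stim = StimProtocol(n_stimuli=100, frequency=20, onset=5.0)
        cfg = syn.SimConfig(duration=60.0, sampling_rate=5.0, noise_sd=0.0)
        reac = syn.ReacidSchedule(acid_windows=[(15.0, 27.0)], tau_reacid=4.0)
        ser, _ = syn.simulate_phluorin_series(5.0, stim, cfg, reacid=reac)
        sel = (ser.time >= 16.0) & (ser.time < 26.0)
        rate = -np.polyfit(ser.time[sel], np.log(ser.F[sel]), 1)[0]
        assert rate == pytest.approx(0.25, rel=1e-6)

    def test_invalid_tau(self):
        stim = StimProtocol(n_stimuli=10, frequency=20, onset=1.0)
        with pytest.raises(ValueError):
            syn.simulate_phluorin_series(-1.0, stim, syn.SimConfig(duration=10.0))


class TestDepressingTrain:
    def test_steady_state_convergence(self):
        a = syn.simulate_depressing_train(250, a_ss=0.44, r=0.9)
        assert a[0] == 1.0
        assert np.mean(a[-10:]) == pytest.approx(0.44, abs=1e-6)

    def test_no_depression(self):
        assert np.all(syn.simulate_depressing_train(20, a_ss=1.0, r=0.5) == 1.0)

    def test_instant_depression(self):
        a = syn.simulate_depressing_train(5, a_ss=0.3, r=0.0)
        assert a[0] == 1.0 and np.allclose(a[1:], 0.3)

    def test_monotone_decrease(self):
        a = syn.simulate_depressing_train(100, a_ss=0.2, r=0.95)
        assert np.all(np.diff(a) <= 0)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            syn.simulate_depressing_train(10, a_ss=0.5, r=1.0)

    def test_depletion_ppr_closed_form(self):
        p, tau, isi = 0.2, 2.0, 0.1
        a = syn.simulate_depletion_train(p, tau, isi, 5)
        assert a[1] / a[0] == pytest.approx(1 - p * np.exp(-isi / tau), rel=1e-12)


class TestWholeCellAdmittance:
    def test_large_gs_limit(self):
        """Gs >> everything: Y ~ Gm + jwCm."""
        gm, cm, f = 0.5e-9, 5e-12, 1e3
        y, _ = syn.simulate_whole_cell_admittance(cm, gm, gm * 1e6, f)
        assert abs(y - (gm + 1j * 2 * np.pi * f * cm)) / abs(y) < 1e-4

    def test_pure_resistive(self):
        y, gt = syn.simulate_whole_cell_admittance(0.0, 1e-9, 10e-9, 1e3)
        assert y.imag == 0 and y.real == pytest.approx(gt, rel=1e-12)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            syn.simulate_whole_cell_admittance(1e-12, -1e-9, 10e-9, 1e3)


class TestGroundTruth:
    def test_json_round_trip(self):
        ev = syn.PoreEventSpec(t_start=0.5, direction="endocytic", cv=1e-15,
                               pore_duration=0.03,
                               gp_profile=syn.linear_closure(2e-9, 0.03))
        _, truth = syn.simulate_fission_trace([ev], syn.SimConfig(duration=1.0))
        again = syn.GroundTruth.from_json(truth.to_json())
        assert again.events == truth.events and again.params == truth.params
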