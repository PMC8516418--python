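"""Capacitance-step detection, pore conductance, circuit inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_

from synaptoquant import capacitance as cap
from synaptoquant import synthetic as syn

OMEGA = 2 * np.pi * 20e3


class TestGpFormulas:
    def test_plug_in(self):
        assert cap.gp_from_re_im(100e-12, 100e-12) == pytest.approx(200e-12)

    def test_open_pore_limit(self):
        # Re -> 0+ with finite Im: conductance above any measurable value
        assert cap.gp_from_re_im(1e-18, 100e-12) > 1e-2

    def test_negative_re_masked_not_fatal(self):
        out = cap.gp_from_re_im(np.array([1e-12, -1e-12, 2e-12]),
                                np.array([1e-12, 1e-12, 1e-12]))
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2]]).all()

    def test_all_negative_re_raises(self):
        with pytest.raises(ValueError):
            cap.gp_from_re_im(np.array([-1e-12, -2e-12]), np.array([1e-12, 1e-12]))

    def test_gp_from_im_half_point(self):
        # Im = wCv/2 -> Gp = wCv
        x = OMEGA * 1e-15
        assert cap.gp_from_im(x / 2, 1e-15, OMEGA) == pytest.approx(x, rel=1e-12)

    def test_gp_from_im_limits(self):
        x = OMEGA * 1e-15
        assert np.isinf(cap.gp_from_im(x, 1e-15, OMEGA))
        assert cap.gp_from_im(-1e-15, 1e-15, OMEGA) == 0.0
        assert cap.gp_from_im(0.999 * x, 1e-15, OMEGA) > 30 * x

    @settings(derandomize=True, max_examples=60)
    @given(
        gp=st_.floats(min_value=10e-12, max_value=10e-9),
        cv=st_.floats(min_value=0.2e-15, max_value=10e-15),
    )
    def test_formula_equivalence_property(self, gp, cv):
        """Both estimators recover the generator Gp to 1e-6 relative."""
        y = syn.pore_admittance(gp, cv, OMEGA)
        g1 = cap.gp_from_re_im(y.real, y.imag)
        g2 = cap.gp_from_im(y.imag, cv, OMEGA)
        assert g1 == pytest.approx(gp, rel=1e-6)
        assert g2 == pytest.approx(gp, rel=1e-6)

    def test_monotone_in_im(self):
        x = OMEGA * 1e-15
        ims = np.linspace(0.01, 0.99, 200) * x
        gps = cap.gp_from_im(ims, 1e-15, OMEGA)
        assert np.all(np.diff(gps) > 0)


class TestStepDetection:
    def make_trace(self, events, noise=0.0, seed=0, duration=5.0):
        cfg = syn.SimConfig(seed=seed, duration=duration, noise_sd=noise)
        tr, _ = syn.simulate_fission_trace(events, cfg, baseline_im=2e-10)
        return tr

    def test_single_step_detected(self):
        ev = syn.PoreEventSpec(t_start=2.0, direction="endocytic", cv=1e-15)
        det = cap.detect_capacitance_steps(self.make_trace([ev]))
        assert len(det) == 1
        assert det[0].direction == "endocytic"
        assert det[0].cv == pytest.approx(1e-15, rel=0.02)

    def test_subthreshold_step_rejected(self):
        ev = syn.PoreEventSpec(t_start=2.0, direction="endocytic", cv=0.15e-15)
        assert cap.detect_capacitance_steps(self.make_trace([ev])) == []

    def test_exocytic_direction(self):
        ev = syn.PoreEventSpec(t_start=2.0, direction="exocytic", cv=1e-15)
        det = cap.detect_capacitance_steps(self.make_trace([ev]))
        assert len(det) == 1 and det[0].direction == "exocytic"

    def test_short_trace_raises(self):
        tr = self.make_trace([], duration=0.02)
        with pytest.raises(ValueError):
            cap.detect_capacitance_steps(tr)

    def test_recall_and_size_under_noise(self):
        """>=95% recall, <=10% size error at SNR 5 for 0.3-1.5 fF steps."""
        rng = np.random.default_rng(11)
        noise = 0.3e-15 * OMEGA / 5
        found, errs, total = 0, [], 0
        for seed in range(4):
            cvs = rng.uniform(0.3e-15, 1.5e-15, 4)
            evs = [syn.PoreEventSpec(t_start=0.5 + k, direction="endocytic", cv=float(c))
                   for k, c in enumerate(cvs)]
            tr = self.make_trace(evs, noise=noise, seed=seed)
            det = cap.detect_capacitance_steps(tr)
            total += len(evs)
            for e in evs:
                m = [d for d in det if abs(d.t_step - e.t_start) < 0.1]
                if m:
                    found += 1
                    errs.append(abs(m[0].cv - e.cv) / e.cv)
        assert found / total >= 0.95
        assert max(errs) <= 0.10

    def test_no_false_positives_on_noise(self):
        noise = 0.3e-15 * OMEGA / 5
        for seed in range(10):
            tr = self.make_trace([], noise=noise, seed=seed + 500)
            assert cap.detect_capacitance_steps(tr) == []


class TestFissionPore:
    def run_pore(self, dur, noise=0.0, seed=0, gp0=2e-9):
        ev = syn.PoreEventSpec(t_start=0.5, direction="endocytic", cv=1e-15,
                               pore_duration=dur,
                               gp_profile=syn.linear_closure(gp0, dur))
        cfg = syn.SimConfig(seed=seed, duration=1.5, noise_sd=noise)
        tr, _ = syn.simulate_fission_trace([ev], cfg)
        evt = cap.CapacitanceEvent("endocytic", t_step=0.5 + dur / 2, cv=1e-15)
        return cap.measure_fission_pore(tr, evt)

    def test_duration_recovery_40ms(self):
        d, gp_mean, valid = self.run_pore(0.040)
        assert d == pytest.approx(0.040, abs=2e-3)
        assert valid

    def test_short_pore_invalid(self):
        d, _, valid = self.run_pore(0.008)
        assert not valid

    def test_instantaneous_step_duration_zero(self):
        ev = syn.PoreEventSpec(t_start=0.5, direction="endocytic", cv=1e-15)
        cfg = syn.SimConfig(duration=1.5, noise_sd=0.0)
        tr, _ = syn.simulate_fission_trace([ev], cfg, apply_filter=False)
        evt = cap.CapacitanceEvent("endocytic", t_step=0.5, cv=1e-15)
        d, gp_mean, valid = cap.measure_fission_pore(tr, evt, filter_tau=None)
        assert d == 0.0 and not valid

    def test_constant_pore_gp_mean(self):
        dur = 0.05
        ev = syn.PoreEventSpec(t_start=0.5, direction="endocytic", cv=1e-15,
                               pore_duration=dur, gp_profile=syn.constant_pore(300e-12))
        cfg = syn.SimConfig(duration=1.5, noise_sd=0.0)
        tr, _ = syn.simulate_fission_trace([ev], cfg)
        evt = cap.CapacitanceEvent("endocytic", t_step=0.525, cv=1e-15)
        _, gp_mean, _ = cap.measure_fission_pore(tr, evt)
        assert gp_mean == pytest.approx(300e-12, rel=0.1)

    def test_exocytic_event_rejected(self):
        tr, _ = syn.simulate_fission_trace([], syn.SimConfig(duration=1.0))
        evt = cap.CapacitanceEvent("exocytic", t_step=0.5, cv=1e-15)
        with pytest.raises(ValueError):
            cap.measure_fission_pore(tr, evt)


class TestEventCounting:
    def test_window_rule(self):
        evs = [cap.CapacitanceEvent("endocytic", t, 1e-15) for t in (10, 100, 400)]
        assert cap.count_endocytic_events(evs, window=300) == 2

    def test_empty(self):
        assert cap.count_endocytic_events([]) == 0

    def test_direction_filtering(self):
        evs = [cap.CapacitanceEvent("endocytic", 10 * k, 1e-15) for k in range(7)]
        evs += [cap.CapacitanceEvent("exocytic", 5 + 10 * k, 1e-15) for k in range(3)]
        assert cap.count_endocytic_events(evs) == 7


class TestEquivalentCircuit:
    def test_round_trip(self):
        y, gt = syn.simulate_whole_cell_admittance(5e-12, 0.5e-9, 50e-9, 1e3)
        cm, gm, gs = cap.solve_equivalent_circuit(y, gt, 2 * np.pi * 1e3)
        assert cm == pytest.approx(5e-12, rel=1e-9)
        assert gm == pytest.approx(0.5e-9, rel=1e-9)
        assert gs == pytest.approx(50e-9, rel=1e-9)

    def test_round_trip_grid(self):
        omega = 2 * np.pi * 1e3
        for cm in np.logspace(np.log10(1e-12), np.log10(30e-12), 5):
            for gm in np.logspace(np.log10(0.2e-9), np.log10(5e-9), 5):
                for gs in np.logspace(np.log10(10e-9), np.log10(100e-9), 5):
                    y, gt = syn.simulate_whole_cell_admittance(cm, gm, gs, 1e3)
                    cm_r, gm_r, gs_r = cap.solve_equivalent_circuit(y, gt, omega)
                    assert cm_r == pytest.approx(cm, rel=1e-9)
                    assert gm_r == pytest.approx(gm, rel=1e-9)
                    assert gs_r == pytest.approx(gs, rel=1e-9)

    def test_degenerate_resistive(self):
        y, gt = syn.simulate_whole_cell_admittance(0.0, 1e-9, 10e-9, 1e3)
        cm, gm, gs = cap.solve_equivalent_circuit(y, gt, 2 * np.pi * 1e3)
        assert cm == 0.0
        assert gs * gm / (gs + gm) == pytest.approx(gt, rel=1e-9) or np.isinf(gs)

    def test_large_gs_limit(self):
        omega = 2 * np.pi * 1e3
        y, gt = syn.simulate_whole_cell_admittance(5e-12, 0.5e-9, 5e-6, 1e3)
        cm, _, _ = cap.solve_equivalent_circuit(y, gt, omega)
        assert cm == pytest.approx(y.imag / omega, rel=1e-3)

    def test_non_physical_raises(self):
        with pytest.raises(ValueError):
            cap.solve_equivalent_circuit(1e-9 + 1e-9j, 2e-9, 2 * np.pi * 1e3)


class TestWholeCellDerived:
    def make_record(self, cm_fn, leak=100e-12, fs=1000.0, duration=1.0):
        t = np.arange(0, duration, 1 / fs)
        return cap.WholeCellRecord(time=t, Cm=cm_fn(t), leak=leak)

    def test_delta_cm_step(self):
        rec = self.make_record(lambda t: np.where(t < 0.5, 5000e-15, 5010e-15))
        dcm = cap.delta_cm_exocytosis(rec, depol_onset=0.45, depol_end=0.5)
        assert dcm == pytest.approx(10e-15, rel=1e-9)

    def test_delta_cm_flat(self):
        rec = self.make_record(lambda t: np.full_like(t, 5e-12))
        assert cap.delta_cm_exocytosis(rec, 0.45, 0.5) == 0.0

    def test_delta_cm_noisy_jump(self):
        rng = np.random.default_rng(3)
        noise = 2e-15
        t = np.arange(0, 1.0, 1e-3)
        cm = np.where(t < 0.5, 5000e-15, 5025e-15) + rng.normal(0, noise, len(t))
        rec = cap.WholeCellRecord(time=t, Cm=cm)
        dcm = cap.delta_cm_exocytosis(rec, 0.45, 0.5)
        sem = noise / np.sqrt(50)
        assert abs(dcm - 25e-15) < 3 * sem * np.sqrt(2)

    def test_delta_cm_insufficient_window(self):
        rec = self.make_record(lambda t: np.full_like(t, 5e-12), duration=0.52)
        with pytest.raises(ValueError):
            cap.delta_cm_exocytosis(rec, 0.5, 0.51)

    @pytest.mark.parametrize("leak,keep", [(100e-12, True), (151e-12, False),
                                           (150e-12, True)])
    def test_leak_qc(self, leak, keep):
        rec = self.make_record(lambda t: np.full_like(t, 5e-12), leak=leak)
        assert cap.qc_leak(rec) is keep

    def test_ca_influx_constant_current(self):
        """100 pA over 100 ms minus the first 10 ms: 9 pC."""
        t = np.arange(0, 0.5, 1e-4)
        i = np.where((t >= 0.2) & (t <= 0.3), -100e-12, 0.0)
        q = cap.ca_influx_charge(t, i, depol_onset=0.2, depol_end=0.3)
        assert q == pytest.approx(9e-12, rel=0.01)

    def test_ca_influx_zero(self):
        t = np.arange(0, 0.5, 1e-4)
        assert cap.ca_influx_charge(t, np.zeros_like(t), 0.2, 0.3) == 0.0

    def test_ca_influx_decaying_analytic(self):
        t = np.arange(0, 0.5, 1e-5)
        tau = 0.03
        i = np.where(t >= 0.2, -200e-12 * np.exp(-(t - 0.2) / tau), 0.0)
        q = cap.ca_influx_charge(t, i, 0.2, 0.3)
        expect = 200e-12 * tau * (np.exp(-0.01 / tau) - np.exp(-0.1 / tau))
        assert q == pytest.approx(expect, rel=0.01)

    def test_ca_influx_bad_exclusion(self):
        t = np.arange(0, 0.5, 1e-4)
        with pytest.raises(ValueError):
            cap.ca_influx_charge(t, np.zeros_like(t), 0.2, 0.205)
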