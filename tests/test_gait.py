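import numpy as np
import pandas as pd
import pytest

import gaitcost as gc
from gaitcost.subjects import ValidationError
from gaitcost.trial import HEEL_STRIKE, TOE_OFF, GaitEvent


def make_events(stride_time=1.1, ds_frac=0.30, n_strides=1, t0=0.0):
    """Analytic event sequence realizing a given total DS fraction."""
    d = ds_frac / 2 * stride_time
    ev = []
    for k in range(n_strides):
        s = t0 + k * stride_time
        ev += [
            GaitEvent(s, "right", HEEL_STRIKE),
            GaitEvent(s + d, "left", TOE_OFF),
            GaitEvent(s + stride_time / 2, "left", HEEL_STRIKE),
            GaitEvent(s + stride_time / 2 + d, "right", TOE_OFF),
        ]
    ev.append(GaitEvent(t0 + n_strides * stride_time, "right", HEEL_STRIKE))
    return ev


class TestEventDetection:
    def _trial_with_time(self, t):
        n = len(t)
        return gc.GaitTrial(t=t, q=np.zeros((n, 1)), qd=np.zeros((n, 1)),
                            tau=np.zeros((n, 1)), v=np.ones(n), dof_ids=("j0",))

    def test_piecewise_linear_grf_crossings_exact(self):
        t = np.linspace(0, 4, 4001)
        trial = self._trial_with_time(t)
        # right foot: ramps 0->800 N over [0.5, 0.6], down over [2.0, 2.1];
        # second contact from 2.9; left foot analogous, shifted
        def ramp_force(on, off, ramp=0.1, peak=800.0):
            f = np.zeros_like(t)
            for a, b in zip(on, off):
                f += np.clip((t - a) / ramp, 0, 1) * np.clip((b - t) / ramp, 0, 1) * peak
            return f
        grf = {
            "right": ramp_force([0.5, 2.9], [2.1, 4.5]),
            "left": ramp_force([1.5, 3.6], [3.0, 5.5]),
        }
        events = gc.detect_gait_events(trial, grf=grf, threshold_N=20, hysteresis_N=5)
        # rising crossing of 20 N: onset + 0.1 * 20/800
        t_hs = 0.5 + 0.1 * 20 / 800
        got = [e for e in events if e.side == "right" and e.type == HEEL_STRIKE][0]
        assert got.time_s == pytest.approx(t_hs, abs=1e-9)
        # falling crossing of 15 N: end - 0.1 * 15/800
        t_to = 2.1 - 0.1 * 15 / 800
        got = [e for e in events if e.side == "right" and e.type == TOE_OFF][0]
        assert got.time_s == pytest.approx(t_to, abs=1e-9)

    def test_events_shift_with_trial(self):
        t = np.linspace(0, 4, 2001)
        trial = self._trial_with_time(t)
        f = np.where((t % 2) < 1.2, 800.0, 0.0)
        g = np.where(((t + 1) % 2) < 1.2, 800.0, 0.0)
        ev1 = gc.detect_gait_events(trial, grf={"right": f, "left": g})
        shifted = self._trial_with_time(t + 0.5)
        ev2 = gc.detect_gait_events(shifted, grf={"right": f, "left": g})
        for a, b in zip(ev1, ev2):
            assert b.time_s - a.time_s == pytest.approx(0.5, abs=1e-9)

    def test_single_stride_errors(self):
        t = np.linspace(0, 1, 501)
        trial = self._trial_with_time(t)
        f = np.where(t < 0.6, 800.0, 0.0)
        with pytest.raises(ValidationError, match="no complete stride"):
            gc.detect_gait_events(trial, grf={"right": f, "left": f})

    def test_generated_stride_ds_fraction_recovered(self):
        """End-to-end: synthetic GRF -> detection -> segmentation within 0.5%."""
        cfg = gc.GeneratorConfig(seed=21, with_grf=True,
                                 ds_fraction_anchors_pct=(30.0, 30.0))
        rng = np.random.default_rng(21)
        subj = gc.generate_subject(cfg, rng, sex="M", subject_id="s")
        trial = gc.generate_gait_trial(subj, 100.0, cfg, rng, n_strides=3)
        events = gc.detect_gait_events(trial, grf=trial.meta["grf"])
        seg = gc.segment_phases(events)
        assert seg.ds_fraction_pct(0) == pytest.approx(30.0, abs=0.5)


class TestPhaseSegmentation:
    def test_exact_fraction_from_analytic_events(self):
        seg = gc.segment_phases(make_events(ds_frac=0.30))
        assert seg.ds_fraction_pct(0) == pytest.approx(30.0, abs=1e-9)
        assert seg.ss_fraction_pct(0) + seg.ds_fraction_pct(0) == pytest.approx(100.0)

    def test_phase_durations_conserve_stride(self):
        seg = gc.segment_phases(make_events(stride_time=1.3, ds_frac=0.25, n_strides=3))
        for k, (s0, s1) in enumerate(seg.strides):
            total = sum(p.duration_s for p in seg.phases_in_stride(k))
            assert total == pytest.approx(s1 - s0, abs=1e-9)
            labels = [p.label for p in seg.phases_in_stride(k)]
            assert labels.count("DS1") == 1 and labels.count("DS2") == 1

    def test_instantaneous_double_support(self):
        seg = gc.segment_phases(make_events(ds_frac=0.0))
        assert seg.ds_fraction_pct(0) == pytest.approx(0.0, abs=1e-12)

    def test_out_of_order_events_raise(self):
        ev = make_events()
        # left heel strike before left toe off
        bad = [e if e.type != TOE_OFF or e.side != "left"
               else GaitEvent(0.9, "left", TOE_OFF) for e in ev]
        with pytest.raises(ValidationError, match="sequencing"):
            gc.segment_phases(bad)


class TestBilateralSynchronization:
    def _periodic_trial(self, t0, T, n, dof_ids, phase_offset=0.0, events=()):
        t = np.linspace(t0, t0 + T, n + 1)
        ph = (t - t0) / T + phase_offset
        q = np.column_stack([np.sin(2 * np.pi * ph + j) for j in range(len(dof_ids))])
        qd = np.column_stack([2 * np.pi / T * np.cos(2 * np.pi * ph + j)
                              for j in range(len(dof_ids))])
        tau = 2 * q
        return gc.GaitTrial(t=t, q=q, qd=qd, tau=tau, v=np.ones(n + 1),
                            dof_ids=dof_ids, events=events)

    def test_half_period_offset_gives_mirror_symmetry(self):
        T, n = 1.2, 4000
        right = self._periodic_trial(0.0, T, n, ("r_j",),
                                     events=(GaitEvent(0.0, "right", HEEL_STRIKE),))
        # left stride starts at its own heel strike, half a period before the
        # right heel strike it contains
        left = self._periodic_trial(0.0, T, n, ("l_j",), phase_offset=0.5,
                                    events=(GaitEvent(T / 2, "right", HEEL_STRIKE),
                                            GaitEvent(0.0, "left", HEEL_STRIKE)))
        merged = gc.synchronize_bilateral(right, left)
        assert merged.duration_s == pytest.approx(right.duration_s)
        assert merged.dof_ids == ("r_j", "l_j")
        # the left stride lags by half a period and splits at its right heel
        # strike (T/2), so the synchronized left channel re-aligns with the
        # right one sample for sample
        assert np.allclose(merged.q[:, 1], merged.q[:, 0], atol=1e-6)

    def test_round_trip_recovers_left_stride(self):
        T, n = 1.0, 4000
        right = self._periodic_trial(0.0, T, n, ("r_j",),
                                     events=(GaitEvent(0.0, "right", HEEL_STRIKE),))
        left = self._periodic_trial(10.0, T, n, ("l_j",), phase_offset=0.25,
                                    events=(GaitEvent(10.0 + 0.4 * T, "right", HEEL_STRIKE),))
        merged = gc.synchronize_bilateral(right, left)
        # sample the merged left channel back at the left stride's own phase
        ph_out = (merged.t - merged.t[0]) / T
        expected = np.sin(2 * np.pi * (ph_out + 0.4 + 0.25))
        assert np.max(np.abs(merged.q[:, 1] - expected)) < 1e-6

    def test_duplicate_channels_rejected(self):
        T, n = 1.0, 100
        a = self._periodic_trial(0.0, T, n, ("j",),
                                 events=(GaitEvent(0.0, "right", HEEL_STRIKE),))
        b = self._periodic_trial(0.0, T, n, ("j",),
                                 events=(GaitEvent(0.5, "right", HEEL_STRIKE),))
        with pytest.raises(ValidationError, match="duplicate"):
            gc.synchronize_bilateral(a, b)


class TestFroude:
    def test_zero_speed(self):
        assert gc.froude_number(0.0, 1.7) == 0.0

    def test_leg_length_convention(self):
        assert 0.53 * 1.70 == pytest.approx(0.901)

    def test_hand_arithmetic(self):
        # 1.29 / sqrt(9.81 * 0.53 * 1.70)
        assert gc.froude_number(1.29, 1.70) == pytest.approx(0.4339031581308078,
                                                             rel=1e-12)

    def test_scaling_invariance(self):
        # v -> k v together with l -> k^2 l leaves Fr unchanged
        fr1 = gc.froude_number(1.2, 1.8)
        fr2 = gc.froude_number(3 * 1.2, 9 * 1.8)
        assert fr1 == pytest.approx(fr2, rel=1e-12)


class TestCOTCurveFit:
    def test_exact_recovery_and_argmin(self):
        v = np.array([0.8, 1.0, 1.2, 1.5, 1.9])
        y = 0.2 / v + 0.1 + 0.1 * v
        curve = gc.fit_cot_curve(list(zip(v, y)))
        assert curve.c_m1 == pytest.approx(0.2, abs=1e-8)
        assert curve.c0 == pytest.approx(0.1, abs=1e-8)
        assert curve.c1 == pytest.approx(0.1, abs=1e-8)
        assert curve.convex
        assert curve.argmin_speed == pytest.approx(np.sqrt(2), rel=1e-7)

    def test_constant_data(self):
        pts = [(0.9, 0.33), (1.2, 0.33), (1.6, 0.33), (2.0, 0.33)]
        curve = gc.fit_cot_curve(pts)
        assert curve.c_m1 == pytest.approx(0.0, abs=1e-10)
        assert curve.c1 == pytest.approx(0.0, abs=1e-10)
        assert curve.c0 == pytest.approx(0.33, abs=1e-10)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        pts = [(v, 0.3 / v + 0.05 + 0.12 * v + 0.01 * rng.standard_normal())
               for v in (0.8, 1.0, 1.3, 1.6, 2.0)]
        a = gc.fit_cot_curve(pts)
        b = gc.fit_cot_curve(pts[::-1])
        assert np.allclose(sorted(a.residuals), sorted(b.residuals), atol=1e-12)

    def test_too_few_speeds(self):
        with pytest.raises(ValidationError):
            gc.fit_cot_curve([(1.0, 0.3), (1.0, 0.31), (1.0, 0.29)])


class TestPhaseCOT:
    def _uniform_trace(self, e0=300.0, v0=1.3, T=1.1, n=1101):
        t = np.linspace(0, T, n)
        e = np.full(n, e0)
        return gc.EnergeticsTrace(t=t, work_rate=e * 0, q_am=e * 0, q_sl=e * 0,
                                  q_cc=e * 0, bmr_W=0.0, e_met=e,
                                  per_dof_e_met=e[:, None], v=np.full(n, v0),
                                  dof_ids=("j0",))

    def test_constant_trace_all_cots_equal(self, male_mean_subject):
        trace = self._uniform_trace()
        seg = gc.segment_phases(make_events(stride_time=1.1, ds_frac=0.3))
        out = gc.phase_cot(trace, seg, male_mean_subject)
        assert out["COT_SS"] == pytest.approx(out["COT_total"], rel=1e-9)
        assert out["COT_DS"] == pytest.approx(out["COT_total"], rel=1e-9)
        assert out["%duration_SS"] + out["%duration_DS"] == pytest.approx(100.0)
        assert out["%MEE_SS"] + out["%MEE_DS"] == pytest.approx(100.0, abs=1e-9)

    def test_doubled_ds_expenditure_raises_ds_share(self, male_mean_subject):
        T, n = 1.1, 2201
        t = np.linspace(0, T, n)
        seg = gc.segment_phases(make_events(stride_time=T, ds_frac=0.3))
        e = np.full(n, 200.0)
        for (a, b) in seg.intervals("DS", 0):
            e[(t >= a) & (t <= b)] *= 2.0
        trace = gc.EnergeticsTrace(t=t, work_rate=e * 0, q_am=e * 0, q_sl=e * 0,
                                   q_cc=e * 0, bmr_W=0.0, e_met=e,
                                   per_dof_e_met=e[:, None], v=np.full(n, 1.3),
                                   dof_ids=("j0",))
        out = gc.phase_cot(trace, seg, male_mean_subject)
        assert out["%MEE_DS"] > out["%duration_DS"]


class TestParameterCorrelations:
    def test_exact_linear_gives_r_one(self):
        df = pd.DataFrame({
            "mass_kg": [60, 70, 80, 90.0],
            "mee_W": [240, 280, 320, 360.0],
        })
        out = gc.parameter_correlations(df)
        assert out.loc["mass_kg", "r"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30)
        df = pd.DataFrame({"p": x, "mee_W": y})
        out = gc.parameter_correlations(df)
        r_direct = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert out.loc["p", "r"] == pytest.approx(r_direct, abs=1e-12)
        assert out.loc["p", "r2"] == pytest.approx(r_direct**2, abs=1e-12)

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"p": [1.0, 1.0, 1.0], "mee_W": [1.0, 2.0, 3.0]})
        out = gc.parameter_correlations(df)
        assert bool(out.loc["p", "undefined"])
        assert np.isnan(out.loc["p", "r"])
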