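import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitcost as gc
from gaitcost.energetics import HeatConstraintError, interval_average
from tests.conftest import single_dof_trial

# Frozen oracle values: exact Decimal evaluation of the separable
# coefficient model with the published weights and the male-mean subject
# (mass 87.9 kg, age 31 yr, height 1.83 m, strength ratio 1), done
# independently of the implementation.
HIP_H_AM = 0.123886522080
HIP_H_SL = 1.055874727772865
ANKLE_H_AM = 0.078181255200
ANKLE_H_SL = 1.062506174750475


class TestHeatCoefficients:
    def test_zero_weights_give_zero_coefficients(self, male_mean_subject, male_catalog):
        w = gc.WeightParameters(am=(0,) * 5, sl=(0,) * 5)
        h = gc.heat_coefficients(w, male_mean_subject, male_catalog)
        assert np.all(h.h_am == 0)
        assert np.all(h.h_sl == 0)

    def test_published_weights_male_mean_oracle(self, published, male_mean_subject,
                                                male_catalog):
        h = gc.heat_coefficients(published, male_mean_subject, male_catalog)
        i, j = male_catalog.index("r_hip_sagi"), male_catalog.index("r_ankle_sagi")
        assert h.h_am[i] == pytest.approx(HIP_H_AM, rel=1e-10)
        assert h.h_sl[i] == pytest.approx(HIP_H_SL, rel=1e-10)
        assert h.h_am[j] == pytest.approx(ANKLE_H_AM, rel=1e-10)
        assert h.h_sl[j] == pytest.approx(ANKLE_H_SL, rel=1e-10)

    def test_mirrored_dofs_equal(self, published, male_mean_subject, male_catalog):
        h = gc.heat_coefficients(published, male_mean_subject, male_catalog)
        for dof in male_catalog.dofs:
            if dof.mirror_of is None:
                continue
            i, j = male_catalog.index(dof.dof_id), male_catalog.index(dof.mirror_of)
            assert h.h_am[i] == h.h_am[j]
            assert h.h_sl[i] == h.h_sl[j]

    def test_substantive_violation_raises_with_dof_detail(self, male_mean_subject,
                                                          male_catalog):
        # large negative DOF-factor weight drives the second factor below zero
        w = gc.WeightParameters(am=(1e-4, 0, 0, 0, -10.0), sl=(1.0, 0, 0, 0, 0))
        with pytest.raises(HeatConstraintError, match="hip"):
            gc.heat_coefficients(w, male_mean_subject, male_catalog)

    def test_rounding_band_clamps_to_zero(self, male_catalog, published):
        # a subject whose maintenance factor sits ~-3e-7 with the published
        # 3-significant-figure weights: within printing precision of zero
        subj = gc.SubjectProfile(id="s9", sex="F", mass_kg=52.2, height_m=1.56,
                                 age_yr=23, knee_max_torque_Nm=109.7, bmr_W=70)
        h = gc.heat_coefficients(published, subj, gc.default_catalog("F"))
        assert np.all(h.h_am == 0.0)
        assert np.all(h.h_sl >= 0.0)


class TestHeatRates:
    def test_zero_torque_zero_heat(self):
        q = gc.heat_coefficients  # noqa: F841 - keep namespace flat
        tau = np.zeros((10, 3))
        assert np.all(gc.energetics.activation_maintenance_heat([0.1, 0.2, 0.3], tau) == 0)

    def test_forced_arithmetic(self):
        out = gc.energetics.activation_maintenance_heat([0.121], np.array([[-50.0]]))
        assert out[0, 0] == pytest.approx(6.05, rel=1e-14)
        out = gc.energetics.shortening_lengthening_heat(
            [1.06], np.array([[50.0]]), np.array([[-2.0]])
        )
        assert out[0, 0] == pytest.approx(106.0, rel=1e-14)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_sign_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        tau = rng.normal(size=(20, 4))
        qd = rng.normal(size=(20, 4))
        h_am = rng.uniform(0, 0.2, 4)
        h_sl = rng.uniform(0, 1.5, 4)
        am = gc.energetics.activation_maintenance_heat
        sl = gc.energetics.shortening_lengthening_heat
        assert np.array_equal(am(h_am, tau), am(h_am, -tau))
        assert np.array_equal(sl(h_sl, tau, qd), sl(h_sl, -tau, -qd))
        # eccentric and concentric with equal |tau qd| dissipate equally
        assert np.allclose(sl(h_sl, tau, qd), sl(h_sl, tau, -qd))


class TestMEERate:
    def test_worked_example_91_2_watts(self):
        trial = single_dof_trial(tau=10.0, qd=1.0)
        h = gc.HeatCoefficients(h_am=[0.02], h_sl=[0.1], dof_ids=("j0",))
        trace = gc.mee_rate(trial, h, bmr_W=80.0)
        # 10*1 + 0.02*10 + 0.1*10 + 80 = 91.2 W
        assert np.all(trace.e_met == pytest.approx(91.2, abs=1e-12))

    def test_rest_trial_equals_bmr(self):
        trial = single_dof_trial(tau=0.0, qd=0.0)
        h = gc.HeatCoefficients(h_am=[0.05], h_sl=[0.5], dof_ids=("j0",))
        trace = gc.mee_rate(trial, h, bmr_W=77.0)
        assert np.all(trace.e_met == 77.0)

    def test_joint_sign_flip_leaves_e_met_unchanged(self):
        rng = np.random.default_rng(3)
        n, d = 40, 5
        t = np.linspace(0, 1, n)
        q = rng.normal(size=(n, d))
        qd = rng.normal(size=(n, d))
        tau = rng.normal(size=(n, d))
        ids = tuple(f"j{i}" for i in range(d))
        h = gc.HeatCoefficients(h_am=rng.uniform(0, 0.1, d),
                                h_sl=rng.uniform(0, 1.2, d), dof_ids=ids)
        a = gc.mee_rate(gc.GaitTrial(t=t, q=q, qd=qd, tau=tau, v=np.ones(n),
                                     dof_ids=ids), h, 80.0)
        b = gc.mee_rate(gc.GaitTrial(t=t, q=q, qd=-qd, tau=-tau, v=np.ones(n),
                                     dof_ids=ids), h, 80.0)
        assert np.allclose(a.e_met, b.e_met, rtol=0, atol=1e-12)

    def test_energy_balance_identity(self):
        rng = np.random.default_rng(7)
        n, d = 60, 4
        ids = tuple(f"j{i}" for i in range(d))
        trial = gc.GaitTrial(
            t=np.linspace(0, 1, n), q=rng.normal(size=(n, d)),
            qd=rng.normal(size=(n, d)), tau=rng.normal(size=(n, d)),
            v=np.full(n, 1.2), dof_ids=ids, qcc=rng.uniform(0, 2, (n, d)),
        )
        h = gc.HeatCoefficients(h_am=rng.uniform(0, 0.1, d),
                                h_sl=rng.uniform(0, 1.2, d), dof_ids=ids)
        tr = gc.mee_rate(trial, h, 91.0)
        recomposed = tr.work_rate + tr.q_am + tr.q_sl + tr.q_cc + tr.bmr_W
        assert np.allclose(tr.e_met, recomposed, rtol=1e-10, atol=0)

    def test_negative_qcc_rejected(self):
        with pytest.raises(gc.subjects.ValidationError, match="non-negative"):
            single_dof_trial(qcc=-1.0)


class TestICOTAndCOT:
    def test_icot_pointwise_identity(self, male_mean_subject):
        rng = np.random.default_rng(5)
        trial = single_dof_trial(tau=12.0, qd=0.8, n=200)
        h = gc.HeatCoefficients(h_am=[0.05], h_sl=[0.9], dof_ids=("j0",))
        trace = gc.mee_rate(trial, h, 85.0)
        v = rng.uniform(0.8, 1.8, trace.n_samples)
        ic = gc.icot(trace, male_mean_subject, v=v)
        back = ic * male_mean_subject.mass_kg * 9.81 * v
        assert np.allclose(back, trace.e_met, rtol=1e-12, atol=0)

    def test_icot_forced_arithmetic(self):
        subj = gc.SubjectProfile(id="x", sex="M", mass_kg=70, height_m=1.75,
                                 age_yr=30, knee_max_torque_Nm=200, bmr_W=80)
        trial = single_dof_trial(tau=0, qd=0, v=1.3, n=10)
        h = gc.HeatCoefficients(h_am=[0.0], h_sl=[0.0], dof_ids=("j0",))
        trace = gc.mee_rate(trial, h, 300.0)
        ic = gc.icot(trace, subj)
        assert np.all(ic == pytest.approx(300 / (70 * 9.81 * 1.3), rel=1e-14))

    def test_icot_rejects_nonpositive_speed(self, male_mean_subject):
        trial = single_dof_trial(n=10)
        h = gc.HeatCoefficients(h_am=[0.0], h_sl=[0.0], dof_ids=("j0",))
        trace = gc.mee_rate(trial, h, 80.0)
        v = np.ones(10)
        v[4] = 0.0
        with pytest.raises(gc.subjects.ValidationError, match="index 4"):
            gc.icot(trace, male_mean_subject, v=v)

    def test_rest_cot_is_bmr_over_mgv(self, male_mean_subject):
        trial = single_dof_trial(tau=0.0, qd=0.0, v=1.1, n=80)
        h = gc.HeatCoefficients(h_am=[0.0], h_sl=[0.0], dof_ids=("j0",))
        trace = gc.mee_rate(trial, h, 85.0)
        got = gc.cot(trace, (0.0, 1.0), male_mean_subject)
        assert got == pytest.approx(85.0 / (87.9 * 9.81 * 1.1), rel=1e-12)

    def test_cot_interval_composition(self, male_mean_subject):
        """COT over a union of disjoint intervals is the duration-weighted
        combination of the phase averages."""
        t = np.linspace(0, 2, 801)
        e = 250 + 40 * np.sin(2 * np.pi * t)
        v = 1.3 + 0.1 * np.cos(2 * np.pi * t)
        trace = gc.EnergeticsTrace(
            t=t, work_rate=e * 0, q_am=e * 0, q_sl=e * 0, q_cc=e * 0,
            bmr_W=0.0, e_met=e, per_dof_e_met=e[:, None], v=v, dof_ids=("j0",),
        )
        ivals = [(0.1, 0.6), (0.9, 1.7)]
        e_avgs = [interval_average(t, e, a, b) for a, b in ivals]
        v_avgs = [interval_average(t, v, a, b) for a, b in ivals]
        durs = [b - a for a, b in ivals]
        e_u = sum(ea * d for ea, d in zip(e_avgs, durs)) / sum(durs)
        v_u = sum(va * d for va, d in zip(v_avgs, durs)) / sum(durs)
        expected = e_u / (male_mean_subject.mass_kg * 9.81 * v_u)
        from gaitcost.gait import _union_average
        eu2, _ = _union_average(t, e, ivals)
        vu2, _ = _union_average(t, v, ivals)
        got = eu2 / (male_mean_subject.mass_kg * 9.81 * vu2)
        assert got == pytest.approx(expected, rel=1e-12)


class TestComponentBreakdown:
    def test_rest_trial_is_all_bmr(self, male_mean_subject):
        trial = single_dof_trial(tau=0.0, qd=0.0)
        h = gc.HeatCoefficients(h_am=[0.1], h_sl=[0.5], dof_ids=("j0",))
        trace = gc.mee_rate(trial, h, 85.0)
        shares = gc.component_breakdown(trace)["shares_pct"]
        assert shares["bmr"] == pytest.approx(100.0, abs=1e-12)

    def test_shares_sum_to_total_and_shift_invariance(self):
        rng = np.random.default_rng(11)
        n, d = 120, 3
        ids = tuple(f"j{i}" for i in range(d))
        trial = gc.GaitTrial(
            t=np.linspace(0, 1.3, n), q=rng.normal(size=(n, d)),
            qd=rng.normal(size=(n, d)), tau=rng.normal(size=(n, d)),
            v=np.full(n, 1.2), dof_ids=ids,
        )
        h = gc.HeatCoefficients(h_am=rng.uniform(0, 0.1, d),
                                h_sl=rng.uniform(0, 1.2, d), dof_ids=ids)
        trace = gc.mee_rate(trial, h, 85.0)
        bd = gc.component_breakdown(trace)
        assert sum(bd["shares_pct"].values()) == pytest.approx(100.0, abs=1e-9)
        assert sum(bd["integrals_J"].values()) == pytest.approx(bd["total_J"], rel=1e-9)
        shifted = gc.mee_rate(trial.time_shift(5.0), h, 85.0)
        bd2 = gc.component_breakdown(shifted)
        for k in bd["shares_pct"]:
            assert bd2["shares_pct"][k] == pytest.approx(bd["shares_pct"][k], rel=1e-12)
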