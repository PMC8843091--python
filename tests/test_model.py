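"""Unit and property tests for the two-fork zipper force-balance model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zipperkit.model import (
    AdhesionSchedule,
    NeuriteState,
    ZipperParams,
    combined_velocity,
    equilibrium_residual,
    fork_velocities,
    infer_differential_adhesion,
    simulate,
)
from zipperkit.kinematics import PositionSeries, finite_difference_velocity

forces = st.floats(0.0, 10.0, allow_nan=False)
etas = st.floats(0.1, 10.0, allow_nan=False)
thetas = st.floats(0.0, math.pi, allow_nan=False)
params_strategy = st.builds(
    ZipperParams,
    s_anterior=forces, s_posterior=forces,
    t_anterior=forces, t_posterior=forces,
    eta=etas, theta=thetas,
)


class TestForkVelocities:
    @pytest.mark.parametrize(
        "kwargs, expected_zip, expected_unzip",
        [
            # symmetric forces cancel fork-by-fork at theta = pi/2
            (dict(s_anterior=1, s_posterior=1, t_anterior=1, t_posterior=1,
                  eta=1, theta=math.pi / 2), 0.0, 0.0),
            # hand evaluation: 2 - 1*(1 - cos(pi/3)) = 1.5 and 0 - 0 = 0
            (dict(s_anterior=2, s_posterior=0, t_anterior=1, t_posterior=0,
                  eta=1, theta=math.pi / 3), 1.5, 0.0),
        ],
    )
    def test_hand_values(self, kwargs, expected_zip, expected_unzip):
        v_zip, v_unzip = fork_velocities(ZipperParams(**kwargs))
        assert v_zip == pytest.approx(expected_zip, abs=1e-12)
        assert v_unzip == pytest.approx(expected_unzip, abs=1e-12)

    def test_tension_term_vanishes_at_zero_angle(self):
        p = ZipperParams(s_anterior=2, s_posterior=1, t_anterior=7, t_posterior=3,
                         eta=1, theta=0.0)
        v_zip, v_unzip = fork_velocities(p)
        assert v_zip + v_unzip == pytest.approx(1.0, abs=1e-12)

    @given(params_strategy)
    @settings(max_examples=200, deadline=None)
    def test_sum_matches_combined_equation(self, p):
        v_zip, v_unzip = fork_velocities(p)
        expected = combined_velocity(p)
        assert v_zip + v_unzip == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @given(params_strategy, st.floats(0.1, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_adhesion_and_tension(self, p, delta):
        import dataclasses

        v0, _ = fork_velocities(p)
        up_s = dataclasses.replace(p, s_anterior=p.s_anterior + delta)
        assert fork_velocities(up_s)[0] >= v0
        up_t = dataclasses.replace(p, t_anterior=p.t_anterior + delta)
        assert fork_velocities(up_t)[0] <= v0

    def test_monotone_in_theta_with_tension(self):
        vals = [
            fork_velocities(ZipperParams(1, 0, t_anterior=2, theta=th))[0]
            for th in np.linspace(0, math.pi, 20)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(s_anterior=1, s_posterior=1, eta=0.0),
            dict(s_anterior=1, s_posterior=1, eta=-1.0),
            dict(s_anterior=1, s_posterior=1, theta=-0.1),
            dict(s_anterior=1, s_posterior=1, theta=math.pi + 0.1),
            dict(s_anterior=-1, s_posterior=1),
            dict(s_anterior=float("nan"), s_posterior=1),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ZipperParams(**kwargs)


class TestCombinedVelocity:
    def test_balanced_forces_give_zero(self):
        p = ZipperParams(1, 1, 3, 3, eta=2.0, theta=1.0)
        assert combined_velocity(p) == 0.0

    def test_hand_value(self):
        # dS=2, dT=1, theta=pi/3: 2 - 1*0.5 = 1.5
        p = ZipperParams(3, 1, 2, 1, eta=1.0, theta=math.pi / 3)
        assert combined_velocity(p) == pytest.approx(1.5, abs=1e-12)

    def test_linearity_in_inverse_friction(self):
        p1 = ZipperParams(3, 1, 2, 1, eta=1.0, theta=math.pi / 3)
        p2 = ZipperParams(3, 1, 2, 1, eta=2.0, theta=math.pi / 3)
        assert combined_velocity(p2) == pytest.approx(combined_velocity(p1) / 2)


class TestEquilibriumResidual:
    def test_balance_is_zero(self):
        # dS = dT (1 - cos theta): 0.5 = 1 * (1 - cos(pi/3))
        p = ZipperParams(1.5, 1.0, 2.0, 1.0, theta=math.pi / 3)
        assert equilibrium_residual(p) == pytest.approx(0.0, abs=1e-12)

    def test_pure_adhesion_difference(self):
        assert equilibrium_residual(ZipperParams(2, 1, 0, 0)) == pytest.approx(1.0)

    @given(params_strategy)
    @settings(max_examples=200, deadline=None)
    def test_sign_matches_combined_velocity(self, p):
        r = equilibrium_residual(p)
        v = combined_velocity(p) * p.eta
        assert r == pytest.approx(v, rel=1e-9, abs=1e-9)


class TestSimulate:
    def test_constant_velocity_is_exact(self):
        # v_zip = 0.1, v_unzip = 0.1 at theta=pi/2 with unit tensions
        p = ZipperParams(1.1, 0.9, 1.0, 1.0)
        init = NeuriteState(0.0, 0.0, 10.0, 0.0)
        traj = simulate(p, init, dt=1.0, t_end=40.0)
        assert np.allclose(traj.l_anterior, 0.1 * traj.times, atol=1e-12)
        assert np.allclose(traj.l_posterior, 10.0 - 0.1 * traj.times, atol=1e-12)

    def test_equilibrium_is_fixed_point(self):
        # both fork velocities individually zero: at theta = pi the
        # geometric factor is exactly 2, so S = 2T balances each fork
        p = ZipperParams(2.0, 2.0, 1.0, 1.0, theta=math.pi)
        assert fork_velocities(p) == (0.0, 0.0)
        init = NeuriteState(0.0, 3.0, 4.0, 1.0)
        traj = simulate(p, init, dt=1.0, t_end=10.0)
        assert np.allclose(traj.l_anterior, 3.0)
        assert np.allclose(traj.l_posterior, 4.0)

    def test_linear_ramp_matches_arithmetic_series(self):
        # Euler with a linearly ramping v_zip: displacement after n steps is
        # the arithmetic series dt * sum of left-endpoint velocities.
        sched = AdhesionSchedule((0.0, 40.0), (1.0, 1.3))
        p = ZipperParams(1.0, 1.0, 1.0, 1.0)  # v_zip = s_ant(t) - 1
        init = NeuriteState(0.0, 0.0, 10.0, 0.0)
        dt = 2.0
        traj = simulate(p, init, dt=dt, t_end=40.0, schedule=sched)
        n = np.arange(len(traj.times))
        slope = 0.3 / 40.0
        expected = dt * (slope * dt) * n * (n - 1) / 2  # sum_{i<n} slope*(i*dt)*dt
        assert np.allclose(traj.l_anterior, expected, atol=1e-10)
        v = np.diff(traj.l_anterior) / dt
        assert np.all(np.diff(v) > 0)

    def test_midline_cap_halts_zippering(self):
        p = ZipperParams(1.2, 1.0, 1.0, 1.0)  # v_zip = 0.2
        init = NeuriteState(0.0, 0.0, 10.0, 0.0)
        traj = simulate(p, init, dt=1.0, t_end=50.0, midline_cap=5.0)
        assert traj.l_anterior.max() == pytest.approx(5.0)
        assert traj.l_anterior[-1] == pytest.approx(5.0)

    def test_length_conservation(self):
        p = ZipperParams(1.15, 0.95, 1.0, 1.0)
        init = NeuriteState(0.0, 2.0, 5.0, 3.0)
        traj = simulate(p, init, dt=0.5, t_end=30.0, conserve_length=True)
        totals = traj.l_anterior + traj.l_free + traj.l_posterior
        assert np.max(np.abs(totals - 10.0)) <= 1e-9

    def test_free_segment_exhaustion_truncates_zippering(self):
        # fast zippering, no unzippering: free segment runs out
        p = ZipperParams(2.0, 1.0, 1.0, 1.0)  # v_zip = 1, v_unzip = 0
        init = NeuriteState(0.0, 0.0, 5.0, 2.0)
        traj = simulate(p, init, dt=1.0, t_end=10.0, conserve_length=True)
        assert np.all(traj.l_free >= 0)
        assert traj.l_anterior[-1] == pytest.approx(2.0)  # capped by free length
        assert np.max(np.abs(traj.l_anterior + traj.l_free + traj.l_posterior - 7.0)) <= 1e-9

    def test_negative_length_clamped(self):
        p = ZipperParams(0.0, 2.0, 0.0, 0.0)  # v_unzip ... s_post pulls back on
        # the unzippering fork: v_unzip = -2 (re-zippering), v_zip = 0
        init = NeuriteState(0.0, 1.0, 0.5, 0.0)
        # choose params so l_posterior would overshoot below zero
        p = ZipperParams(1.0, 0.0, 1.0, 2.0)  # v_unzip = 2, v_zip = 0
        traj = simulate(p, init, dt=1.0, t_end=3.0)
        assert np.all(traj.l_posterior >= 0)

    @pytest.mark.parametrize(
        "dt, t_end",
        [(0.0, 10.0), (-1.0, 10.0), (11.0, 10.0), (1.0, 0.0)],
    )
    def test_invalid_stepping_rejected(self, dt, t_end):
        p = ZipperParams(1.0, 1.0)
        with pytest.raises(ValueError):
            simulate(p, NeuriteState(0.0, 0.0, 1.0), dt=dt, t_end=t_end)


class TestInferDifferentialAdhesion:
    def test_noiseless_self_consistency(self):
        p = ZipperParams(1.15, 0.95, 1.0, 1.0)  # dS/eta = 0.2, dT = 0
        init = NeuriteState(0.0, 2.0, 5.0, 3.0)
        traj = simulate(p, init, dt=5.0, t_end=60.0)
        est = infer_differential_adhesion(*traj.position_series())
        assert est.aggregate == pytest.approx(0.2, abs=1e-12)
        assert est.direction == "anterior"

    def test_constant_series_give_zero(self):
        t = np.array([0.0, 5.0, 10.0])
        a = PositionSeries(t, np.full(3, 2.0), "anterior")
        b = PositionSeries(t, np.full(3, 5.0), "posterior")
        est = infer_differential_adhesion(a, b)
        assert est.aggregate == 0.0
        assert est.direction == "balanced"

    def test_unbiased_under_gaussian_noise(self):
        from zipperkit.synthetic import gen_trajectory

        truth = 0.2
        estimates = [
            infer_differential_adhesion(*gen_trajectory(seed=s).payload).aggregate
            for s in range(50)
        ]
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - truth) <= 2 * se + 1e-12

    def test_partial_time_grid_overlap_uses_common_stamps(self):
        t1 = np.array([0.0, 5.0, 10.0, 15.0])
        t2 = np.array([0.0, 10.0, 15.0, 20.0])
        a = PositionSeries(t1, 0.1 * t1, "anterior")
        b = PositionSeries(t2, 5.0 - 0.1 * t2, "posterior")
        est = infer_differential_adhesion(a, b)
        assert est.aggregate == pytest.approx(0.2, abs=1e-12)

    def test_errors(self):
        one_pt = PositionSeries(np.array([0.0]), np.array([1.0]), "anterior")
        two_pt = PositionSeries(np.array([0.0, 1.0]), np.array([1.0, 2.0]), "posterior")
        with pytest.raises(ValueError):
            infer_differential_adhesion(one_pt, two_pt)
        disjoint = PositionSeries(np.array([100.0, 101.0]), np.array([1.0, 2.0]), "posterior")
        a = PositionSeries(np.array([0.0, 1.0]), np.array([1.0, 2.0]), "anterior")
        with pytest.raises(ValueError):
            infer_differential_adhesion(a, disjoint)


class TestEqualDisplacement:
    def test_balanced_forks_move_equal_lengths(self):
        # v_zip = v_unzip = 0.1: zippered gain mirrors unzippered loss
        p = ZipperParams(1.1, 0.9, 1.0, 1.0)
        init = NeuriteState(0.0, 0.0, 5.0, 5.0)
        traj = simulate(p, init, dt=1.0, t_end=40.0, conserve_length=True)
        gains = traj.l_anterior - traj.l_anterior[0]
        losses = traj.l_posterior[0] - traj.l_posterior
        assert np.allclose(gains, losses, atol=1e-12)


class TestAdhesionSchedule:
    def test_interpolation_and_extrapolation(self):
        s = AdhesionSchedule((0.0, 10.0), (1.0, 2.0))
        assert s(5.0) == pytest.approx(1.5)
        assert s(-5.0) == 1.0 and s(20.0) == 2.0

    def test_validation(self):
        with pytest.raises(ValueError):
            AdhesionSchedule((0.0, 0.0), (1.0, 2.0))
        with pytest.raises(ValueError):
            AdhesionSchedule((0.0, 1.0), (1.0, -2.0))
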