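"""Extrapolated CoM, base of support, and margin-of-stability geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vrmaze_gait as vg
from vrmaze_gait.balance import (
    BoSRect,
    PendulumParams,
    base_of_support,
    com_ml_displacement,
    direction_of_progression,
    estimate_com_velocity,
    leg_length,
    mos_ml,
    summarize_balance,
    xcom,
)

from conftest import make_stream


def brute_force_mos(xcom_point, bos: BoSRect, n_samples=4000):
    """Oracle: densely sample the two ML border lines of the rectangle and
    take the minimum |projection on the ML axis| of (xcom - border point),
    signed by containment in the ML extent."""
    ap, ml = bos.axes
    h_ap, h_ml = bos.half_extents
    ts = np.linspace(-h_ap, h_ap, n_samples)
    dists = []
    for side in (+1, -1):
        border = bos.center + side * h_ml * ml + ts[:, None] * ap
        proj = np.abs((np.asarray(xcom_point) - border) @ ml)
        dists.append(proj.min())
    d = min(dists)
    c = float((np.asarray(xcom_point) - bos.center) @ ml)
    return d if abs(c) <= h_ml else -d


class TestXcom:
    def test_zero_velocity_returns_com_exactly(self):
        p = PendulumParams(l=0.9)
        u = np.array([0.3, -0.1])
        out = xcom(u, np.zeros(2), p)
        assert np.array_equal(out, u)

    def test_hand_evaluated_case(self):
        # l=0.98, g=9.8 -> omega0 = sqrt(10); u_dot=(3.1623, 0) -> offset ~1
        p = PendulumParams(l=0.98, g=9.8)
        assert p.omega0 == pytest.approx(np.sqrt(10.0), abs=1e-12)
        out = xcom(np.zeros(2), np.array([3.1623, 0.0]), p)
        assert out[0] == pytest.approx(1.0, abs=1e-4)
        assert out[1] == 0.0

    def test_offset_linear_in_velocity(self):
        p = PendulumParams(l=1.1)
        u = np.array([0.2, 0.4])
        v = np.array([0.5, -0.3])
        off1 = xcom(u, v, p) - u
        off2 = xcom(u, 2 * v, p) - u
        np.testing.assert_allclose(off2, 2 * off1, rtol=1e-12)

    def test_identity_offset_equals_vel_times_sqrt_l_over_g(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            l = rng.uniform(0.5, 1.3)
            u = rng.normal(size=2)
            v = rng.normal(size=2)
            p = PendulumParams(l=l)
            np.testing.assert_allclose(
                xcom(u, v, p) - u, v * np.sqrt(l / 9.8), atol=1e-9
            )

    def test_nonpositive_leg_length_fatal(self):
        with pytest.raises(ValueError):
            PendulumParams(l=0.0)


class TestComVelocity:
    def test_linear_trajectory(self):
        t = np.arange(0, 3, 1 / 90)
        xy = np.column_stack([1.3 * t, np.zeros(len(t))])
        navel = make_stream("navel", t, xy=xy, z=1.0)
        vel = estimate_com_velocity(navel)
        np.testing.assert_allclose(vel[:, 0], 1.3, atol=1e-6)
        np.testing.assert_allclose(vel[:, 1], 0.0, atol=1e-6)

    def test_stationary(self):
        t = np.arange(0, 2, 1 / 90)
        navel = make_stream("navel", t, z=1.0)
        np.testing.assert_allclose(estimate_com_velocity(navel), 0.0, atol=1e-9)

    def test_sinusoid_peak_speed(self):
        t = np.arange(0, 5, 1 / 90)
        A = 0.04
        xy = np.column_stack([A * np.sin(2 * np.pi * t), np.zeros(len(t))])
        navel = make_stream("navel", t, xy=xy, z=1.0)
        vel = estimate_com_velocity(navel)
        assert np.max(np.abs(vel[:, 0])) == pytest.approx(2 * np.pi * A, rel=0.02)


class TestLegLength:
    def test_constant_heights(self):
        t = np.arange(0, 1, 1 / 90)
        ankle = make_stream("left_ankle", t, z=0.1)
        navel = make_stream("navel", t, z=1.0)
        assert leg_length(ankle, navel) == pytest.approx(0.9)

    def test_median_robust_to_swing_excursions(self):
        t = np.arange(0, 4, 1 / 90)
        z = 0.1 + 0.12 * np.clip(np.sin(2 * np.pi * t), 0, None)  # swing lifts
        ankle = make_stream("left_ankle", t, z=0.1)
        ankle.pos[:, 2] = z
        navel = make_stream("navel", t, z=1.0)
        assert leg_length(ankle, navel) == pytest.approx(0.9, rel=0.02)

    def test_navel_below_ankle_fatal(self):
        t = np.arange(0, 1, 1 / 90)
        ankle = make_stream("left_ankle", t, z=1.0)
        navel = make_stream("navel", t, z=0.1)
        with pytest.raises(ValueError, match="below"):
            leg_length(ankle, navel)


class TestBaseOfSupport:
    def test_hand_union_of_two_footprints(self):
        bos = base_of_support(
            np.array([0.0, 0.1]), np.array([0.0, -0.1]), foot_dirs=(0.0, 0.0)
        )
        np.testing.assert_allclose(bos.half_extents, [0.125, 0.15], atol=1e-12)

    def test_coincident_feet_degrade_to_single_footprint(self):
        p = np.array([0.3, 0.2])
        bos = base_of_support(p, p, foot_dirs=(0.0, 0.0))
        np.testing.assert_allclose(bos.half_extents, [0.125, 0.05], atol=1e-12)

    def test_footprints_always_contained(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            lp = rng.normal(size=2)
            rp = lp + rng.normal(scale=0.3, size=2)
            dirs = tuple(rng.uniform(-180, 180, 2))
            bos = base_of_support(lp, rp, foot_dirs=dirs)
            for pos, h in ((lp, dirs[0]), (rp, dirs[1])):
                hrad = np.radians(h)
                fwd = np.array([np.cos(hrad), np.sin(hrad)])
                lat = np.array([-fwd[1], fwd[0]])
                for sa in (1, -1):
                    for sb in (1, -1):
                        corner = pos + sa * 0.125 * fwd + sb * 0.05 * lat
                        assert bos.contains(corner)


class TestMosMl:
    def test_boundary_inside_outside(self):
        bos = BoSRect(
            center=np.zeros(2), axes=np.eye(2), half_extents=np.array([0.2, 0.15])
        )
        assert mos_ml(np.array([0.0, 0.15]), bos) == pytest.approx(0.0, abs=1e-12)
        assert mos_ml(np.array([0.05, 0.10]), bos) == pytest.approx(0.05)
        assert mos_ml(np.array([0.0, 0.18]), bos) == pytest.approx(-0.03)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(500):
            theta = rng.uniform(0, 2 * np.pi)
            ap = np.array([np.cos(theta), np.sin(theta)])
            ml = np.array([-ap[1], ap[0]])
            bos = BoSRect(
                center=rng.normal(size=2),
                axes=np.vstack([ap, ml]),
                half_extents=rng.uniform(0.05, 0.4, 2),
            )
            point = bos.center + rng.normal(scale=0.3, size=2)
            assert mos_ml(point, bos) == pytest.approx(
                brute_force_mos(point, bos), abs=1e-6
            )

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([2.0, -1.0])
        bos = BoSRect(
            center=np.array([0.3, 0.1]),
            axes=np.eye(2),
            half_extents=np.array([0.2, 0.12]),
        )
        p = np.array([0.35, 0.18])
        moved = BoSRect(
            center=R @ bos.center + shift,
            axes=bos.axes @ R.T,
            half_extents=bos.half_extents,
        )
        assert mos_ml(R @ p + shift, moved) == pytest.approx(mos_ml(p, bos), abs=1e-12)


class TestDirectionAndDisplacement:
    def test_unit_direction_cases(self):
        np.testing.assert_allclose(
            direction_of_progression(np.zeros(2), np.array([1.0, 0.0])), [1, 0]
        )
        np.testing.assert_allclose(
            direction_of_progression(np.zeros(2), np.array([1.0, 1.0])),
            [np.sqrt(2) / 2, np.sqrt(2) / 2],
        )

    def test_zero_displacement_flagged(self):
        with pytest.raises(ValueError):
            direction_of_progression(np.zeros(2), np.zeros(2) + 1e-9)

    def test_collinear_trajectory_zero_deviation(self):
        traj = np.column_stack([np.linspace(0, 2, 50), np.zeros(50)])
        assert com_ml_displacement(traj, np.array([1.0, 0.0])) == 0.0

    def test_half_sine_bow_amplitude(self):
        x = np.linspace(0, 1, 400)
        traj = np.column_stack([x, 0.04 * np.sin(np.pi * x)])
        assert com_ml_displacement(traj, np.array([1.0, 0.0])) == pytest.approx(
            0.04, abs=1e-4
        )

    @given(st.floats(0, 2 * np.pi))
    @settings(max_examples=25, deadline=None)
    def test_rotation_invariance(self, theta):
        x = np.linspace(0, 1, 100)
        traj = np.column_stack([x, 0.03 * np.sin(np.pi * x)])
        dop = np.array([1.0, 0.0])
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = traj @ R.T
        assert com_ml_displacement(rotated, R @ dop) == pytest.approx(
            com_ml_displacement(traj, dop), abs=1e-9
        )


class TestSessionBalance:
    def test_zero_noise_sway_recovered(self, zero_noise_walk):
        session, truth = zero_noise_walk
        analysis = vg.analyze_session(session)
        assert analysis.balance.com_ml_mean == pytest.approx(
            truth.profile.com_sway_amp, rel=0.05
        )

    def test_identical_cycles_have_zero_cov(self):
        from vrmaze_gait.balance import BalanceCycle

        cycles = [
            BalanceCycle("left", float(i), np.array([1.0, 0]), 0.04, 0.05, "straight")
            for i in range(4)
        ]
        summary = summarize_balance(cycles)
        assert summary.com_ml_cov == 0.0
        assert summary.mos_ml_mean == pytest.approx(0.05)

    def test_wall_profile_sways_less_than_no_wall(self):
        from dataclasses import replace

        means = {}
        for cond in ("no_wall", "wall"):
            vals = []
            for seed in range(4):
                maze = vg.generate_maze(seed=seed)
                prof = replace(vg.default_profile(cond), seed=seed)
                sess, _ = vg.simulate_walk(maze, prof, condition=cond)
                vals.append(vg.analyze_session(sess).balance.com_ml_mean)
            means[cond] = np.nanmean(vals)
        assert means["wall"] < means["no_wall"]
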