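"""Synthetic walker, cohort, and study generators."""

from dataclasses import replace

import numpy as np
import pytest

import vrmaze_gait as vg
from vrmaze_gait.cohort import SCORE_COLUMNS
from vrmaze_gait.simulate import (
    GaitProfile,
    default_profile,
    generate_cohort,
    normalize_planted_effects,
    simulate_study,
    simulate_walk,
)


class TestProfiles:
    def test_wall_condition_direction_of_effects(self):
        nw, w = default_profile("no_wall"), default_profile("wall")
        assert w.stride_length_mean < nw.stride_length_mean
        assert w.stride_time_mean > nw.stride_time_mean
        assert w.com_sway_amp < nw.com_sway_amp
        # larger *relative* variability under walls
        assert (
            w.stride_length_sd / w.stride_length_mean
            > nw.stride_length_sd / nw.stride_length_mean
        )
        assert (
            w.stride_time_sd / w.stride_time_mean
            > nw.stride_time_sd / nw.stride_time_mean
        )

    def test_unknown_condition_fatal(self):
        with pytest.raises(ValueError):
            default_profile("glass_wall")

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            GaitProfile(
                stride_length_mean=-1,
                stride_length_sd=0,
                stride_time_mean=1,
                stride_time_sd=0,
                stride_width_mean=0.1,
                stride_width_sd=0,
                stance_fraction=0.6,
                com_sway_amp=0.04,
            )


class TestWalker:
    def test_same_seed_bit_identical(self, default_maze):
        prof = replace(default_profile("no_wall"), seed=42)
        s1, _ = simulate_walk(default_maze, prof)
        s2, _ = simulate_walk(default_maze, prof)
        for tid in s1.streams:
            assert np.array_equal(s1.streams[tid].t, s2.streams[tid].t)
            assert np.array_equal(s1.streams[tid].pos, s2.streams[tid].pos)
            assert np.array_equal(s1.streams[tid].quat, s2.streams[tid].quat)

    def test_nominal_rate_is_ninety(self, zero_noise_walk):
        session, _ = zero_noise_walk
        for stream in session.streams.values():
            assert stream.nominal_rate == 90.0
            assert np.median(np.diff(stream.t)) == pytest.approx(1 / 90)

    def test_overlong_stride_fatal(self, default_maze):
        prof = replace(default_profile("no_wall"), stride_length_mean=1.2)
        with pytest.raises(ValueError, match="block"):
            simulate_walk(default_maze, prof)

    def test_ground_truth_internal_consistency(self, zero_noise_walk):
        _, truth = zero_noise_walk
        st = truth.strides
        np.testing.assert_allclose(st["velocity"], st["length"] / st["time"], rtol=0)
        for side in ("left", "right"):
            ev = [e for e in truth.events if e.side == side]
            kinds = [e.kind for e in ev]
            assert all(a != b for a, b in zip(kinds, kinds[1:]))
            n_hs = sum(k == "heel_strike" for k in kinds)
            assert n_hs == (st["side"] == side).sum() + 1

    def test_dropouts_recorded_as_gaps(self, default_maze):
        prof = replace(default_profile("no_wall"), dropout_rate=20.0, seed=3)
        session, _ = simulate_walk(default_maze, prof)
        assert sum(len(s.gaps) for s in session.streams.values()) > 0


class TestCohort:
    def test_score_moments_match_population(self):
        df = generate_cohort(10000, seed=0, include_outcomes=False)
        assert df["tmt_a"].mean() == pytest.approx(37.7, rel=0.02)
        assert df["tmt_a"].std() == pytest.approx(13.4, rel=0.05)

    def test_scores_respect_instrument_bounds(self):
        df = generate_cohort(5000, seed=1, include_outcomes=False)
        assert df["porteus_maze"].between(0, 17).all()
        assert df["dsst"].between(0, 93).all()
        assert (df["age"] >= 60).all()

    def test_same_seed_identical(self):
        a = generate_cohort(50, seed=7)
        b = generate_cohort(50, seed=7)
        assert a.equals(b)

    def test_unknown_test_name_fatal(self):
        with pytest.raises(ValueError, match="unknown cognitive test"):
            generate_cohort(10, seed=0, planted_effects={("stride_velocity", "nope"): 0.1})

    def test_unknown_outcome_fatal(self):
        with pytest.raises(ValueError, match="unknown outcome"):
            normalize_planted_effects({("not_an_outcome", "tmt_a"): 0.1})


class TestStudy:
    def test_bookkeeping_twelve_sessions_for_three_subjects(self):
        study = simulate_study(3, seed=0, mode="kinematic")
        assert len(study.sessions) == 12
        labels = {(s.subject_id, s.condition, s.visit) for s, _ in study.sessions}
        assert len(labels) == 12
        # same maze across visits within a condition, different across conditions
        by_subj = {}
        for s, _ in study.sessions:
            by_subj.setdefault(s.subject_id, {}).setdefault(s.condition, set()).add(s.maze_id)
        for conds in by_subj.values():
            assert len(conds["no_wall"]) == 1
            assert len(conds["wall"]) == 1
            assert conds["no_wall"] != conds["wall"]

    def test_learning_effect_delayed_strides_longer_and_faster(self):
        study = simulate_study(40, seed=1, mode="summary")
        g = study.long.groupby("visit")[["stride_length", "stride_velocity"]].mean()
        assert g.loc["delayed", "stride_length"] > g.loc["immediate", "stride_length"]
        assert g.loc["delayed", "stride_velocity"] > g.loc["immediate", "stride_velocity"]

    def test_wall_condition_completion_times_higher(self):
        study = simulate_study(40, seed=2, mode="summary")
        g = study.long.groupby("condition")["completion_time"].mean()
        assert g["wall"] > g["no_wall"]

    def test_summary_and_kinematic_modes_agree_on_condition_ordering(self):
        ks = simulate_study(2, seed=3, mode="kinematic")
        long = vg.study_long_table(ks.sessions, mazes=ks.mazes)
        g = long.groupby("condition")[["stride_length", "stride_velocity"]].mean()
        assert g.loc["wall", "stride_length"] < g.loc["no_wall", "stride_length"]
        assert g.loc["wall", "stride_velocity"] < g.loc["no_wall", "stride_velocity"]

    def test_invalid_n_fatal(self):
        with pytest.raises(ValueError):
            simulate_study(0, seed=0)


class TestRecovery:
    def test_zero_noise_full_pipeline_recovers_profile(self, default_maze):
        prof = replace(
            default_profile("no_wall"),
            stride_length_sd=0.0,
            stride_time_sd=0.0,
            stride_width_sd=0.0,
            noise_sd_pos=0.0,
            noise_sd_angle=0.0,
            seed=5,
        )
        session, truth = simulate_walk(default_maze, prof)
        analysis = vg.analyze_session(session, maze=default_maze)
        truths = {
            "length": prof.stride_length_mean,
            "width": prof.stride_width_mean,
            "time": prof.stride_time_mean,
            "velocity": prof.stride_length_mean / prof.stride_time_mean,
            "stance_pct": 100 * prof.stance_fraction,
        }
        for key, expected in truths.items():
            assert analysis.gait.means[key] == pytest.approx(expected, rel=0.02), key
        assert analysis.completion_time == pytest.approx(truth.completion_time, abs=0.3)

    def test_default_noise_recovery_within_five_percent(self):
        rel_errs = []
        for seed in range(5):
            maze = vg.generate_maze(seed=seed)
            prof = replace(default_profile("no_wall"), seed=seed + 50)
            session, _ = simulate_walk(maze, prof)
            analysis = vg.analyze_session(session, maze=maze)
            for key, expected in (
                ("length", prof.stride_length_mean),
                ("time", prof.stride_time_mean),
                ("velocity", prof.stride_length_mean / prof.stride_time_mean),
            ):
                rel_errs.append(abs(analysis.gait.means[key] - expected) / expected)
        assert np.mean(rel_errs) < 0.05
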