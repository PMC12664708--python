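"""Synthetic walker, cohort, and study generators with known ground truth.

This module replaces the unavailable human dataset.  It simulates

* 90 Hz tracker streams (two ankles + navel) of a walker traversing a
  grid maze, with configurable stride statistics, turning slowdown,
  mediolateral CoM sway, sensor noise and dropouts, plus the full
  ground truth (events, per-stride parameters, per-cycle sway,
  completion time) needed for recovery testing;
* cohorts of covariates and neuropsychological scores drawn from
  truncated normals matching the study population, with optional
  planted linear gait–cognition effects;
* whole studies (2 conditions × 2 visits per subject) either as full
  kinematic sessions or as outcome-level summary tables for
  Monte-Carlo work.

The ankle orientation encodes a shank-angle waveform α(t) built from
raised-cosine arcs: α = 90° when standing, dips to 75° at each heel
strike and peaks at 105° at each toe-off, so heel strikes are exactly
the local minima and toe-offs the local maxima, as the event detector
assumes.  Planted cognition effects enter through the gait profiles
(the data-generating process), not post hoc on summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import truncnorm

from .cohort import (
    DEMOGRAPHICS,
    OUTCOME_COLUMNS,
    P_MALE,
    SCORE_COLUMNS,
    SCORE_MEANS,
    SCORE_SPECS,
)
from .maze import Maze, generate_maze, solution_path
from .session import DEFAULT_RATE_HZ, Session, TrackerStream, drop_samples
from .strides import STRAIGHT, TURN, _perp_distance, cov, wrap_angle_deg

ALPHA_STAND_DEG = 90.0
ALPHA_HS_DEG = 75.0
ALPHA_TO_DEG = 105.0
ANKLE_HEIGHT_M = 0.10
NAVEL_HEIGHT_M = 1.00
SWING_LIFT_M = 0.08
LEADIN_S = 0.30  # shank-angle transition into the first / out of the last heel strike

#: nominal solution-path length of the default maze, used by summary mode
SUMMARY_PATH_LENGTH_M = 10.6

#: wandering multipliers mapping pure walking time to completion time, by
#: (condition, visit); wall-condition navigation involves far more searching
WANDER_FACTOR = {
    ("no_wall", "immediate"): 2.62,
    ("no_wall", "delayed"): 2.56,
    ("wall", "immediate"): 3.95,
    ("wall", "delayed"): 3.25,
}
WANDER_LOG_SD = {"no_wall": 0.35, "wall": 0.55}
MOS_BASE = {"no_wall": 0.048, "wall": 0.054}

#: between-subject SDs of the gait-profile random effects
SUBJECT_SD = {
    "length": 0.06,
    "time": 0.045,
    "width": 0.015,
    "sway": 0.007,
    "stance": 0.008,
    "mos": 0.012,
    "wander": 0.20,
}

#: visit learning effect: additive shifts applied on the delayed visit,
#: identical in both conditions (hence no condition × visit interaction)
LEARNING_LENGTH_M = 0.04
LEARNING_TIME_S = -0.03

PROFILE_OUTCOMES = ("stride_length", "stride_time", "stride_velocity", "com_ml", "stance_pct")


@dataclass
class GaitProfile:
    """Stride statistics and noise settings of one walker.

    ``com_sway_amp`` is the ground-truth per-cycle mediolateral CoM
    deviation from the direction-of-progression line (m); internally the
    CoM oscillates ±com_sway_amp/2 about the path so that the deviation
    of the opposite-side sway peak from the DoP line equals the stated
    amplitude exactly.
    """

    stride_length_mean: float
    stride_length_sd: float
    stride_time_mean: float
    stride_time_sd: float
    stride_width_mean: float
    stride_width_sd: float
    stance_fraction: float
    com_sway_amp: float
    turn_slowdown_factor: float = 1.3
    noise_sd_pos: float = 0.0
    noise_sd_angle: float = 0.0
    dropout_rate: float = 0.0  # dropout events per minute
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("stride_length_mean", "stride_time_mean", "stride_width_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("stride_length_sd", "stride_time_sd", "stride_width_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0, 1)")


def default_profile(condition: str) -> GaitProfile:
    """Default walker profiles for the two wall conditions.

    The wall profile has smaller and more variable strides, longer
    stride times, larger stance fraction, narrower steps and less
    mediolateral sway than the no-wall profile, matching the observed
    direction of the wall effect.
    """
    if condition == "no_wall":
        return GaitProfile(
            stride_length_mean=1.10,
            stride_length_sd=0.050,
            stride_time_mean=1.06,
            stride_time_sd=0.040,
            stride_width_mean=0.120,
            stride_width_sd=0.020,
            stance_fraction=0.62,
            com_sway_amp=0.045,
            turn_slowdown_factor=1.3,
            noise_sd_pos=0.003,
            noise_sd_angle=1.0,
        )
    if condition == "wall":
        return GaitProfile(
            stride_length_mean=0.92,
            stride_length_sd=0.055,
            stride_time_mean=1.22,
            stride_time_sd=0.060,
            stride_width_mean=0.095,
            stride_width_sd=0.021,
            stance_fraction=0.66,
            com_sway_amp=0.032,
            turn_slowdown_factor=1.4,
            noise_sd_pos=0.003,
            noise_sd_angle=1.0,
        )
    raise ValueError(f"unknown condition {condition!r}")


@dataclass(frozen=True)
class TrueEvent:
    side: str
    kind: str  # "heel_strike" | "toe_off"
    t: float


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    events: list[TrueEvent]
    strides: pd.DataFrame  # side, t0, t1, length, time, velocity, stance_pct, width, label
    cycles: pd.DataFrame  # side, t0, t1, com_ml, label
    com_t: np.ndarray
    com_xy: np.ndarray
    completion_time: float
    profile: GaitProfile


# ---------------------------------------------------------------------------
# kinematic walker


def _polyline_geometry(path: np.ndarray):
    seg = np.diff(path, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    vertex_s = np.concatenate([[0.0], np.cumsum(seglen)])
    tangents = seg / seglen[:, None]
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)  # left of travel
    # corners = interior vertices where the travel direction actually changes
    turn_idx = [
        k
        for k in range(1, len(seglen))
        if abs(wrap_angle_deg(_seg_heading(tangents[k]) - _seg_heading(tangents[k - 1]))) > 1.0
    ]
    corner_s = vertex_s[turn_idx] if turn_idx else np.array([])
    return seglen, vertex_s, tangents, normals, corner_s


def _seg_heading(tangent: np.ndarray) -> float:
    return float(np.degrees(np.arctan2(tangent[1], tangent[0])))


def _point_at(s, path, vertex_s):
    x = np.interp(s, vertex_s, path[:, 0])
    y = np.interp(s, vertex_s, path[:, 1])
    return np.stack(np.broadcast_arrays(x, y), axis=-1)


def _normal_at(s, vertex_s, normals, corner_s, blend: float = 0.10):
    """Left normal of the path at arclength ``s``, blended near corners so
    the laterally offset CoM trajectory stays continuous."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    idx = np.clip(np.searchsorted(vertex_s, s, side="right") - 1, 0, len(normals) - 1)
    n = normals[idx].astype(float).copy()
    for vs in corner_s:
        k = int(np.searchsorted(vertex_s, vs))
        w = np.clip((s - (vs - blend)) / (2 * blend), 0.0, 1.0)
        mixed = (w > 0) & (w < 1)
        if mixed.any():
            n[mixed] = (1 - w[mixed, None]) * normals[k - 1] + w[mixed, None] * normals[k]
    nrm = np.hypot(n[:, 0], n[:, 1])
    nrm[nrm < 1e-9] = 1.0
    return n / nrm[:, None]


def _quat_from_heading_alpha(heading_deg: np.ndarray, alpha_deg: np.ndarray) -> np.ndarray:
    """Quaternions (w,x,y,z) whose rotated local x-axis has the given
    horizontal heading and angle α from global Z."""
    psi = np.radians(heading_deg)
    al = np.radians(alpha_deg)
    sa, ca = np.sin(al), np.cos(al)
    x_img = np.stack([sa * np.cos(psi), sa * np.sin(psi), ca], axis=1)
    y_img = np.stack([-np.sin(psi), np.cos(psi), np.zeros_like(psi)], axis=1)
    z_img = np.cross(x_img, y_img)
    mats = np.stack([x_img, y_img, z_img], axis=2)  # columns are image vectors
    return Rotation.from_matrix(mats).as_quat(scalar_first=True)


def _interp_heading(h0: float, h1: float, u: np.ndarray) -> np.ndarray:
    return h0 + wrap_angle_deg(h1 - h0) * u


def simulate_walk(
    maze: Maze,
    profile: GaitProfile,
    condition: str = "no_wall",
    visit: str = "immediate",
    subject_id: str = "sim",
    rate: float = DEFAULT_RATE_HZ,
) -> tuple[Session, GroundTruth]:
    """Simulate one maze traversal; returns the session and its ground truth.

    Heel-strike positions are laid along the maze solution path with
    alternating lateral offsets of ± half the stride width; per-step
    lengths and durations are drawn from the profile (halved, since two
    steps make a stride).  Steps whose arc interval crosses a path
    corner are turn steps: their duration is multiplied by the turn
    slowdown factor and their ground-truth label is ``turn``.
    Deterministic for a fixed profile seed.
    """
    if profile.stride_length_mean > 2 * maze.block_size:
        raise ValueError(
            f"stride length {profile.stride_length_mean} m exceeds twice the block "
            f"size ({maze.block_size} m); the walker cannot negotiate corners"
        )
    rng = np.random.default_rng(profile.seed)
    path = solution_path(maze)
    orig_s = float(np.sum(np.hypot(*np.diff(path, axis=0).T)))
    # extend the path one stride past the exit so terminal strides are not
    # clipped at the maze boundary (the walker walks out through the exit)
    last_dir = path[-1] - path[-2]
    last_dir = last_dir / np.hypot(*last_dir)
    path = np.vstack([path, path[-1] + last_dir * 2 * profile.stride_length_mean])
    seglen, vertex_s, tangents, normals, corner_s = _polyline_geometry(path)
    total_s = float(vertex_s[-1])

    def seg_index(s: float) -> int:
        return int(np.clip(np.searchsorted(vertex_s, s, side="right") - 1, 0, len(seglen) - 1))

    seg_heading = np.degrees(np.arctan2(tangents[:, 1], tangents[:, 0]))

    # --- step sequence: alternating feet along the path ---------------------
    # A step crossing a corner lands just past it (a pivot step) and the next
    # step stops short of any further corner, so no stride spans two corners:
    # straight strides then have exactly zero true heading deviation.
    pivot_land = 0.18
    t_stand = 1.0  # quiet standing before the first heel strike
    step_t = [t_stand]
    step_s = [0.0]
    step_side = [0]  # 0=left, 1=right
    step_turn = [False]
    stop_s = orig_s + profile.stride_length_mean
    prev_crossed = False
    while step_s[-1] < stop_s:
        half_len = rng.normal(profile.stride_length_mean / 2, profile.stride_length_sd / 2)
        half_len = max(half_len, 0.1 * profile.stride_length_mean / 2)
        half_t = rng.normal(profile.stride_time_mean / 2, profile.stride_time_sd / 2)
        half_t = max(half_t, 0.1 * profile.stride_time_mean / 2)
        s_prev = step_s[-1]
        s_next = min(s_prev + half_len, total_s - 0.05)

        def corners_in(a: float, b: float) -> np.ndarray:
            return corner_s[(corner_s > a) & (corner_s <= b)] if len(corner_s) else corner_s

        ahead = corners_in(s_prev, s_next)
        if prev_crossed and len(ahead):
            s_next = max(s_prev + 0.05, float(ahead[0]) - 0.02)
        elif len(ahead):
            s_next = min(s_next, float(ahead[0]) + pivot_land)
        ahead = corners_in(s_prev, s_next)
        is_turn = len(ahead) > 0
        if is_turn:
            half_t *= profile.turn_slowdown_factor
        prev_crossed = is_turn
        step_t.append(step_t[-1] + half_t)
        step_s.append(s_next)
        step_side.append(1 - step_side[-1])
        step_turn.append(is_turn)
        if s_next >= total_s - 0.05:
            break
    step_t = np.array(step_t)
    step_s = np.array(step_s)
    step_side = np.array(step_side)
    n_steps = len(step_t)

    half_widths = np.abs(rng.normal(profile.stride_width_mean / 2, profile.stride_width_sd / 2, n_steps))
    side_sign = np.where(step_side == 0, 1.0, -1.0)  # left foot left of travel
    step_heading_deg = np.array([seg_heading[seg_index(s)] for s in step_s])
    step_pos = _point_at(step_s, path, vertex_s) + (
        normals[[seg_index(s) for s in step_s]] * (side_sign * half_widths)[:, None]
    )

    duration = float(step_t[-1]) + 1.5
    t_grid = np.arange(0.0, duration, 1.0 / rate)
    n = len(t_grid)

    # --- per-foot ankle trajectories and shank-angle waveform ---------------
    streams: dict[str, TrackerStream] = {}
    per_side_truth: dict[str, dict] = {}
    for side_code, side_name in ((0, "left"), (1, "right")):
        k_idx = np.nonzero(step_side == side_code)[0]
        hs_t = step_t[k_idx]
        hs_pos = step_pos[k_idx]
        hs_head = step_heading_deg[k_idx]
        to_t = hs_t[:-1] + profile.stance_fraction * np.diff(hs_t)

        xy = np.empty((n, 2))
        z = np.full(n, ANKLE_HEIGHT_M)
        alpha = np.full(n, ALPHA_STAND_DEG)
        heading = np.empty(n)
        xy[:] = hs_pos[0]
        heading[:] = hs_head[0]

        # lead-in: standing angle eases down into the first heel strike
        m = (t_grid >= hs_t[0] - LEADIN_S) & (t_grid < hs_t[0])
        u = (t_grid[m] - (hs_t[0] - LEADIN_S)) / LEADIN_S
        alpha[m] = ALPHA_STAND_DEG + (ALPHA_HS_DEG - ALPHA_STAND_DEG) * 0.5 * (1 - np.cos(np.pi * u))

        for j in range(len(hs_t) - 1):
            t0, t1, tt = hs_t[j], hs_t[j + 1], to_t[j]
            stance = (t_grid >= t0) & (t_grid < tt)
            swing = (t_grid >= tt) & (t_grid < t1)
            xy[stance] = hs_pos[j]
            heading[stance] = hs_head[j]
            u = (t_grid[swing] - tt) / (t1 - tt)
            smooth = 3 * u**2 - 2 * u**3
            xy[swing] = hs_pos[j] + smooth[:, None] * (hs_pos[j + 1] - hs_pos[j])
            z[swing] = ANKLE_HEIGHT_M + SWING_LIFT_M * np.sin(np.pi * u)
            heading[swing] = _interp_heading(hs_head[j], hs_head[j + 1], u)
            # raised-cosine alpha: min at heel strikes, max at toe-off
            ur = (t_grid[stance] - t0) / (tt - t0)
            alpha[stance] = ALPHA_HS_DEG + (ALPHA_TO_DEG - ALPHA_HS_DEG) * 0.5 * (1 - np.cos(np.pi * ur))
            alpha[swing] = ALPHA_TO_DEG + (ALPHA_HS_DEG - ALPHA_TO_DEG) * 0.5 * (1 - np.cos(np.pi * u))

        after = t_grid >= hs_t[-1]
        xy[after] = hs_pos[-1]
        heading[after] = hs_head[-1]
        m = (t_grid >= hs_t[-1]) & (t_grid < hs_t[-1] + LEADIN_S)
        u = (t_grid[m] - hs_t[-1]) / LEADIN_S
        alpha[m] = ALPHA_HS_DEG + (ALPHA_STAND_DEG - ALPHA_HS_DEG) * 0.5 * (1 - np.cos(np.pi * u))
        alpha[t_grid >= hs_t[-1] + LEADIN_S] = ALPHA_STAND_DEG

        alpha_noisy = alpha + rng.normal(0, profile.noise_sd_angle, n)
        heading_noisy = heading + rng.normal(0, profile.noise_sd_angle, n)
        quat = _quat_from_heading_alpha(heading_noisy, np.clip(alpha_noisy, 1.0, 179.0))
        pos = np.column_stack([xy, z]) + rng.normal(0, profile.noise_sd_pos, (n, 3))
        streams[f"{side_name}_ankle"] = TrackerStream(
            tracker_id=f"{side_name}_ankle", t=t_grid.copy(), pos=pos, quat=quat, nominal_rate=rate
        )
        per_side_truth[side_name] = {"hs_t": hs_t, "hs_pos": hs_pos, "to_t": to_t, "k_idx": k_idx}

    # --- navel (CoM) stream --------------------------------------------------
    s_com = np.interp(t_grid, step_t, step_s)
    sway_amp = profile.com_sway_amp / 2.0
    offset = np.empty(n)
    offset[t_grid < step_t[0]] = sway_amp * side_sign[0]
    for k in range(n_steps - 1):
        m = (t_grid >= step_t[k]) & (t_grid < step_t[k + 1])
        u = (t_grid[m] - step_t[k]) / (step_t[k + 1] - step_t[k])
        offset[m] = sway_amp * side_sign[k] * np.cos(np.pi * u)
    offset[t_grid >= step_t[-1]] = sway_amp * side_sign[-1]
    com_xy = (
        _point_at(s_com, path, vertex_s)
        + _normal_at(s_com, vertex_s, normals, corner_s) * offset[:, None]
    )
    navel_pos = np.column_stack([com_xy, np.full(n, NAVEL_HEIGHT_M)])
    navel_pos_noisy = navel_pos + rng.normal(0, profile.noise_sd_pos, (n, 3))
    # navel tracker x-axis points upward
    navel_quat = np.tile(
        Rotation.from_matrix(
            np.array([[0.0, 0.0, -1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
        ).as_quat(scalar_first=True),
        (n, 1),
    )
    streams["navel"] = TrackerStream(
        tracker_id="navel", t=t_grid.copy(), pos=navel_pos_noisy, quat=navel_quat, nominal_rate=rate
    )

    session = Session(
        subject_id=subject_id,
        condition=condition,
        visit=visit,
        streams=streams,
        maze_id=maze.maze_id,
    )

    # --- dropouts -------------------------------------------------------------
    if profile.dropout_rate > 0:
        n_drop = rng.poisson(profile.dropout_rate * duration / 60.0)
        for _ in range(n_drop):
            tid = list(streams)[int(rng.integers(3))]
            t0 = rng.uniform(t_stand, duration - 1.0)
            session.streams[tid] = drop_samples(
                session.streams[tid], t0, t0 + rng.uniform(0.2, 0.6)
            )

    # --- ground truth ---------------------------------------------------------
    events: list[TrueEvent] = []
    stride_rows = []
    cycle_rows = []
    for side_name in ("left", "right"):
        tr = per_side_truth[side_name]
        hs_t, hs_pos, to_t, k_idx = tr["hs_t"], tr["hs_pos"], tr["to_t"], tr["k_idx"]
        for t in hs_t:
            events.append(TrueEvent(side_name, "heel_strike", float(t)))
        for t in to_t:
            events.append(TrueEvent(side_name, "toe_off", float(t)))
        contra_idx = np.nonzero(step_side != (0 if side_name == "left" else 1))[0]
        for j in range(len(hs_t) - 1):
            length = float(np.hypot(*(hs_pos[j + 1] - hs_pos[j])))
            time = float(hs_t[j + 1] - hs_t[j])
            s_lo, s_hi = step_s[k_idx[j]], step_s[k_idx[j + 1]]
            label = TURN if np.any((corner_s > s_lo) & (corner_s <= s_hi)) else STRAIGHT
            mids = [k for k in contra_idx if hs_t[j] < step_t[k] < hs_t[j + 1]]
            width = (
                _perp_distance(step_pos[mids[0]], hs_pos[j], hs_pos[j + 1])
                if len(mids) == 1
                else float("nan")
            )
            stride_rows.append(
                {
                    "side": side_name,
                    "t0": float(hs_t[j]),
                    "t1": float(hs_t[j + 1]),
                    "length": length,
                    "time": time,
                    "velocity": length / time,
                    "stance_pct": 100.0 * float(to_t[j] - hs_t[j]) / time,
                    "width": width,
                    "label": label,
                }
            )
            # true per-cycle CoM deviation from the DoP line
            m = (t_grid >= hs_t[j]) & (t_grid <= hs_t[j + 1])
            seg = com_xy[m]
            if len(seg) >= 2 and np.hypot(*(seg[-1] - seg[0])) > 1e-6:
                dop = (seg[-1] - seg[0]) / np.hypot(*(seg[-1] - seg[0]))
                rel = seg - seg[0]
                dev = np.abs(rel[:, 0] * dop[1] - rel[:, 1] * dop[0])
                cycle_rows.append(
                    {
                        "side": side_name,
                        "t0": float(hs_t[j]),
                        "t1": float(hs_t[j + 1]),
                        "com_ml": float(dev.max()),
                        "label": label,
                    }
                )
    events.sort(key=lambda e: e.t)
    b = maze.block_size
    s_exit = max(orig_s - b / 2.0, 0.0)
    truth_completion = float(np.interp(s_exit, step_s, step_t)) - float(t_grid[0])
    truth = GroundTruth(
        events=events,
        strides=pd.DataFrame(stride_rows).sort_values("t0").reset_index(drop=True),
        cycles=pd.DataFrame(cycle_rows).sort_values("t0").reset_index(drop=True),
        com_t=t_grid,
        com_xy=com_xy,
        completion_time=truth_completion,
        profile=profile,
    )
    return session, truth


# ---------------------------------------------------------------------------
# cohorts and planted effects


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a = (lo - mean) / sd if np.isfinite(lo) else -np.inf
    b = (hi - mean) / sd if np.isfinite(hi) else np.inf
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def normalize_planted_effects(
    planted_effects: Mapping | Iterable | None,
) -> list[tuple[str, str, str | None, float]]:
    """Normalize planted effects to (outcome, test, condition|None, slope).

    Accepts a mapping keyed by (outcome, test) or (outcome, test,
    condition), or an iterable of such tuples with the slope appended.
    """
    if not planted_effects:
        return []
    items = (
        [(k, v) for k, v in planted_effects.items()]
        if isinstance(planted_effects, Mapping)
        else [(tuple(e[:-1]), e[-1]) for e in planted_effects]
    )
    out = []
    for key, slope in items:
        if len(key) == 2:
            outcome, test = key
            condition = None
        elif len(key) == 3:
            outcome, test, condition = key
        else:
            raise ValueError(f"planted-effect key {key!r} must be (outcome, test[, condition])")
        if test not in SCORE_COLUMNS:
            raise ValueError(f"unknown cognitive test {test!r}; known: {SCORE_COLUMNS}")
        if outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"unknown outcome {outcome!r}; known: {OUTCOME_COLUMNS}")
        if condition is not None and condition not in ("no_wall", "wall"):
            raise ValueError(f"unknown condition {condition!r}")
        out.append((outcome, test, condition, float(slope)))
    return out


#: cohort-level outcome baselines (mean, between-subject SD) used when
#: generating outcome columns directly (single no-wall session equivalent)
OUTCOME_BASELINES = {
    "completion_time": (28.4, 10.9),
    "stride_length": (1.10, 0.10),
    "stride_width": (0.12, 0.03),
    "stride_time": (1.06, 0.08),
    "stride_velocity": (1.04, 0.12),
    "stance_pct": (62.0, 3.0),
    "stride_length_cov": (0.045, 0.015),
    "stride_width_cov": (0.18, 0.05),
    "stride_time_cov": (0.038, 0.012),
    "stride_velocity_cov": (0.055, 0.018),
    "stance_pct_cov": (0.020, 0.007),
    "mos_ml": (0.050, 0.015),
    "com_ml": (0.045, 0.012),
    "com_ml_cov": (0.10, 0.03),
}


def generate_cohort(
    n: int,
    seed: int | None = None,
    planted_effects: Mapping | Iterable | None = None,
    include_outcomes: bool = True,
) -> pd.DataFrame:
    """Generate a cohort of covariates, scores, and optional outcomes.

    Scores and demographics are truncated normals with the study
    population's means and SDs as parent parameters.  When
    ``include_outcomes`` is set, per-subject outcome columns are added
    as baseline + Σ slope·(score − population mean) + Gaussian noise, so
    planted effects are recoverable by covariate-adjusted regression.
    Condition-specific planted effects are applied unconditionally here
    (the cohort table is one stratum); use :func:`simulate_study` for
    condition-resolved data.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    effects = normalize_planted_effects(planted_effects)
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {"subject_id": np.array([f"S{i:04d}" for i in range(n)])}
    for name, (mean, sd, lo) in DEMOGRAPHICS.items():
        data[name] = _truncated_normal(rng, mean, sd, lo, np.inf, n)
    data["sex"] = np.where(rng.random(n) < P_MALE, "M", "F")
    for spec in SCORE_SPECS:
        data[spec.name] = _truncated_normal(rng, spec.mean, spec.sd, spec.lo, spec.hi, n)
    df = pd.DataFrame(data)
    if include_outcomes:
        for outcome, (mean, sd) in OUTCOME_BASELINES.items():
            vals = mean + rng.normal(0, sd, n)
            for o, test, _cond, slope in effects:
                if o == outcome:
                    vals = vals + slope * (df[test].to_numpy() - SCORE_MEANS[test])
            df[outcome] = vals
    return df


# ---------------------------------------------------------------------------
# whole-study simulation


@dataclass
class StudyData:
    """A simulated study: cohort, outcome long table, and (optionally)
    the full kinematic sessions with their ground truths."""

    cohort: pd.DataFrame
    long: pd.DataFrame
    sessions: list[tuple[Session, GroundTruth]] = field(default_factory=list)
    mazes: dict[str, Maze] = field(default_factory=dict)


def _effective_profile(
    base: GaitProfile,
    scores: Mapping[str, float],
    res: Mapping[str, float],
    effects: list[tuple[str, str, str | None, float]],
    condition: str,
    visit: str,
    interaction_effects: Mapping[str, float] | None,
) -> tuple[GaitProfile, dict[str, float]]:
    length = base.stride_length_mean + res["length"]
    time = base.stride_time_mean + res["time"]
    width = base.stride_width_mean + res["width"]
    sway = base.com_sway_amp + res["sway"]
    stance = base.stance_fraction + res["stance"]
    if visit == "delayed":
        length += LEARNING_LENGTH_M
        time += LEARNING_TIME_S
    shifts: dict[str, float] = {}

    def apply(outcome: str, delta: float) -> None:
        nonlocal length, time, sway, stance
        if outcome == "stride_length":
            length += delta
        elif outcome == "stride_time":
            time += delta
        elif outcome == "stride_velocity":
            length += delta * time
        elif outcome == "com_ml":
            sway += delta
        elif outcome == "stance_pct":
            stance += delta / 100.0
        else:
            shifts[outcome] = shifts.get(outcome, 0.0) + delta

    if interaction_effects and condition == "no_wall" and visit == "delayed":
        for outcome, delta in interaction_effects.items():
            apply(outcome, delta)
    for outcome, test, cond, slope in effects:
        if cond is not None and cond != condition:
            continue
        apply(outcome, slope * (scores[test] - SCORE_MEANS[test]))

    profile = replace(
        base,
        stride_length_mean=max(length, 0.3),
        stride_time_mean=max(time, 0.5),
        stride_width_mean=max(width, 0.02),
        com_sway_amp=max(sway, 0.005),
        stance_fraction=float(np.clip(stance, 0.45, 0.80)),
    )
    return profile, shifts


def _summary_session_row(
    profile: GaitProfile,
    shifts: Mapping[str, float],
    res: Mapping[str, float],
    condition: str,
    visit: str,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Analytic per-session outcome summary drawn from the profile truth.

    Per-stride values are drawn from the profile's stride distributions
    (the number of straight strides follows from the path length), then
    summarized exactly as the kinematic pipeline would (mean, sample-SD
    CoV), so sampling noise has the right magnitude without simulating
    90 Hz kinematics.
    """
    m = max(5, int(round(2 * SUMMARY_PATH_LENGTH_M / profile.stride_length_mean)) - 8)
    lengths = np.clip(rng.normal(profile.stride_length_mean, profile.stride_length_sd, m), 0.05, None)
    times = np.clip(rng.normal(profile.stride_time_mean, profile.stride_time_sd, m), 0.2, None)
    widths = np.abs(rng.normal(profile.stride_width_mean, profile.stride_width_sd, m))
    vels = lengths / times
    stance = rng.normal(100 * profile.stance_fraction, 1.0, m)
    com = np.clip(rng.normal(profile.com_sway_amp, 0.10 * profile.com_sway_amp, m), 1e-4, None)
    mos = rng.normal(MOS_BASE[condition] + res["mos"], 0.012, m)

    v_true = profile.stride_length_mean / profile.stride_time_mean
    walk_time = SUMMARY_PATH_LENGTH_M / v_true
    z = rng.normal(0, WANDER_LOG_SD[condition]) + res["wander"]
    completion = walk_time * WANDER_FACTOR[(condition, visit)] * float(np.exp(z))

    row = {
        "completion_time": completion,
        "stride_length": float(lengths.mean()),
        "stride_width": float(widths.mean()),
        "stride_time": float(times.mean()),
        "stride_velocity": float(vels.mean()),
        "stance_pct": float(stance.mean()),
        "stride_length_cov": cov(lengths),
        "stride_width_cov": cov(widths),
        "stride_time_cov": cov(times),
        "stride_velocity_cov": cov(vels),
        "stance_pct_cov": cov(stance),
        "mos_ml": float(mos.mean()),
        "com_ml": float(com.mean()),
        "com_ml_cov": cov(com),
    }
    for outcome, delta in shifts.items():
        row[outcome] = row.get(outcome, 0.0) + delta
    return row


def simulate_study(
    n: int,
    seed: int | None = None,
    planted_effects: Mapping | Iterable | None = None,
    interaction_effects: Mapping[str, float] | None = None,
    mode: str = "summary",
    maze_kwargs: Mapping | None = None,
) -> StudyData:
    """Simulate a full study: per subject, 2 conditions × 2 visits.

    Each subject reuses the same maze across visits within a condition
    and gets a different maze across conditions.  Subject-level random
    effects are shared across that subject's four sessions (the mixed
    model's random intercept); the delayed visit applies an additive
    learning effect (longer, faster strides) identical in both
    conditions; ``interaction_effects`` optionally adds outcome shifts
    in the no-wall delayed cell only, creating a condition × visit
    interaction.

    ``mode="summary"`` generates per-session outcome rows analytically
    from the ground-truth profiles (fast; for Monte-Carlo work);
    ``mode="kinematic"`` simulates full 90 Hz sessions and leaves the
    outcome table to the analysis pipeline.
    """
    if n < 1:
        raise ValueError("study must have at least 1 subject")
    if mode not in ("summary", "kinematic"):
        raise ValueError(f"unknown mode {mode!r}")
    effects = normalize_planted_effects(planted_effects)
    rng = np.random.default_rng(seed)
    cohort_df = generate_cohort(
        n, seed=int(rng.integers(2**31 - 1)), include_outcomes=False
    )

    rows = []
    sessions: list[tuple[Session, GroundTruth]] = []
    all_mazes: dict[str, Maze] = {}
    for i in range(n):
        subject = cohort_df.iloc[i]
        res = {name: rng.normal(0, sd) for name, sd in SUBJECT_SD.items()}
        mazes = {
            cond: generate_maze(seed=int(rng.integers(2**31 - 1)), **(maze_kwargs or {}))
            for cond in ("no_wall", "wall")
        }
        for mz in mazes.values():
            all_mazes[mz.maze_id] = mz
        for condition in ("no_wall", "wall"):
            for visit in ("immediate", "delayed"):
                profile, shifts = _effective_profile(
                    default_profile(condition),
                    subject,
                    res,
                    effects,
                    condition,
                    visit,
                    interaction_effects,
                )
                if mode == "summary":
                    row = _summary_session_row(profile, shifts, res, condition, visit, rng)
                    row.update(
                        subject_id=subject["subject_id"], condition=condition, visit=visit
                    )
                    rows.append(row)
                else:
                    cap = 1.9 * mazes[condition].block_size
                    profile = replace(
                        profile,
                        seed=int(rng.integers(2**31 - 1)),
                        stride_length_mean=min(profile.stride_length_mean, cap),
                    )
                    sess, truth = simulate_walk(
                        mazes[condition],
                        profile,
                        condition=condition,
                        visit=visit,
                        subject_id=str(subject["subject_id"]),
                    )
                    sessions.append((sess, truth))
    long = (
        pd.DataFrame(rows)[["subject_id", "condition", "visit", *OUTCOME_COLUMNS]]
        if rows
        else pd.DataFrame(columns=["subject_id", "condition", "visit", *OUTCOME_COLUMNS])
    )
    return StudyData(cohort=cohort_df, long=long, sessions=sessions, mazes=all_mazes)
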