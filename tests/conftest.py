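"""Shared fixtures: mazes, zero-noise walks, and synthetic stream builders."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import vrmaze_gait as vg
from vrmaze_gait.session import Session, TrackerStream


@pytest.fixture(scope="session")
def default_maze():
    return vg.generate_maze(seed=0)


@pytest.fixture(scope="session")
def zero_noise_profile():
    return replace(
        vg.default_profile("no_wall"),
        stride_length_sd=0.0,
        stride_time_sd=0.0,
        stride_width_sd=0.0,
        noise_sd_pos=0.0,
        noise_sd_angle=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def zero_noise_walk(default_maze, zero_noise_profile):
    """One deterministic zero-noise session with its ground truth."""
    return vg.simulate_walk(default_maze, zero_noise_profile)


def make_stream(
    tracker_id: str,
    t: np.ndarray,
    xy: np.ndarray | None = None,
    z: float = 0.1,
    heading_deg: float = 0.0,
    rate: float = 90.0,
) -> TrackerStream:
    """Stream with given planar positions and a constant horizontal x-axis."""
    t = np.asarray(t, dtype=float)
    n = len(t)
    if xy is None:
        xy = np.zeros((n, 2))
    pos = np.column_stack([np.asarray(xy, dtype=float), np.full(n, z)])
    quat = np.tile(
        Rotation.from_euler("z", heading_deg, degrees=True).as_quat(scalar_first=True), (n, 1)
    )
    return TrackerStream(tracker_id=tracker_id, t=t, pos=pos, quat=quat, nominal_rate=rate)


def make_session(left=None, right=None, navel=None, **meta) -> Session:
    t = np.array([0.0, 0.5, 1.0])
    streams = {
        "left_ankle": left if left is not None else make_stream("left_ankle", t),
        "right_ankle": right if right is not None else make_stream("right_ankle", t),
        "navel": navel if navel is not None else make_stream("navel", t, z=1.0),
    }
    meta.setdefault("subject_id", "T01")
    meta.setdefault("condition", "no_wall")
    meta.setdefault("visit", "immediate")
    return Session(streams=streams, **meta)
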