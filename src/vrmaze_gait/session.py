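"""Tracker-session data model and on-disk bundle format.

A recording session holds three 6-DoF tracker streams (left ankle, right
ankle, navel), each a time series of 3-D position (meters, right-handed
global frame with Z up) and unit-quaternion orientation (w, x, y, z,
rotating tracker-local axes into the global frame), nominally sampled at
90 Hz.  Dropouts — intervals where the tracker lost tracking — are
represented as half-open gap intervals on the time axis; strides that
overlap a gap are excluded from all downstream summaries.

On disk a session is a directory containing one CSV per tracker
(``t,px,py,pz,qw,qx,qy,qz``) plus a ``meta.json`` sidecar with subject,
condition, visit, maze id and nominal rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TRACKER_IDS = ("left_ankle", "right_ankle", "navel")
CONDITIONS = ("no_wall", "wall")
VISITS = ("immediate", "delayed")

DEFAULT_RATE_HZ = 90.0
#: inter-sample interval > max_gap_factor / nominal_rate counts as a dropout
DEFAULT_MAX_GAP_FACTOR = 3.0

_QUAT_NORM_TOL = 1e-6


class SessionError(ValueError):
    """Raised for invalid or inconsistent session data."""


@dataclass
class TrackerStream:
    """One tracker's time-ordered position + orientation series.

    Attributes
    ----------
    tracker_id : str
        One of ``left_ankle``, ``right_ankle``, ``navel``.
    t : ndarray, shape (n,)
        Seconds from session start, strictly increasing.
    pos : ndarray, shape (n, 3)
        Global-frame position in meters, Z up.
    quat : ndarray, shape (n, 4)
        Unit quaternions (w, x, y, z) rotating local axes into the
        global frame.
    nominal_rate : float
        Nominal sampling rate in Hz.
    gaps : list of (t_start, t_end)
        Half-open dropout intervals, sorted, non-overlapping.
    """

    tracker_id: str
    t: np.ndarray
    pos: np.ndarray
    quat: np.ndarray
    nominal_rate: float = DEFAULT_RATE_HZ
    gaps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float).reshape(len(self.t), 3)
        self.quat = np.asarray(self.quat, dtype=float).reshape(len(self.t), 4)
        self.validate()

    def __len__(self) -> int:
        return len(self.t)

    def validate(self) -> None:
        if self.tracker_id not in TRACKER_IDS:
            raise SessionError(f"unknown tracker_id {self.tracker_id!r}")
        if not np.all(np.isfinite(self.t)) or np.any(self.t < 0):
            raise SessionError(f"{self.tracker_id}: timestamps must be finite and non-negative")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            i = int(np.argmin(np.diff(self.t)))
            raise SessionError(f"{self.tracker_id}: non-monotone timestamps at index {i + 1}")
        norms = np.linalg.norm(self.quat, axis=1)
        bad = np.abs(norms - 1.0) > _QUAT_NORM_TOL
        if np.any(bad):
            i = int(np.argmax(bad))
            raise SessionError(
                f"{self.tracker_id}: quaternion norm {norms[i]:.8f} violates unit "
                f"constraint at sample {i}"
            )
        lo, hi = (self.t[0], self.t[-1]) if len(self.t) else (0.0, 0.0)
        for a, b in self.gaps:
            if not (lo <= a < b <= hi):
                raise SessionError(f"{self.tracker_id}: gap [{a}, {b}) outside stream span")

    def in_gap(self, times: np.ndarray | float) -> np.ndarray:
        """Boolean mask: which of ``times`` fall inside a dropout gap."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        mask = np.zeros(times.shape, dtype=bool)
        for a, b in self.gaps:
            mask |= (times >= a) & (times < b)
        return mask

    def sample_at(self, time: float) -> int:
        """Index of the sample closest in time to ``time``."""
        return int(np.argmin(np.abs(self.t - time)))


@dataclass
class Session:
    """Three tracker streams plus study metadata; the unit of analysis."""

    subject_id: str
    condition: str
    visit: str
    streams: dict[str, TrackerStream]
    maze_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise SessionError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.visit not in VISITS:
            raise SessionError(f"visit must be one of {VISITS}, got {self.visit!r}")
        missing = set(TRACKER_IDS) - set(self.streams)
        if missing:
            raise SessionError(f"session missing tracker stream(s): {sorted(missing)}")
        if set(self.streams) != set(TRACKER_IDS):
            extra = set(self.streams) - set(TRACKER_IDS)
            raise SessionError(f"unexpected tracker stream(s): {sorted(extra)}")
        if not self.session_id:
            self.session_id = f"{self.subject_id}_{self.condition}_{self.visit}"

    @property
    def left_ankle(self) -> TrackerStream:
        return self.streams["left_ankle"]

    @property
    def right_ankle(self) -> TrackerStream:
        return self.streams["right_ankle"]

    @property
    def navel(self) -> TrackerStream:
        return self.streams["navel"]

    @property
    def start_t(self) -> float:
        return min(s.t[0] for s in self.streams.values())

    @property
    def end_t(self) -> float:
        return max(s.t[-1] for s in self.streams.values())

    def all_gaps(self) -> list[tuple[float, float]]:
        """Union (as a sorted list) of the dropout gaps of all three streams."""
        gaps = sorted(g for s in self.streams.values() for g in s.gaps)
        merged: list[tuple[float, float]] = []
        for a, b in gaps:
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        return merged


def detect_dropouts(
    stream: TrackerStream, max_gap_factor: float = DEFAULT_MAX_GAP_FACTOR
) -> list[tuple[float, float]]:
    """Find dropout gaps from timestamp discontinuities.

    Any inter-sample interval longer than ``max_gap_factor`` nominal
    periods is reported as a half-open gap ``[t_i, t_{i+1})``.  Returns a
    sorted, non-overlapping list; an empty list for streams with fewer
    than two samples.
    """
    if len(stream) < 2:
        return []
    period = 1.0 / stream.nominal_rate
    dt = np.diff(stream.t)
    idx = np.nonzero(dt > max_gap_factor * period)[0]
    return [(float(stream.t[i]), float(stream.t[i + 1])) for i in idx]


def _stream_to_frame(stream: TrackerStream) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t": stream.t,
            "px": stream.pos[:, 0],
            "py": stream.pos[:, 1],
            "pz": stream.pos[:, 2],
            "qw": stream.quat[:, 0],
            "qx": stream.quat[:, 1],
            "qy": stream.quat[:, 2],
            "qz": stream.quat[:, 3],
        }
    )


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session bundle: one CSV per tracker plus ``meta.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for tid, stream in session.streams.items():
        _stream_to_frame(stream).to_csv(path / f"{tid}.csv", index=False, float_format="%.9g")
    meta = {
        "subject_id": session.subject_id,
        "condition": session.condition,
        "visit": session.visit,
        "maze_id": session.maze_id,
        "session_id": session.session_id,
        "nominal_rate": session.navel.nominal_rate,
        "gaps": {tid: [list(g) for g in s.gaps] for tid, s in session.streams.items()},
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def load_session(path: str | Path, max_gap_factor: float = DEFAULT_MAX_GAP_FACTOR) -> Session:
    """Load a session bundle written by :func:`write_session`.

    Dropout gaps are taken from the sidecar when recorded there and are
    always augmented with gaps re-detected from timestamp
    discontinuities, so a bundle whose samples were thinned out after
    writing still reports its gaps.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SessionError(f"no meta.json in {path}")
    meta = json.loads(meta_path.read_text())
    rate = float(meta.get("nominal_rate", DEFAULT_RATE_HZ))
    streams: dict[str, TrackerStream] = {}
    for tid in TRACKER_IDS:
        csv = path / f"{tid}.csv"
        if not csv.exists():
            raise SessionError(f"bundle {path} is missing the {tid!r} tracker file")
        df = pd.read_csv(csv)
        stream = TrackerStream(
            tracker_id=tid,
            t=df["t"].to_numpy(),
            pos=df[["px", "py", "pz"]].to_numpy(),
            quat=df[["qw", "qx", "qy", "qz"]].to_numpy(),
            nominal_rate=rate,
        )
        recorded = [tuple(g) for g in meta.get("gaps", {}).get(tid, [])]
        detected = detect_dropouts(stream, max_gap_factor)
        stream.gaps = _merge_gaps(recorded + detected)
        stream.validate()
        streams[tid] = stream
    return Session(
        subject_id=str(meta["subject_id"]),
        condition=meta["condition"],
        visit=meta["visit"],
        streams=streams,
        maze_id=str(meta.get("maze_id", "")),
        session_id=str(meta.get("session_id", "")),
    )


def _merge_gaps(gaps: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[tuple[float, float]] = []
    for a, b in sorted(gaps):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((float(a), float(b)))
    return merged


def drop_samples(stream: TrackerStream, t_start: float, t_end: float) -> TrackerStream:
    """Return a copy of ``stream`` with samples in ``[t_start, t_end)`` removed
    and the interval recorded as a dropout gap."""
    keep = ~((stream.t >= t_start) & (stream.t < t_end))
    if keep.all():
        return stream
    new = replace(
        stream,
        t=stream.t[keep],
        pos=stream.pos[keep],
        quat=stream.quat[keep],
        gaps=list(stream.gaps),
    )
    new.gaps = _merge_gaps(new.gaps + detect_dropouts(new))
    return new
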