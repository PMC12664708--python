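"""Stride assembly, straight/turn classification, and spatiotemporal summaries.

A stride runs from a heel strike to the next heel strike of the same
foot, with the intervening toe-off.  Five spatiotemporal parameters are
computed per stride:

* length — horizontal distance between the ipsilateral ankle positions
  at the two heel strikes (m);
* time — elapsed time between them (s);
* velocity — length / time (m/s);
* stance percentage — 100 · (toe-off − initial heel strike) / time;
* width — perpendicular horizontal distance from the contralateral
  ankle position at its intervening heel strike to the line joining the
  two ipsilateral heel-strike positions (m).

Steps are classified as straight or turning from the change in foot
heading (projection of the tracker x-axis on the horizontal plane)
between the two heel strikes: straight iff the absolute wrapped heading
deviation is strictly below a threshold in the 20–30° range (default
25°, or calibrated from straight-segment walking).  Only straight
strides enter session summaries; strides overlapping dropout gaps are
excluded.  Variability is reported as the coefficient of variation
CoV = sample SD / mean (n−1 denominator).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .events import HEEL_STRIKE, TOE_OFF, GaitEvent
from .session import Session, TrackerStream

logger = logging.getLogger(__name__)

STRAIGHT = "straight"
TURN = "turn"
EXCLUDED = "excluded"

DEFAULT_TURN_THRESHOLD_DEG = 25.0  # midpoint of the 20-30 deg range
THRESHOLD_CLAMP = (20.0, 30.0)
CALIBRATION_MARGIN_DEG = 5.0
MIN_CALIBRATION_STRIDES = 5

#: the five spatiotemporal parameters summarized per session
GAIT_PARAMS = ("length", "width", "time", "velocity", "stance_pct")


@dataclass
class Stride:
    side: str
    hs_initial: GaitEvent
    toe_off: GaitEvent
    hs_terminal: GaitEvent
    classification: str
    length: float
    width: float  # NaN when no intervening contralateral heel strike
    time: float
    velocity: float
    stance_pct: float
    heading_initial: float
    heading_terminal: float


@dataclass
class SessionGaitSummary:
    """Per-session means and CoVs over straight strides."""

    means: dict[str, float]
    covs: dict[str, float]
    n_straight: int
    n_turn: int
    n_excluded: int
    completion_time: float = float("nan")
    sufficient: bool = True

    @property
    def n_total(self) -> int:
        return self.n_straight + self.n_turn + self.n_excluded


def wrap_angle_deg(a: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees to (−180, 180]."""
    w = (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return float(w) if np.ndim(w) == 0 else w


def foot_heading(stream: TrackerStream, t: float) -> float:
    """Foot heading (deg) at the sample nearest ``t``.

    The heading is the atan2 angle of the horizontal projection of the
    rotated local x-axis, wrapped to (−180, 180].  Raises ValueError if
    the x-axis is within numerical tolerance of vertical (undefined
    heading) or ``t`` falls in a dropout gap.
    """
    if stream.in_gap(t)[0]:
        raise ValueError(f"heading requested inside a dropout gap at t={t}")
    i = stream.sample_at(t)
    rot = Rotation.from_quat(stream.quat[i], scalar_first=True)
    x = rot.apply(np.array([1.0, 0.0, 0.0]))
    if np.hypot(x[0], x[1]) < 1e-6:
        raise ValueError(f"foot x-axis vertical at t={t}: heading undefined")
    return float(wrap_angle_deg(np.degrees(np.arctan2(x[1], x[0]))))


def classify_step(
    heading_initial: float,
    heading_terminal: float,
    threshold_deg: float = DEFAULT_TURN_THRESHOLD_DEG,
) -> str:
    """Straight iff |wrapped heading deviation| is strictly below threshold."""
    if not 0.0 <= threshold_deg <= 180.0:
        raise ValueError("threshold_deg must lie in [0, 180]")
    dev = abs(wrap_angle_deg(heading_terminal - heading_initial))
    return STRAIGHT if dev < threshold_deg else TURN


def _perp_distance(point: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Perpendicular distance from ``point`` to the line through a, b (2-D)."""
    d = b - a
    nrm = np.hypot(d[0], d[1])
    if nrm < 1e-12:
        return float(np.hypot(*(point - a)))
    r = point - a
    return float(abs(d[0] * r[1] - d[1] * r[0]) / nrm)


def assemble_strides(
    events: dict[str, list[GaitEvent]],
    session: Session,
    threshold_deg: float = DEFAULT_TURN_THRESHOLD_DEG,
) -> list[Stride]:
    """Build per-side strides from alternating heel-strike/toe-off events.

    One stride per (HS, TO, HS) triple per side.  Strides that overlap
    any dropout gap of any stream are classified ``excluded``; strides
    with undefined headings are likewise excluded.
    """
    gaps = session.all_gaps()
    strides: list[Stride] = []
    for side in ("left", "right"):
        tid = f"{side}_ankle"
        stream = session.streams[tid]
        contra_side = "right" if side == "left" else "left"
        contra_stream = session.streams[f"{contra_side}_ankle"]
        ev = events[side]
        hs = [e for e in ev if e.kind == HEEL_STRIKE]
        contra_hs = [e for e in events[contra_side] if e.kind == HEEL_STRIKE]
        for h0, h1 in zip(hs, hs[1:]):
            tos = [e for e in ev if e.kind == TOE_OFF and h0.t < e.t < h1.t]
            if len(tos) != 1:
                continue  # alternation violation inside the stride window
            to = tos[0]
            p0 = stream.pos[h0.sample_index, :2]
            p1 = stream.pos[h1.sample_index, :2]
            length = float(np.hypot(*(p1 - p0)))
            time = h1.t - h0.t
            velocity = length / time
            stance_pct = 100.0 * (to.t - h0.t) / time

            mids = [e for e in contra_hs if h0.t < e.t < h1.t]
            if len(mids) == 1:
                pc = contra_stream.pos[mids[0].sample_index, :2]
                width = _perp_distance(pc, p0, p1)
            else:
                width = float("nan")

            overlaps_gap = any(a < h1.t and h0.t < b for a, b in gaps)
            classification = EXCLUDED
            heading0 = heading1 = float("nan")
            if not overlaps_gap:
                try:
                    heading0 = foot_heading(stream, h0.t)
                    heading1 = foot_heading(stream, h1.t)
                    classification = classify_step(heading0, heading1, threshold_deg)
                except ValueError:
                    classification = EXCLUDED
            strides.append(
                Stride(
                    side=side,
                    hs_initial=h0,
                    toe_off=to,
                    hs_terminal=h1,
                    classification=classification,
                    length=length,
                    width=width,
                    time=time,
                    velocity=velocity,
                    stance_pct=stance_pct,
                    heading_initial=heading0,
                    heading_terminal=heading1,
                )
            )
    strides.sort(key=lambda s: s.hs_initial.t)
    return strides


def cov(values: np.ndarray) -> float:
    """Coefficient of variation: sample SD (n−1) divided by the mean."""
    values = np.asarray(values, dtype=float)
    m = values.mean()
    if len(values) < 2 or m == 0:
        return float("nan")
    return float(values.std(ddof=1) / m)


def summarize_session(
    strides: list[Stride], completion_time: float = float("nan")
) -> SessionGaitSummary:
    """Session means and CoVs of the five parameters over straight strides.

    With fewer than two straight strides the summary is flagged
    insufficient and CoVs (and, with zero strides, means) are NaN.
    Width statistics use the straight strides whose width is defined.
    """
    straight = [s for s in strides if s.classification == STRAIGHT]
    n_turn = sum(1 for s in strides if s.classification == TURN)
    n_excluded = sum(1 for s in strides if s.classification == EXCLUDED)

    means: dict[str, float] = {}
    covs: dict[str, float] = {}
    for param in GAIT_PARAMS:
        vals = np.array([getattr(s, param) for s in straight], dtype=float)
        vals = vals[np.isfinite(vals)]
        means[param] = float(vals.mean()) if len(vals) else float("nan")
        covs[param] = cov(vals) if len(vals) >= 2 else float("nan")

    return SessionGaitSummary(
        means=means,
        covs=covs,
        n_straight=len(straight),
        n_turn=n_turn,
        n_excluded=n_excluded,
        completion_time=completion_time,
        sufficient=len(straight) >= 2,
    )


def calibrate_threshold(
    session: Session,
    maze,
    events: dict[str, list[GaitEvent]] | None = None,
    margin_deg: float = CALIBRATION_MARGIN_DEG,
) -> float:
    """Straight/turn threshold from straight-line walking in the maze.

    Strides whose two heel strikes fall on the same straight run of the
    maze solution path are calibration strides; the threshold is their
    maximum absolute heading deviation plus ``margin_deg``, clamped to
    the 20–30° range.  With fewer than five calibration strides the
    default 25° is returned with a warning.
    """
    from .events import detect_session_events
    from .maze import solution_path

    if events is None:
        events = detect_session_events(session)
    path = solution_path(maze)
    seg_dirs = np.diff(path, axis=0)
    seg_angles = np.degrees(np.arctan2(seg_dirs[:, 1], seg_dirs[:, 0]))
    # cumulative arclength of each vertex; corners sit at interior vertices
    seglen = np.hypot(seg_dirs[:, 0], seg_dirs[:, 1])
    vertex_s = np.concatenate([[0.0], np.cumsum(seglen)])
    corner_s = [
        vertex_s[i + 1]
        for i in range(len(seg_angles) - 1)
        if abs(wrap_angle_deg(seg_angles[i + 1] - seg_angles[i])) > 1.0
    ]

    def arclength_of(xy: np.ndarray) -> float:
        # project onto the polyline, return arclength of nearest point
        best_s, best_d = 0.0, np.inf
        for i in range(len(path) - 1):
            a, b = path[i], path[i + 1]
            ab = b - a
            tt = np.clip(np.dot(xy - a, ab) / np.dot(ab, ab), 0.0, 1.0)
            proj = a + tt * ab
            d = np.hypot(*(xy - proj))
            if d < best_d:
                best_d, best_s = d, vertex_s[i] + tt * seglen[i]
        return best_s

    # project the navel (which stays near the corridor centerline) rather
    # than the feet: adjacent corridors are only one block apart, so a foot
    # offset laterally can project onto the wrong corridor
    navel = session.navel
    deviations = []
    strides = assemble_strides(events, session, threshold_deg=180.0)
    for s in strides:
        if not np.isfinite(s.heading_initial):
            continue
        s0 = arclength_of(navel.pos[navel.sample_at(s.hs_initial.t), :2])
        s1 = arclength_of(navel.pos[navel.sample_at(s.hs_terminal.t), :2])
        lo, hi = min(s0, s1), max(s0, s1)
        # guard band: projection of a laterally offset tracker onto the path
        # is only accurate to a few centimeters, so corners within a small
        # buffer of the interval disqualify the stride as well
        buf = 0.10
        if any(lo - buf < cs <= hi + buf for cs in corner_s):
            continue  # spans (or abuts) a corner: not straight-line walking
        deviations.append(abs(wrap_angle_deg(s.heading_terminal - s.heading_initial)))

    if len(deviations) < MIN_CALIBRATION_STRIDES:
        msg = (
            f"only {len(deviations)} calibration strides (<{MIN_CALIBRATION_STRIDES}); "
            f"falling back to the default {DEFAULT_TURN_THRESHOLD_DEG} deg threshold"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        return DEFAULT_TURN_THRESHOLD_DEG
    return threshold_from_deviations(deviations, margin_deg)


def threshold_from_deviations(deviations, margin_deg: float = CALIBRATION_MARGIN_DEG) -> float:
    """Threshold rule: max |heading deviation| + margin, clamped to 20-30 deg."""
    raw = float(np.max(np.abs(deviations))) + margin_deg
    return float(np.clip(raw, *THRESHOLD_CLAMP))
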