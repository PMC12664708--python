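"""End-to-end per-session analysis: events → strides → balance → summary row.

Glues the pipeline stages together: detect gait events from the ankle
orientation waveforms, assemble and classify strides (optionally
calibrating the straight/turn threshold from the maze geometry),
compute balance cycles, and collapse everything to the per-session
outcome row used by the statistical stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .balance import BalanceCycle, BalanceSummary, balance_cycles, summarize_balance
from .cohort import OUTCOME_COLUMNS
from .events import GaitEvent, detect_session_events
from .maze import IncompleteTraversal, Maze
from .maze import completion_time as maze_completion_time
from .session import Session
from .strides import (
    DEFAULT_TURN_THRESHOLD_DEG,
    SessionGaitSummary,
    Stride,
    assemble_strides,
    calibrate_threshold,
    summarize_session,
)


@dataclass
class SessionAnalysis:
    """Full per-session analysis product."""

    session: Session
    events: dict[str, list[GaitEvent]]
    strides: list[Stride]
    gait: SessionGaitSummary
    cycles: list[BalanceCycle]
    balance: BalanceSummary
    threshold_deg: float
    completion_time: float

    def outcome_row(self) -> dict[str, float]:
        """The session's row of the outcome long table."""
        row = {
            "subject_id": self.session.subject_id,
            "condition": self.session.condition,
            "visit": self.session.visit,
            "completion_time": self.completion_time,
        }
        for p_out, p_in in (
            ("stride_length", "length"),
            ("stride_width", "width"),
            ("stride_time", "time"),
            ("stride_velocity", "velocity"),
            ("stance_pct", "stance_pct"),
        ):
            row[p_out] = self.gait.means[p_in]
            row[f"{p_out}_cov"] = self.gait.covs[p_in]
        row["mos_ml"] = self.balance.mos_ml_mean
        row["com_ml"] = self.balance.com_ml_mean
        row["com_ml_cov"] = self.balance.com_ml_cov
        return row


def analyze_session(
    session: Session,
    maze: Maze | None = None,
    threshold_deg: float | str = "auto",
    compute_balance: bool = True,
) -> SessionAnalysis:
    """Run the full pipeline on one session.

    ``threshold_deg="auto"`` calibrates the straight/turn threshold from
    straight-line walking in the maze (falling back to the default 25°
    when the maze is absent or calibration strides are insufficient).
    """
    events = detect_session_events(session)
    if threshold_deg == "auto":
        if maze is not None:
            threshold = calibrate_threshold(session, maze, events=events)
        else:
            threshold = DEFAULT_TURN_THRESHOLD_DEG
    else:
        threshold = float(threshold_deg)
    strides = assemble_strides(events, session, threshold_deg=threshold)

    ct = float("nan")
    if maze is not None:
        try:
            ct = maze_completion_time(session, maze)
        except IncompleteTraversal:
            ct = float("nan")
    gait = summarize_session(strides, completion_time=ct)

    if compute_balance:
        cycles = balance_cycles(session, strides)
        bal = summarize_balance(cycles)
    else:
        cycles, bal = [], summarize_balance([])
    return SessionAnalysis(
        session=session,
        events=events,
        strides=strides,
        gait=gait,
        cycles=cycles,
        balance=bal,
        threshold_deg=threshold,
        completion_time=ct,
    )


def strides_frame(strides: list[Stride]) -> pd.DataFrame:
    """Per-stride table (one row per stride)."""
    return pd.DataFrame(
        {
            "side": [s.side for s in strides],
            "t_hs_initial": [s.hs_initial.t for s in strides],
            "t_toe_off": [s.toe_off.t for s in strides],
            "t_hs_terminal": [s.hs_terminal.t for s in strides],
            "classification": [s.classification for s in strides],
            "length": [s.length for s in strides],
            "width": [s.width for s in strides],
            "time": [s.time for s in strides],
            "velocity": [s.velocity for s in strides],
            "stance_pct": [s.stance_pct for s in strides],
        }
    )


def study_long_table(
    sessions: list,
    mazes: dict[str, Maze] | None = None,
    threshold_deg: float | str = DEFAULT_TURN_THRESHOLD_DEG,
) -> pd.DataFrame:
    """Outcome long table (subject × condition × visit rows) from sessions.

    ``sessions`` may contain Session objects or (Session, GroundTruth)
    pairs as produced by the study simulator; ``mazes`` maps maze_id to
    Maze for completion timing and threshold calibration.
    """
    rows = []
    for item in sessions:
        session = item[0] if isinstance(item, tuple) else item
        maze = (mazes or {}).get(session.maze_id)
        analysis = analyze_session(session, maze=maze, threshold_deg=threshold_deg)
        rows.append(analysis.outcome_row())
    df = pd.DataFrame(rows)
    return df[["subject_id", "condition", "visit", *[c for c in OUTCOME_COLUMNS if c in df]]]


def match_events(
    detected: list[GaitEvent],
    truth_events,
    window_s: float = 0.05,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected vs ground-truth events.

    Events match when same side and kind and |Δt| ≤ ``window_s``.
    Returns (true positives, false positives, false negatives).
    """
    truth = list(truth_events)
    used = [False] * len(truth)
    tp = 0
    for ev in detected:
        best, best_dt = -1, window_s
        for i, tr in enumerate(truth):
            if used[i] or tr.side != ev.side or tr.kind != ev.kind:
                continue
            dt = abs(tr.t - ev.t)
            if dt <= best_dt:
                best, best_dt = i, dt
        if best >= 0:
            used[best] = True
            tp += 1
    fp = len(detected) - tp
    fn = len(truth) - tp
    return tp, fp, fn


def event_f1(detected, truth_events, window_s: float = 0.05) -> float:
    tp, fp, fn = match_events(detected, truth_events, window_s)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else float("nan")
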