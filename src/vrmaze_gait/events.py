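"""Gait-event detection from ankle-tracker orientation.

The shank angle α is the angle between the tracker's local x-axis
(which points along the foot) rotated into the global frame and the
fixed global Z-axis.  Over a gait cycle α rises from heel strike to
toe-off and falls back to the next heel strike, so heel strikes are
local minima of the α waveform and toe-offs are local maxima.

Detection smooths α with a short moving average, finds prominent
extrema, enforces min/max alternation, and suppresses events that fall
inside dropout gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial.transform import Rotation

from .session import TrackerStream

HEEL_STRIKE = "heel_strike"
TOE_OFF = "toe_off"

DEFAULT_SMOOTH_WINDOW_S = 0.1
DEFAULT_MIN_PROMINENCE_DEG = 5.0
DEFAULT_MIN_INTERVAL_S = 0.3


@dataclass(frozen=True)
class GaitEvent:
    side: str  # "left" | "right"
    kind: str  # HEEL_STRIKE | TOE_OFF
    t: float
    sample_index: int


@dataclass
class AngleWaveform:
    """Per-sample shank angle in degrees, aligned with its source stream."""

    t: np.ndarray
    alpha: np.ndarray
    stream: TrackerStream | None = None


def shank_angle(stream: TrackerStream) -> AngleWaveform:
    """Angle α_i = arccos((R(q_i)·x̂)·Ẑ) in degrees, per sample."""
    rot = Rotation.from_quat(stream.quat, scalar_first=True)
    x_global = rot.apply(np.array([1.0, 0.0, 0.0]))
    cosang = np.clip(x_global[:, 2], -1.0, 1.0)
    alpha = np.degrees(np.arccos(cosang))
    return AngleWaveform(t=stream.t, alpha=alpha, stream=stream)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x.astype(float)
    kernel = np.ones(width) / width
    # edge-padded so the smoothed series keeps the original length/alignment
    pad = width // 2
    xp = np.pad(x, (pad, width - 1 - pad), mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def detect_events(
    waveform: AngleWaveform,
    side: str,
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
    min_prominence_deg: float = DEFAULT_MIN_PROMINENCE_DEG,
    min_interval_s: float = DEFAULT_MIN_INTERVAL_S,
) -> list[GaitEvent]:
    """Detect heel strikes (α minima) and toe-offs (α maxima).

    Extrema are accepted when their prominence is at least
    ``min_prominence_deg`` and same-kind events are at least
    ``min_interval_s`` apart; where alternation is violated, the most
    prominent extremum of a same-kind run is kept.  Boundary samples are
    never events, and events inside dropout gaps of the source stream
    are suppressed.
    """
    t = waveform.t
    n = len(t)
    rate = 1.0 / np.median(np.diff(t)) if n > 1 else 0.0
    width = max(1, int(round(smooth_window_s * rate)))
    if n < max(3, width):
        raise ValueError("waveform shorter than the smoothing window")
    smooth = _moving_average(waveform.alpha, width)
    distance = max(1, int(round(min_interval_s * rate)))

    maxima, maxprops = find_peaks(smooth, prominence=min_prominence_deg, distance=distance)
    minima, minprops = find_peaks(-smooth, prominence=min_prominence_deg, distance=distance)

    candidates = [(int(i), TOE_OFF, float(p)) for i, p in zip(maxima, maxprops["prominences"])]
    candidates += [(int(i), HEEL_STRIKE, float(p)) for i, p in zip(minima, minprops["prominences"])]
    candidates.sort()

    # enforce alternation: within a run of same-kind extrema keep the most prominent
    accepted: list[tuple[int, str, float]] = []
    for cand in candidates:
        if accepted and accepted[-1][1] == cand[1]:
            if cand[2] > accepted[-1][2]:
                accepted[-1] = cand
        else:
            accepted.append(cand)

    stream = waveform.stream
    events = []
    raw = waveform.alpha
    # localization: the smoothed-peak index is biased where the waveform is
    # asymmetric around the extremum, so refine it — against the raw samples
    # when they are effectively noiseless at sample scale, else with a
    # parabolic vertex fit on the smoothed waveform (robust to noise)
    noise_est = 1.4826 * float(np.median(np.abs(raw - smooth)))
    use_raw = noise_est < 0.3
    for idx, kind, _prom in accepted:
        if use_raw:
            idx = _refine_to_raw_extremum(raw, idx, width, maximum=(kind == TOE_OFF))
        else:
            idx = _parabolic_refine(smooth, idx, width)
        if idx <= 0 or idx >= n - 1:
            continue
        if stream is not None and stream.in_gap(t[idx])[0]:
            continue
        events.append(GaitEvent(side=side, kind=kind, t=float(t[idx]), sample_index=idx))
    events.sort(key=lambda e: e.t)
    return events


def _parabolic_refine(smooth: np.ndarray, idx: int, width: int) -> int:
    """Quadratic vertex fit on the smoothed waveform around an extremum."""
    lo = max(idx - width, 0)
    hi = min(idx + width, len(smooth) - 1)
    if hi - lo < 4:
        return idx
    xs = np.arange(lo, hi + 1) - idx
    c = np.polyfit(xs, smooth[lo : hi + 1], 2)
    if abs(c[0]) < 1e-12:
        return idx
    off = float(np.clip(-c[1] / (2 * c[0]), -width, width))
    return int(np.clip(idx + round(off), 0, len(smooth) - 1))


def _refine_to_raw_extremum(raw: np.ndarray, idx: int, width: int, maximum: bool) -> int:
    """Snap a smoothed-extremum index to the best raw local extremum within
    the smoothing window; plateau ties resolve to the plateau center."""
    lo = max(idx - width, 1)
    hi = min(idx + width, len(raw) - 2)
    sign = 1.0 if maximum else -1.0
    best, best_val = idx, -np.inf
    i = lo
    while i <= hi:
        # plateau-aware local-extremum test
        j = i
        while j + 1 <= hi and raw[j + 1] == raw[i]:
            j += 1
        left_ok = sign * raw[i] > sign * raw[i - 1]
        right_ok = j + 1 < len(raw) and sign * raw[j] > sign * raw[j + 1]
        if left_ok and right_ok:
            center = (i + j) // 2
            if sign * raw[center] > best_val:
                best, best_val = center, sign * raw[center]
        i = j + 1
    return best


def detect_session_events(
    session,
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
    min_prominence_deg: float = DEFAULT_MIN_PROMINENCE_DEG,
    min_interval_s: float = DEFAULT_MIN_INTERVAL_S,
) -> dict[str, list[GaitEvent]]:
    """Detect events for both ankles of a session, keyed by side."""
    out = {}
    for side, tid in (("left", "left_ankle"), ("right", "right_ankle")):
        wf = shank_angle(session.streams[tid])
        out[side] = detect_events(
            wf,
            side,
            smooth_window_s=smooth_window_s,
            min_prominence_deg=min_prominence_deg,
            min_interval_s=min_interval_s,
        )
    return out
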