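"""Extrapolated center of mass, base of support, and margin-of-stability metrics.

The body is modelled as an inverted pendulum of length ``l`` (the
vertical distance between an ankle tracker and the navel tracker).  The
extrapolated center of mass is

    XCoM = u + u̇ / ω0,      ω0 = sqrt(g / l)

with u the horizontal CoM position (navel tracker), u̇ its horizontal
velocity and g = 9.8 m/s².  The base of support (BoS) is a rectangle
covering both feet, aligned with the step frame: the anterior-posterior
(AP) axis points from the cycle's initial to its terminal heel strike,
the mediolateral (ML) axis is its perpendicular.  The mediolateral
margin of stability MoS_ml at a heel strike is the signed distance along
the ML axis from the XCoM to the nearer ML border of the BoS — positive
inside the ML extent (stable), negative outside.

Per gait cycle, the direction of progression (DoP) runs from the CoM at
the initial heel strike to the CoM at the terminal heel strike, and
CoM_ml is the maximum absolute perpendicular deviation of the CoM from
the DoP line within the cycle — a body-sway proxy.  Its variability is
reported as the coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .session import Session, TrackerStream
from .strides import STRAIGHT, Stride, cov

GRAVITY = 9.8  # m/s^2
DEFAULT_FOOT_DIMS = (0.25, 0.10)  # (length, width) m of the nominal footprint
DEFAULT_VELOCITY_CUTOFF_HZ = 6.0


@dataclass
class PendulumParams:
    """Inverted-pendulum constants: leg length l (m) and g (m/s²)."""

    l: float
    g: float = GRAVITY

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError(f"leg length must be positive, got {self.l}")

    @property
    def omega0(self) -> float:
        return float(np.sqrt(self.g / self.l))


@dataclass
class BoSRect:
    """Base-of-support rectangle in the step frame.

    ``axes`` rows are the (AP, ML) unit vectors; ``half_extents`` are the
    rectangle half-sizes along them.
    """

    center: np.ndarray
    axes: np.ndarray  # (2, 2): rows = AP, ML unit vectors
    half_extents: np.ndarray  # (2,)

    def contains(self, point: np.ndarray) -> bool:
        rel = self.axes @ (np.asarray(point) - self.center)
        return bool(np.all(np.abs(rel) <= self.half_extents + 1e-12))

    def corners(self) -> np.ndarray:
        """The four corner points, (4, 2)."""
        signs = np.array([[1, 1], [1, -1], [-1, -1], [-1, 1]], dtype=float)
        return self.center + (signs * self.half_extents) @ self.axes


@dataclass
class BalanceCycle:
    """Per-gait-cycle balance metrics, aligned with a stride."""

    side: str
    t_hs: float
    dop: np.ndarray
    com_ml: float
    mos_ml: float
    classification: str


def xcom(u: np.ndarray, u_dot: np.ndarray, params: PendulumParams) -> np.ndarray:
    """Extrapolated CoM: u + u̇/ω0, componentwise (horizontal 2-vectors)."""
    return np.asarray(u, dtype=float) + np.asarray(u_dot, dtype=float) / params.omega0


def estimate_com_velocity(
    navel: TrackerStream, cutoff_hz: float = DEFAULT_VELOCITY_CUTOFF_HZ
) -> np.ndarray:
    """Horizontal CoM velocity by central differences + low-pass smoothing.

    Central finite differences on the navel horizontal position (one-sided
    at the endpoints), then a zero-phase 4th-order Butterworth low-pass at
    ``cutoff_hz``.  Returns an (n, 2) array aligned with the stream.
    """
    if len(navel) < 3:
        raise ValueError("need at least 3 samples to estimate CoM velocity")
    xy = navel.pos[:, :2]
    vel = np.gradient(xy, navel.t, axis=0)
    rate = navel.nominal_rate
    nyq = rate / 2.0
    if 0 < cutoff_hz < nyq and len(navel) > 15:
        b, a = butter(4, cutoff_hz / nyq)
        vel = filtfilt(b, a, vel, axis=0)
    return vel


def leg_length(
    ankle: TrackerStream,
    navel: TrackerStream,
    window: tuple[float, float] | None = None,
) -> float:
    """Leg length: median vertical navel−ankle tracker separation (m).

    The median over the window (default: the whole session) is robust to
    the ankle's vertical excursion during swing.
    """
    if window is None:
        lo, hi = -np.inf, np.inf
    else:
        lo, hi = window
    a_sel = (ankle.t >= lo) & (ankle.t <= hi)
    n_sel = (navel.t >= lo) & (navel.t <= hi)
    if not a_sel.any() or not n_sel.any():
        raise ValueError("no overlapping samples in the leg-length window")
    navel_z = np.interp(ankle.t[a_sel], navel.t[n_sel], navel.pos[n_sel, 2])
    sep = navel_z - ankle.pos[a_sel, 2]
    med = float(np.median(sep))
    if med <= 0:
        raise ValueError(
            f"navel tracker below ankle tracker (median separation {med:.3f} m); "
            "check tracker placement or coordinate frame"
        )
    return med


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.hypot(*v)
    if n < 1e-12:
        raise ValueError("cannot normalize a near-zero vector")
    return np.asarray(v, dtype=float) / n


def base_of_support(
    left_pos: np.ndarray,
    right_pos: np.ndarray,
    foot_dirs: tuple[float, float],
    foot_dims: tuple[float, float] = DEFAULT_FOOT_DIMS,
    ap_axis: np.ndarray | None = None,
) -> BoSRect:
    """Base-of-support rectangle covering both feet in the step frame.

    Each foot is modelled as a ``foot_dims`` (length × width) footprint
    rectangle centered at its ankle tracker and oriented by its heading
    (degrees).  The BoS is the minimal rectangle aligned with the step
    AP/ML axes containing both footprints.  ``ap_axis`` defaults to the
    mean foot-heading direction; coincident feet degrade gracefully to
    the single-foot footprint.
    """
    left_pos = np.asarray(left_pos, dtype=float)
    right_pos = np.asarray(right_pos, dtype=float)
    hl, hr = np.radians(foot_dirs[0]), np.radians(foot_dirs[1])
    if ap_axis is None:
        mean_dir = np.array([np.cos(hl) + np.cos(hr), np.sin(hl) + np.sin(hr)])
        ap = _unit(mean_dir)
    else:
        ap = _unit(np.asarray(ap_axis, dtype=float))
    ml = np.array([-ap[1], ap[0]])

    half_l, half_w = foot_dims[0] / 2.0, foot_dims[1] / 2.0
    pts = []
    for pos, h in ((left_pos, hl), (right_pos, hr)):
        fwd = np.array([np.cos(h), np.sin(h)])
        lat = np.array([-fwd[1], fwd[0]])
        for sa in (1, -1):
            for sb in (1, -1):
                pts.append(pos + sa * half_l * fwd + sb * half_w * lat)
    pts = np.array(pts)

    frame = np.vstack([ap, ml])
    proj = pts @ frame.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    center = ((lo + hi) / 2.0) @ frame
    half_extents = (hi - lo) / 2.0
    half_extents = np.maximum(half_extents, 1e-9)
    return BoSRect(center=center, axes=frame, half_extents=half_extents)


def mos_ml(xcom_point: np.ndarray, bos: BoSRect, ml_axis: np.ndarray | None = None) -> float:
    """Signed mediolateral margin of stability (m).

    Signed distance along the ML axis from the XCoM to the nearer ML
    border of the BoS: positive when the XCoM lies within the ML extent,
    negative when outside.
    """
    ml = _unit(ml_axis) if ml_axis is not None else bos.axes[1]
    c = float(np.dot(np.asarray(xcom_point, dtype=float) - bos.center, ml))
    h = float(bos.half_extents[1]) if ml_axis is None else _ml_half_extent(bos, ml)
    return h - abs(c)


def _ml_half_extent(bos: BoSRect, ml: np.ndarray) -> float:
    proj = (bos.corners() - bos.center) @ ml
    return float(proj.max())


def direction_of_progression(com_start: np.ndarray, com_end: np.ndarray) -> np.ndarray:
    """Unit vector from cycle-initial to cycle-terminal CoM position."""
    d = np.asarray(com_end, dtype=float) - np.asarray(com_start, dtype=float)
    n = np.hypot(*d)
    if n <= 1e-6:
        raise ValueError("near-zero CoM displacement: direction of progression undefined")
    return d / n


def com_ml_displacement(com_xy: np.ndarray, dop: np.ndarray) -> float:
    """Max |perpendicular deviation| of the CoM from the DoP line (m).

    The line passes through the first CoM sample of the cycle along
    ``dop``.
    """
    com_xy = np.asarray(com_xy, dtype=float)
    if len(com_xy) < 2:
        raise ValueError("need at least 2 CoM samples in the cycle")
    rel = com_xy - com_xy[0]
    perp = rel[:, 0] * dop[1] - rel[:, 1] * dop[0]
    return float(np.max(np.abs(perp)))


def balance_cycles(
    session: Session,
    strides: list[Stride],
    foot_dims: tuple[float, float] = DEFAULT_FOOT_DIMS,
    g: float = GRAVITY,
    single_foot_bos: bool = False,
) -> list[BalanceCycle]:
    """Per-stride balance metrics: DoP, CoM_ml, and MoS_ml at heel strike.

    Each stride defines a gait cycle.  The MoS is evaluated at the
    cycle's initial heel strike against the BoS formed by both feet at
    that instant (or the leading foot only when ``single_foot_bos``),
    with the step frame taken from the cycle's heel-strike-to-heel-strike
    AP axis.  Cycles whose DoP is undefined are skipped.
    """
    from .strides import foot_heading

    navel = session.navel
    left = session.left_ankle
    right = session.right_ankle
    l = leg_length(left, navel)
    params = PendulumParams(l=l, g=g)
    vel = estimate_com_velocity(navel)

    cycles: list[BalanceCycle] = []
    for s in strides:
        i0 = navel.sample_at(s.hs_initial.t)
        i1 = navel.sample_at(s.hs_terminal.t)
        if i1 <= i0 + 1:
            continue
        com0 = navel.pos[i0, :2]
        com1 = navel.pos[i1, :2]
        try:
            dop = direction_of_progression(com0, com1)
        except ValueError:
            continue
        com_ml = com_ml_displacement(navel.pos[i0 : i1 + 1, :2], dop)

        stream = session.streams[f"{s.side}_ankle"]
        ip_pos = stream.pos[s.hs_initial.sample_index, :2]
        # step AP axis: initial to terminal heel strike of the cycle
        ip_term = stream.pos[s.hs_terminal.sample_index, :2]
        try:
            ap = _unit(ip_term - ip_pos)
        except ValueError:
            ap = dop
        try:
            h_ip = s.heading_initial if np.isfinite(s.heading_initial) else foot_heading(
                stream, s.hs_initial.t
            )
            contra = right if s.side == "left" else left
            j = contra.sample_at(s.hs_initial.t)
            contra_pos = contra.pos[j, :2]
            h_contra = foot_heading(contra, s.hs_initial.t)
        except ValueError:
            continue
        if single_foot_bos:
            bos = base_of_support(ip_pos, ip_pos, (h_ip, h_ip), foot_dims, ap_axis=ap)
        elif s.side == "left":
            bos = base_of_support(ip_pos, contra_pos, (h_ip, h_contra), foot_dims, ap_axis=ap)
        else:
            bos = base_of_support(contra_pos, ip_pos, (h_contra, h_ip), foot_dims, ap_axis=ap)

        xc = xcom(navel.pos[i0, :2], vel[i0], params)
        m = mos_ml(xc, bos)
        cycles.append(
            BalanceCycle(
                side=s.side,
                t_hs=s.hs_initial.t,
                dop=dop,
                com_ml=com_ml,
                mos_ml=m,
                classification=s.classification,
            )
        )
    return cycles


@dataclass
class BalanceSummary:
    com_ml_mean: float
    com_ml_cov: float
    mos_ml_mean: float
    n_cycles: int
    sufficient: bool = True


def summarize_balance(cycles: list[BalanceCycle], straight_only: bool = True) -> BalanceSummary:
    """Session means of CoM_ml (with CoV) and MoS_ml over straight cycles."""
    sel = [c for c in cycles if (not straight_only or c.classification == STRAIGHT)]
    if len(sel) < 2:
        return BalanceSummary(float("nan"), float("nan"), float("nan"), len(sel), False)
    com = np.array([c.com_ml for c in sel])
    mos = np.array([c.mos_ml for c in sel])
    return BalanceSummary(
        com_ml_mean=float(com.mean()),
        com_ml_cov=cov(com),
        mos_ml_mean=float(mos.mean()),
        n_cycles=len(sel),
    )
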