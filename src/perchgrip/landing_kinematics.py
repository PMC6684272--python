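"""Tau-theory approach analysis, landing-stage segmentation, and
superfast-claw-movement detection.

Tau is the visually available time-to-contact estimate: perch distance
divided by closing speed.  A controlled collision keeps the time rate of
change of tau constant between 0.5 and 1.  Landing stages are segmented
from the foot spread angle trace (10%/90%/peak crossings, contact, and
stable claw contact); superfast claw movements are sub-2-ms displacements
that start from quiescence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "ApproachTrace",
    "TauFit",
    "LandingTrial",
    "SuperfastEvent",
    "STAGE_ORDER",
    "compute_tau",
    "fit_tau_dot",
    "segment_stages",
    "detect_superfast",
    "lowpass_trace",
]

STAGE_ORDER = ("resting", "spreading", "open", "pre_shaping", "foot_wrapping", "claw_curling")


@dataclass(frozen=True)
class ApproachTrace:
    """Distance-to-perch record during the aerial approach."""

    time_s: np.ndarray
    distance_m: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        s = np.asarray(self.distance_m, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "distance_m", s)
        if t.shape != s.shape or t.ndim != 1 or t.size < 3:
            raise ValueError("need matching 1D time/distance arrays with >= 3 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(s < -1e-12):
            raise ValueError("distance must be non-negative")


@dataclass(frozen=True)
class TauFit:
    tau_dot: float
    r_squared: float | None
    n_samples: int


@dataclass(frozen=True)
class LandingTrial:
    """Synchronized kinematics and forces for one landing.

    Angles in degrees, forces in bw, claw tip position in mm relative to
    the foot centre.  ``contact_time_s`` marks first perch contact (end of
    pre-shaping).  ``stage_bounds_s`` maps stage name -> (start, end); for
    generated trials it holds ground truth, for measured trials it is
    filled by :func:`segment_stages`.
    """

    time_s: np.ndarray
    foot_spread_deg: np.ndarray
    claw_angle_deg: np.ndarray
    claw_tip_mm: np.ndarray
    contact_time_s: float
    body_force_bw: np.ndarray | None = None
    squeeze_force_bw: np.ndarray | None = None
    approach_distance_m: np.ndarray | None = None
    sample_rate_hz: float = 3000.0
    stage_bounds_s: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SuperfastEvent:
    onset_time_s: float
    displacement_mm: float
    window_ms: float


def compute_tau(trace: ApproachTrace):
    """Tau series s/v with v = -ds/dt by central differences.

    Samples where the closing speed is non-positive are masked (NaN).
    Returns (time_s, tau_s, valid_mask).
    """
    t, s = trace.time_s, trace.distance_m
    # edge_order=2 keeps the derivative exact for quadratic trajectories
    v = -np.gradient(s, t, edge_order=2)
    valid = v > 0
    tau = np.full(s.shape, np.nan)
    tau[valid] = s[valid] / v[valid]
    return t, tau, valid


def fit_tau_dot(time_s, tau_s) -> TauFit:
    """OLS slope magnitude of tau against time over the valid samples."""
    t = np.asarray(time_s, dtype=float)
    tau = np.asarray(tau_s, dtype=float)
    ok = np.isfinite(tau)
    t, tau = t[ok], tau[ok]
    if t.size < 2:
        raise ValueError("need at least 2 valid tau samples")
    slope, intercept = np.polyfit(t, tau, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((tau - pred) ** 2))
    ss_tot = float(np.sum((tau - tau.mean()) ** 2))
    r2 = None if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return TauFit(tau_dot=abs(float(slope)), r_squared=r2, n_samples=int(t.size))


def tau_dot_from_approach(trace: ApproachTrace) -> TauFit:
    """Convenience: compute tau then fit its slope."""
    t, tau, _ = compute_tau(trace)
    return fit_tau_dot(t, tau)


def segment_stages(
    trial: LandingTrial,
    stable_contact_time_s: float | None = None,
    claw_rate_cap_deg_s: float = 100.0,
    claw_rate_hold_ms: float = 5.0,
) -> dict:
    """Stage boundaries from the foot spread angle trace.

    resting: start of tracking to the first upward crossing of 10% of the
    peak spread angle; spreading: 10% to 90%; open: 90% to the peak
    sample; pre_shaping: peak to contact; foot_wrapping: contact to stable
    claw contact; claw_curling: stable contact to end of tracking.

    Stable claw contact defaults to the first post-contact time where the
    claw-angle rate stays below ``claw_rate_cap_deg_s`` for at least
    ``claw_rate_hold_ms``; it may also be supplied explicitly.
    """
    t = trial.time_s
    spread = trial.foot_spread_deg
    contact = trial.contact_time_s
    pre_contact = t <= contact
    if not np.any(pre_contact):
        raise ValueError("contact time precedes the tracked window")
    spread_pre = spread[pre_contact]
    peak_idx = int(np.argmax(spread_pre))  # ties -> first sample attaining the max
    peak = float(spread_pre[peak_idx])
    if peak <= 0:
        raise ValueError("no foot-spread peak before contact; cannot segment stages")
    t_peak = float(t[peak_idx])
    if t_peak >= contact and not math.isclose(t_peak, contact):
        raise ValueError("foot-spread peak must precede contact")

    def first_crossing(level: float) -> float:
        # tiny slack so a sample generated exactly at the threshold counts
        above = spread[: peak_idx + 1] >= level - 1e-9 * max(abs(level), 1.0)
        idx = int(np.argmax(above))
        if not above[idx]:
            raise ValueError(f"spread angle never reaches {level:.3g} deg before its peak")
        return float(t[idx])

    t10 = first_crossing(0.1 * peak)
    t90 = first_crossing(0.9 * peak)

    if stable_contact_time_s is None:
        stable_contact_time_s = _stable_claw_contact(
            t, trial.claw_angle_deg, contact, claw_rate_cap_deg_s, claw_rate_hold_ms
        )
    bounds = {
        "resting": (float(t[0]), t10),
        "spreading": (t10, t90),
        "open": (t90, t_peak),
        "pre_shaping": (t_peak, contact),
        "foot_wrapping": (contact, stable_contact_time_s),
        "claw_curling": (stable_contact_time_s, float(t[-1])),
    }
    # boundaries must be ordered
    seq = [bounds[s] for s in STAGE_ORDER]
    for (a0, a1), (b0, b1) in zip(seq, seq[1:]):
        if a1 < a0 - 1e-12 or abs(a1 - b0) > 1e-9:
            raise ValueError("stage boundaries out of order")
    return bounds


def _stable_claw_contact(t, claw_deg, contact_s, rate_cap, hold_ms) -> float:
    dt = float(np.median(np.diff(t)))
    rate = np.abs(np.gradient(np.asarray(claw_deg, dtype=float), t))
    hold_n = max(int(round(hold_ms / 1000.0 / dt)), 1)
    start = int(np.searchsorted(t, contact_s, side="left"))
    quiet = rate < rate_cap
    for i in range(start, t.size - hold_n + 1):
        if np.all(quiet[i : i + hold_n]):
            return float(t[i])
    return float(t[-1])


def detect_superfast(
    time_s,
    claw_tip_mm,
    threshold_mm: float = 0.3,
    window_ms: float = 2.0,
    quiescence_speed_mm_s: float = 20.0,
    quiescence_ms: float = 2.0,
) -> list[SuperfastEvent]:
    """Displacements >= ``threshold_mm`` completed within ``window_ms``
    starting from no perceptible motion.

    A window start is quiescent when the tip speed stayed below
    ``quiescence_speed_mm_s`` throughout the preceding ``quiescence_ms``.
    Overlapping detections merge into a single reported event.
    """
    t = np.asarray(time_s, dtype=float)
    x = np.asarray(claw_tip_mm, dtype=float)
    if t.shape != x.shape or t.size < 3:
        raise ValueError("need matching 1D arrays with >= 3 samples")
    dt = float(np.median(np.diff(t)))
    win_n = max(int(round(window_ms / 1000.0 / dt)), 1)
    quiet_n = max(int(round(quiescence_ms / 1000.0 / dt)), 1)
    speed = np.abs(np.gradient(x, t))
    quiet = speed < quiescence_speed_mm_s

    events = []
    last_end = -1
    for i in range(t.size - win_n):
        if i <= last_end:
            continue
        lo = max(0, i - quiet_n)
        if not np.all(quiet[lo : i + 1]):
            continue
        seg = x[i : i + win_n + 1]
        disp = float(np.max(np.abs(seg - x[i])))
        if disp >= threshold_mm:
            events.append(
                SuperfastEvent(onset_time_s=float(t[i]), displacement_mm=disp, window_ms=window_ms)
            )
            last_end = i + win_n
    return events


def lowpass_trace(series, sample_rate_hz: float, cutoff_hz: float = 100.0, order: int = 8):
    """Zero-phase Butterworth low-pass applied to a channel before analysis."""
    y = np.asarray(series, dtype=float)
    nyq = sample_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff_hz must lie in (0, {nyq}) Hz")
    # half order per pass: forward-backward filtering doubles the effective order
    b, a = butter(order // 2 if order >= 2 else 1, cutoff_hz / nyq)
    return filtfilt(b, a, y)
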