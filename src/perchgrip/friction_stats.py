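"""Stick-slip friction statistics for toe pads and claws.

Dragged contacts load up against surface asperities and release suddenly;
the tangential-to-normal force ratio immediately before each release
measures how much friction that asperity offered.  This module extracts
those slip peaks from drag traces, fits the through-origin Coulomb model
for toe pads, and runs the two Monte Carlo procedures for claws: variance
shrinkage of the mean force when several claws share load, and growth of
the expected best-asperity friction with drag distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

__all__ = [
    "DragTrace",
    "SlipEventSeries",
    "CoulombFit",
    "LoadSharingResult",
    "ExpectedMaxCurve",
    "extract_slip_peaks",
    "fit_coulomb",
    "load_sharing_sd",
    "expected_max_friction",
    "curl_angle_to_drag_distance",
    "lowpass_drag_trace",
    "read_drag_csv",
    "write_drag_csv",
]

DEFAULT_DROP_FRACTION = 0.2


@dataclass(frozen=True)
class DragTrace:
    """Synchronized normal/tangential force record from a drag test."""

    time_s: np.ndarray
    normal_bw: np.ndarray
    tangential_bw: np.ndarray
    position_mm: np.ndarray
    surface: str = ""
    contact_type: str = "claw"  # "toe_pad" or "claw"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        fn = np.asarray(self.normal_bw, dtype=float)
        ft = np.asarray(self.tangential_bw, dtype=float)
        pos = np.asarray(self.position_mm, dtype=float)
        for name, arr in (("time_s", t), ("normal_bw", fn), ("tangential_bw", ft), ("position_mm", pos)):
            object.__setattr__(self, name, arr)
            if arr.shape != t.shape:
                raise ValueError("all trace channels must share one length")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(fn < 0):
            raise ValueError("normal force must be non-negative")

    @property
    def ratio(self) -> np.ndarray:
        """F_T / F_N, with zero-normal samples mapped to 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(self.normal_bw > 0, self.tangential_bw / self.normal_bw, 0.0)
        return r

    @property
    def drag_length_mm(self) -> float:
        return float(self.position_mm[-1] - self.position_mm[0])


@dataclass(frozen=True)
class SlipEventSeries:
    """F_T/F_N values immediately before slip, with positions and linear density."""

    peak_ratios: np.ndarray
    positions_mm: np.ndarray
    drag_length_mm: float

    def __post_init__(self) -> None:
        pk = np.asarray(self.peak_ratios, dtype=float)
        pos = np.asarray(self.positions_mm, dtype=float)
        object.__setattr__(self, "peak_ratios", pk)
        object.__setattr__(self, "positions_mm", pos)
        if pk.shape != pos.shape:
            raise ValueError("peak_ratios and positions_mm must have equal length")
        if np.any(pk <= 0):
            raise ValueError("slip-peak ratios must be positive")
        if self.drag_length_mm <= 0:
            raise ValueError("drag_length_mm must be positive")

    @property
    def asperity_density_per_mm(self) -> float:
        """Usable asperities encountered per mm of drag."""
        return self.peak_ratios.size / self.drag_length_mm


@dataclass(frozen=True)
class CoulombFit:
    mu: float
    se: float
    n_points: int


@dataclass(frozen=True)
class LoadSharingResult:
    n_claws: int
    sd_mean_ratio: float
    n_trials: int
    seed: int
    mc_se: float = 0.0  # Monte Carlo standard error of the reported SD


@dataclass(frozen=True)
class ExpectedMaxCurve:
    drag_distances_mm: np.ndarray
    expected_max_ratio: np.ndarray
    sd_max_ratio: np.ndarray
    n_trials: int
    seed: int


def extract_slip_peaks(
    trace: DragTrace, drop_fraction: float = DEFAULT_DROP_FRACTION
) -> SlipEventSeries:
    """Find F_T/F_N local maxima followed by a relative drop of at least
    ``drop_fraction`` before the ratio next rises above the peak's level.

    A peak qualifies as a slip event when the ratio subsequently falls to
    ``(1 - drop_fraction) * peak`` or lower before exceeding the peak again.
    """
    if not 0.0 < drop_fraction < 1.0:
        raise ValueError("drop_fraction must lie in (0, 1)")
    if not np.any(trace.normal_bw > 0):
        raise ValueError("normal force is zero everywhere; friction ratio undefined")
    r = trace.ratio
    peaks = []
    positions = []
    n = r.size
    i = 1
    while i < n - 1:
        if r[i] >= r[i - 1] and r[i] > r[i + 1]:
            peak_val = r[i]
            j = i + 1
            is_slip = False
            while j < n:
                if r[j] <= peak_val * (1.0 - drop_fraction):
                    is_slip = True
                    break
                if r[j] > peak_val:
                    break
                j += 1
            if is_slip and peak_val > 0:
                peaks.append(peak_val)
                positions.append(trace.position_mm[i])
                i = j
                continue
        i += 1
    length = trace.drag_length_mm if trace.drag_length_mm > 0 else 1.0
    return SlipEventSeries(
        peak_ratios=np.asarray(peaks, dtype=float),
        positions_mm=np.asarray(positions, dtype=float),
        drag_length_mm=length,
    )


def fit_coulomb(normal_bw, tangential_max_bw) -> CoulombFit:
    """Through-origin least squares: mu = sum(F_N * F_T,max) / sum(F_N^2)."""
    fn = np.asarray(normal_bw, dtype=float)
    ft = np.asarray(tangential_max_bw, dtype=float)
    if fn.size != ft.size or fn.size == 0:
        raise ValueError("need equal-length, non-empty force arrays")
    denom = np.sum(fn**2)
    if denom == 0:
        raise ValueError("all normal forces are zero")
    mu = float(np.sum(fn * ft) / denom)
    resid = ft - mu * fn
    dof = max(fn.size - 1, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / denom))
    return CoulombFit(mu=mu, se=se, n_points=int(fn.size))


def load_sharing_sd(
    peaks: SlipEventSeries, n_claws: int, n_trials: int = 10_000, seed: int = 0
) -> LoadSharingResult:
    """SD of the mean of ``n_claws`` draws from the empirical peak distribution.

    Each trial samples once per engaged claw (with replacement) from the
    measured slip-peak ratios and averages; the spread of those averages
    over ``n_trials`` trials quantifies the benefit of load sharing.
    """
    if n_claws < 1:
        raise ValueError("n_claws must be >= 1")
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    vals = peaks.peak_ratios
    if vals.size == 0:
        raise ValueError("empty slip-peak series")
    rng = np.random.default_rng(seed)
    draws = rng.choice(vals, size=(n_trials, n_claws), replace=True)
    means = draws.mean(axis=1)
    sd = float(means.std(ddof=1))
    # SE of a sample SD, normal approximation
    mc_se = sd / np.sqrt(2.0 * (n_trials - 1))
    return LoadSharingResult(
        n_claws=n_claws, sd_mean_ratio=sd, n_trials=n_trials, seed=seed, mc_se=float(mc_se)
    )


def expected_max_friction(
    peaks: SlipEventSeries,
    drag_distances_mm,
    n_trials: int = 10_000,
    seed: int = 0,
    asperity_density_per_mm: float | None = None,
) -> ExpectedMaxCurve:
    """Expected best F_T/F_N found over a drag of each given distance.

    The mean asperity count for distance d is N_a(d) = density * d.  Each
    trial draws floor(N_a) + Bernoulli(frac(N_a)) samples (so the average
    draw count over trials equals N_a) from the empirical peak distribution
    and records their maximum; zero-draw trials contribute 0.
    """
    if peaks.peak_ratios.size == 0:
        raise ValueError("empty slip-peak series")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    d = np.asarray(drag_distances_mm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("drag distances must be positive")
    density = (
        peaks.asperity_density_per_mm if asperity_density_per_mm is None else asperity_density_per_mm
    )
    rng = np.random.default_rng(seed)
    vals = peaks.peak_ratios
    e_max = np.empty(d.size)
    sd_max = np.empty(d.size)
    for k, dist in enumerate(d):
        n_a = density * dist
        base = int(np.floor(n_a))
        frac = n_a - base
        counts = base + (rng.random(n_trials) < frac).astype(int)
        maxima = np.zeros(n_trials)
        for count in np.unique(counts):
            if count == 0:
                continue
            idx = np.nonzero(counts == count)[0]
            draws = rng.choice(vals, size=(idx.size, count), replace=True)
            maxima[idx] = draws.max(axis=1)
        e_max[k] = maxima.mean()
        sd_max[k] = maxima.std(ddof=1) if n_trials > 1 else 0.0
    return ExpectedMaxCurve(
        drag_distances_mm=d,
        expected_max_ratio=e_max,
        sd_max_ratio=sd_max,
        n_trials=n_trials,
        seed=seed,
    )


def curl_angle_to_drag_distance(curl_angle_deg, mm_per_degree: float):
    """Linear map from claw curl angle to drag distance along the surface."""
    if mm_per_degree < 0:
        raise ValueError("mm_per_degree must be non-negative")
    return np.asarray(curl_angle_deg, dtype=float) * mm_per_degree


def lowpass_drag_trace(trace: DragTrace, cutoff_hz: float, order: int = 4) -> DragTrace:
    """Optional zero-phase low-pass of the force channels of a measured trace."""
    dt = np.median(np.diff(trace.time_s))
    nyq = 0.5 / dt
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff_hz must lie in (0, {nyq:.1f}) Hz for this trace")
    b, a = butter(order, cutoff_hz / nyq)
    return DragTrace(
        time_s=trace.time_s,
        normal_bw=filtfilt(b, a, trace.normal_bw),
        tangential_bw=filtfilt(b, a, trace.tangential_bw),
        position_mm=trace.position_mm,
        surface=trace.surface,
        contact_type=trace.contact_type,
    )


def read_drag_csv(path, surface: str = "", contact_type: str = "claw") -> DragTrace:
    """Read a DragTrace CSV (time_s, FN_bw, FT_bw[, position_mm])."""
    df = pd.read_csv(path)
    required = {"time_s", "FN_bw", "FT_bw"}
    if not required.issubset(df.columns):
        raise ValueError(f"drag CSV needs columns {sorted(required)}")
    t = df["time_s"].to_numpy(dtype=float)
    if "position_mm" in df.columns:
        pos = df["position_mm"].to_numpy(dtype=float)
    else:
        # assume uniform drag speed of 1 mm/s when position is not recorded
        pos = t - t[0]
    return DragTrace(
        time_s=t,
        normal_bw=df["FN_bw"].to_numpy(dtype=float),
        tangential_bw=df["FT_bw"].to_numpy(dtype=float),
        position_mm=pos,
        surface=surface,
        contact_type=contact_type,
    )


def write_drag_csv(trace: DragTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time_s,
            "FN_bw": trace.normal_bw,
            "FT_bw": trace.tangential_bw,
            "position_mm": trace.position_mm,
        }
    ).to_csv(path, index=False)
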