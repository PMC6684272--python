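"""Synthetic input generators with embedded ground truth.

Every generator returns both the signal a measurement pipeline would see
and the ground truth needed to score the estimator that consumes it:
self-affine rough surfaces with an exact RMS contract, sawtooth stick-slip
drag traces with known slip-peak values, constant-tau-dot landing trials
with known stage boundaries, and circular-arc-plus-flank claw profiles.

All randomness flows through one seeded ``numpy.random.Generator`` per
call; fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .friction_stats import DragTrace
from .landing_kinematics import STAGE_ORDER, LandingTrial
from .surface_metrology import SurfaceProfile
from .claw_surface_model import ClawProfile

__all__ = [
    "SurfaceGenSpec",
    "DragGenSpec",
    "LandingGenSpec",
    "ClawGenSpec",
    "gen_surface_profile",
    "gen_drag_trace",
    "gen_landing_trial",
    "gen_claw_profile",
    "write_landing_bundle",
    "read_landing_bundle",
]

DEFAULT_STAGE_DURATIONS_MS = {
    "resting": 60.0,
    "spreading": 40.0,
    "open": 21.0,
    "pre_shaping": 31.0,
    "foot_wrapping": 19.0,
    "claw_curling": 185.0,
}


@dataclass(frozen=True)
class SurfaceGenSpec:
    """Self-affine rough-surface profile parameters.

    ``spectral_exponent`` is the power-law slope of the height power
    spectrum (amplitude falls as k**(-exponent/2)); larger values put the
    roughness at longer wavelengths.
    """

    target_rms_um: float
    spectral_exponent: float = 2.0
    length_mm: float = 10.0
    spacing_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_rms_um < 0:
            raise ValueError("target_rms_um must be non-negative")
        if self.spacing_um <= 0 or self.length_mm <= 0:
            raise ValueError("length and spacing must be positive")
        if self.n_samples < 64:
            raise ValueError(
                f"length/spacing gives only {self.n_samples} samples (need >= 64)"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.length_mm * 1000.0 / self.spacing_um))


@dataclass(frozen=True)
class DragGenSpec:
    """Sawtooth stick-slip drag-trace parameters.

    ``peak_dist`` describes the distribution of pre-slip F_T/F_N values as
    a dict: {"family": "constant"|"uniform"|"exponential"|"lognormal", ...}.
    ``mu`` is the no-asperity Coulomb asymptote the ratio ramps toward when
    no asperity interrupts the rise.
    """

    mu: float = 0.3
    asperity_density_per_mm: float = 2.0
    peak_dist: dict = field(default_factory=lambda: {"family": "constant", "value": 1.0})
    normal_force_bw: float = 0.05
    sample_rate_hz: float = 1000.0
    drag_length_mm: float = 5.0
    drag_speed_mm_s: float = 1.0
    residual_ratio: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.asperity_density_per_mm < 0:
            raise ValueError("asperity_density_per_mm must be non-negative")
        if self.drag_length_mm <= 0:
            raise ValueError("drag_length_mm must be positive")
        if self.normal_force_bw <= 0 or self.sample_rate_hz <= 0 or self.drag_speed_mm_s <= 0:
            raise ValueError("forces, rates, and speeds must be positive")


@dataclass(frozen=True)
class LandingGenSpec:
    """Constant-tau-dot landing trial parameters."""

    tau_dot: float = 0.8
    stage_durations_ms: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_DURATIONS_MS))
    peak_spread_angle_deg: float = 60.0
    squeeze_peak_bw: float = 2.0
    body_force_peak_bw: float = 2.5
    body_mass_kg: float = 0.030
    sample_rate_hz: float = 3000.0
    noise_sd: float = 0.0
    approach_distance_m: float = 0.5
    claw_angle_open_deg: float = 60.0
    claw_angle_wrapped_deg: float = 30.0
    claw_curl_total_deg: float = 5.0
    superfast_times_ms: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_dot <= 1.0:
            raise ValueError("tau_dot must lie in (0, 1]")
        missing = set(STAGE_ORDER) - set(self.stage_durations_ms)
        if missing:
            raise ValueError(f"stage_durations_ms missing stages: {sorted(missing)}")
        if any(v <= 0 for v in self.stage_durations_ms.values()):
            raise ValueError("all stage durations must be positive")
        if self.sample_rate_hz < 1000.0:
            raise ValueError("sample_rate_hz must be >= 1000 Hz")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class ClawGenSpec:
    """Circular-arc tip blended into straight flanks."""

    tip_radius_um: float = 50.0
    opening_halfangle_deg: float = 30.0
    profile_height_um: float = 500.0
    step_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tip_radius_um <= 0:
            raise ValueError("tip_radius_um must be positive")
        if not 0.0 < self.opening_halfangle_deg < 90.0:
            raise ValueError("opening_halfangle_deg must lie in (0, 90)")
        if self.profile_height_um <= 0 or self.step_um <= 0:
            raise ValueError("profile_height_um and step_um must be positive")


def gen_surface_profile(spec: SurfaceGenSpec) -> SurfaceProfile:
    """Spectral synthesis of a zero-mean self-affine profile.

    Fourier amplitudes fall as k**(-exponent/2) with Gaussian random
    phases; the result is rescaled so the realized RMS equals the target
    exactly.  A zero target gives a flat profile.
    """
    n = spec.n_samples
    positions = np.arange(n) * spec.spacing_um / 1000.0  # mm
    if spec.target_rms_um == 0.0:
        return SurfaceProfile(positions, np.zeros(n))
    rng = np.random.default_rng(spec.seed)
    k = np.arange(n // 2 + 1, dtype=float)
    amp = np.zeros_like(k)
    amp[1:] = k[1:] ** (-spec.spectral_exponent / 2.0)
    phases = rng.standard_normal(k.size) + 1j * rng.standard_normal(k.size)
    spectrum = amp * phases
    spectrum[0] = 0.0  # zero mean
    heights = np.fft.irfft(spectrum, n=n)
    rms = math.sqrt(float(np.mean(heights**2)))
    heights *= spec.target_rms_um / rms
    return SurfaceProfile(positions, heights)


def _sample_peaks(rng: np.random.Generator, dist: dict, n: int) -> np.ndarray:
    family = dist.get("family", "constant")
    if family == "constant":
        return np.full(n, float(dist["value"]))
    if family == "uniform":
        return rng.uniform(float(dist["low"]), float(dist["high"]), size=n)
    if family == "exponential":
        return float(dist.get("loc", 0.0)) + rng.exponential(float(dist["scale"]), size=n)
    if family == "lognormal":
        return rng.lognormal(float(dist["mean"]), float(dist["sigma"]), size=n)
    raise ValueError(f"unknown peak distribution family: {family!r}")


def gen_drag_trace(spec: DragGenSpec) -> tuple[DragTrace, dict]:
    """Piecewise-rising F_T/F_N sawtooth with Poisson-spaced asperities.

    Between asperities the ratio ramps linearly from the residual toward
    the next slip peak (drawn from ``peak_dist``); at each asperity it
    attains the peak then drops back to the residual.  With zero asperity
    density the ratio ramps monotonically toward ``mu`` and never drops.

    Returns (trace, ground_truth) where ground_truth holds the peak values
    and positions actually realized on the sample grid.
    """
    rng = np.random.default_rng(spec.seed)
    duration_s = spec.drag_length_mm / spec.drag_speed_mm_s
    n = int(round(duration_s * spec.sample_rate_hz)) + 1
    t = np.arange(n) / spec.sample_rate_hz
    x = t * spec.drag_speed_mm_s

    r0 = spec.residual_ratio
    n_asp = rng.poisson(spec.asperity_density_per_mm * spec.drag_length_mm)
    if n_asp > 0:
        asp_pos = np.sort(rng.uniform(0.0, spec.drag_length_mm, size=n_asp))
        raw_peaks = _sample_peaks(rng, spec.peak_dist, n_asp)
        raw_peaks = np.maximum(raw_peaks, r0 * 1.5)  # a slip peak must exceed the residual
        # snap each asperity to the first sample at/after it; merge collisions
        idx = np.searchsorted(x, asp_pos)
        idx = np.clip(idx, 1, n - 2)  # peaks need room to drop before trace end
        keep_idx, keep_val = [], []
        for i, v in zip(idx, raw_peaks):
            if keep_idx and i == keep_idx[-1]:
                keep_val[-1] = v
            else:
                keep_idx.append(int(i))
                keep_val.append(float(v))
        idx = np.array(keep_idx, dtype=int)
        vals = np.array(keep_val, dtype=float)
    else:
        idx = np.array([], dtype=int)
        vals = np.array([], dtype=float)

    ratio = np.empty(n)
    start = 0
    for i_pk, v_pk in zip(idx, vals):
        seg = np.arange(start, i_pk + 1)
        frac = (seg - start) / max(i_pk - start, 1)
        ratio[seg] = r0 + (v_pk - r0) * frac
        start = i_pk + 1
    if start < n:
        seg = np.arange(start, n)
        tail_target = max(spec.mu, r0)
        frac = (seg - start) / max(n - 1 - start, 1)
        ratio[seg] = r0 + (tail_target - r0) * frac

    fn = np.full(n, spec.normal_force_bw)
    ft = ratio * fn
    trace = DragTrace(time_s=t, normal_bw=fn, tangential_bw=ft, position_mm=x, contact_type="claw")
    truth = {
        "peak_ratios": vals,
        "peak_positions_mm": x[idx] if idx.size else np.array([]),
        "asperity_density_per_mm": idx.size / spec.drag_length_mm,
        "residual_ratio": r0,
        "mu": spec.mu,
    }
    return trace, truth


def _rise_decay_envelope(u: np.ndarray, peak_time_s: float) -> np.ndarray:
    """Fast-rise/slow-decay envelope normalized to a unit peak at ``peak_time_s``."""
    out = np.zeros_like(u)
    pos = u > 0
    out[pos] = (u[pos] / peak_time_s) * np.exp(1.0 - u[pos] / peak_time_s)
    return out


def gen_landing_trial(spec: LandingGenSpec) -> LandingTrial:
    """Landing trial with exact stage boundaries and a closed-form approach.

    The approach distance follows s(t) = s0 * ((T - t)/T)**(1/tau_dot)
    before contact at T (constant tau-dot by construction).  The foot
    spread angle is piecewise linear so the 10%/90%/peak stage thresholds
    fall exactly at the specified boundaries; claw angle drops quickly
    during foot wrapping and drifts slowly during claw curling.  All
    ground truth (boundaries, tau series, envelopes) is embedded.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sample_rate_hz

    def snap(ms: float) -> float:
        return round(ms / 1000.0 / dt) * dt

    durs = {k: snap(spec.stage_durations_ms[k]) for k in STAGE_ORDER}
    t10 = durs["resting"]
    t90 = t10 + durs["spreading"]
    t_peak = t90 + durs["open"]
    t_contact = t_peak + durs["pre_shaping"]
    t_stable = t_contact + durs["foot_wrapping"]
    t_end = t_stable + durs["claw_curling"]

    n = int(round(t_end / dt)) + 1
    t = np.arange(n) * dt

    peak = spec.peak_spread_angle_deg
    knots_t = [0.0, t10, t90, t_peak, t_contact, t_stable, t_end]
    knots_v = [0.0, 0.1 * peak, 0.9 * peak, peak, 0.6 * peak, 0.35 * peak, 0.3 * peak]
    spread = np.interp(t, knots_t, knots_v)

    claw_knots_t = [0.0, t_contact, t_stable, t_end]
    claw_knots_v = [
        spec.claw_angle_open_deg,
        spec.claw_angle_open_deg,
        spec.claw_angle_wrapped_deg,
        spec.claw_angle_wrapped_deg - spec.claw_curl_total_deg,
    ]
    claw = np.interp(t, claw_knots_t, claw_knots_v)

    # approach distance: closed-form constant-tau-dot trajectory, 0 after contact
    k_exp = 1.0 / spec.tau_dot
    s = np.zeros(n)
    pre = t < t_contact
    s[pre] = spec.approach_distance_m * ((t_contact - t[pre]) / t_contact) ** k_exp
    tau_truth = np.full(n, np.nan)
    tau_truth[pre] = (t_contact - t[pre]) * spec.tau_dot

    u = t - t_contact
    squeeze = spec.squeeze_peak_bw * _rise_decay_envelope(u, 0.020)
    body = spec.body_force_peak_bw * _rise_decay_envelope(u, 0.010)

    claw_tip = np.zeros(n)
    for ms in spec.superfast_times_ms:
        onset = int(round(ms / 1000.0 / dt))
        rise = max(int(round(0.0015 / dt)), 1)  # 0.4 mm step over ~1.5 ms
        if onset + rise < n:
            claw_tip[onset : onset + rise] += 0.4 * np.arange(rise) / rise
            claw_tip[onset + rise :] += 0.4

    if spec.noise_sd > 0:
        spread = spread + rng.normal(0.0, spec.noise_sd, n)
        claw = claw + rng.normal(0.0, spec.noise_sd, n)
        squeeze = squeeze + rng.normal(0.0, spec.noise_sd * 0.01, n)
        body = body + rng.normal(0.0, spec.noise_sd * 0.01, n)

    bounds = {
        "resting": (0.0, t10),
        "spreading": (t10, t90),
        "open": (t90, t_peak),
        "pre_shaping": (t_peak, t_contact),
        "foot_wrapping": (t_contact, t_stable),
        "claw_curling": (t_stable, t_end),
    }
    truth = {
        "tau_dot": spec.tau_dot,
        "stage_bounds_s": bounds,
        "stage_durations_s": durs,
        "contact_time_s": t_contact,
        "peak_spread_angle_deg": peak,
        "tau_s": tau_truth,
        "squeeze_peak_bw": spec.squeeze_peak_bw,
        "superfast_times_ms": tuple(spec.superfast_times_ms),
    }
    return LandingTrial(
        time_s=t,
        foot_spread_deg=spread,
        claw_angle_deg=claw,
        claw_tip_mm=claw_tip,
        contact_time_s=t_contact,
        body_force_bw=body,
        squeeze_force_bw=squeeze,
        approach_distance_m=s,
        sample_rate_hz=spec.sample_rate_hz,
        stage_bounds_s=bounds,
        ground_truth=truth,
    )


def gen_claw_profile(spec: ClawGenSpec) -> ClawProfile:
    """Width-vs-height profile: circular tip arc tangent to straight flanks.

    The arc of radius R meets the flank (at opening half-angle phi from
    the claw axis) at height h_t = R * (1 - sin(phi)); below h_t the width
    is the chord of the circle, above it the flanks continue linearly.
    """
    r = spec.tip_radius_um
    phi = math.radians(spec.opening_halfangle_deg)
    h_t = r * (1.0 - math.sin(phi))
    x_t = r * math.cos(phi)
    h = np.arange(0.0, spec.profile_height_um + spec.step_um / 2.0, spec.step_um)
    half_w = np.empty_like(h)
    on_arc = h <= min(h_t, r)
    half_w[on_arc] = np.sqrt(np.clip(2.0 * r * h[on_arc] - h[on_arc] ** 2, 0.0, None))
    half_w[~on_arc] = x_t + (h[~on_arc] - h_t) * math.tan(phi)
    return ClawProfile(heights_um=h, widths_um=2.0 * half_w)


def write_landing_bundle(trial: LandingTrial, csv_path, sidecar_path) -> None:
    """Write a LandingTrial as a CSV of channels plus a JSON sidecar."""
    df = pd.DataFrame(
        {
            "time_s": trial.time_s,
            "foot_spread_deg": trial.foot_spread_deg,
            "claw_angle_deg": trial.claw_angle_deg,
            "claw_tip_mm": trial.claw_tip_mm,
        }
    )
    if trial.approach_distance_m is not None:
        df["approach_m"] = trial.approach_distance_m
    if trial.body_force_bw is not None:
        df["body_force_bw"] = trial.body_force_bw
    if trial.squeeze_force_bw is not None:
        df["squeeze_bw"] = trial.squeeze_force_bw
    df.to_csv(csv_path, index=False)
    meta = {
        "contact_time_s": trial.contact_time_s,
        "sample_rate_hz": trial.sample_rate_hz,
        "stage_bounds_s": {k: list(v) for k, v in trial.stage_bounds_s.items()},
        "ground_truth": _jsonable(trial.ground_truth),
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_landing_bundle(csv_path, sidecar_path) -> LandingTrial:
    df = pd.read_csv(csv_path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    return LandingTrial(
        time_s=df["time_s"].to_numpy(float),
        foot_spread_deg=df["foot_spread_deg"].to_numpy(float),
        claw_angle_deg=df["claw_angle_deg"].to_numpy(float),
        claw_tip_mm=df["claw_tip_mm"].to_numpy(float),
        contact_time_s=float(meta["contact_time_s"]),
        body_force_bw=df["body_force_bw"].to_numpy(float) if "body_force_bw" in df else None,
        squeeze_force_bw=df["squeeze_bw"].to_numpy(float) if "squeeze_bw" in df else None,
        approach_distance_m=df["approach_m"].to_numpy(float) if "approach_m" in df else None,
        sample_rate_hz=float(meta["sample_rate_hz"]),
        stage_bounds_s={k: tuple(v) for k, v in meta["stage_bounds_s"].items()},
        ground_truth=meta.get("ground_truth", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [None if (isinstance(v, float) and math.isnan(v)) else v for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj
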