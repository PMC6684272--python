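"""Traced-surface model of claw-asperity engagement.

A circular claw tip of radius ``r_a`` dragged over a rough profile cannot
reach into features narrower than itself.  The path of the tip's lowest
point defines the *traced surface*, a smoothed version of the profile.
The *usable surface* fraction ``n_a`` is the proportion of the traced
surface whose local slope, on faces rising in the drag direction, exceeds
the minimum angle needed to sustain static friction.  Elastic penetration
of the tip into the substrate relaxes that angle requirement; the
correction is derived from the contact geometry of a rigid sphere
indenting an elastic half-space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .surface_metrology import SurfaceProfile

__all__ = [
    "ClawTipModel",
    "ClawProfile",
    "TracedSurfaceResult",
    "ExpOffsetFit",
    "PenetrationCurveFit",
    "trace_surface",
    "usable_surface",
    "penetration_slope",
    "effective_theta",
    "depth_ratio",
    "sweep_usable_surface",
    "fit_exponential_offset",
    "fit_sphere_tip",
    "fit_penetration_curve",
    "evaluate_penetration",
]

SLOPE_EVAL_STEP_UM = 1.0  # slope comparison distance along the traced surface


@dataclass(frozen=True)
class ClawTipModel:
    """Claw tip radius, penetration depth ratio, and friction angle threshold."""

    tip_radius_um: float
    depth_ratio: float = 0.0
    theta_min_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.tip_radius_um <= 0:
            raise ValueError("tip_radius_um must be positive")
        if not 0.0 <= self.depth_ratio < 1.0:
            raise ValueError("depth_ratio must lie in [0, 1)")
        if not 0.0 <= self.theta_min_deg < 90.0:
            raise ValueError("theta_min_deg must lie in [0, 90)")


@dataclass(frozen=True)
class ClawProfile:
    """Sagittal-plane claw width as a function of height from the tip.

    ``heights_um`` is monotone increasing from 0 at the tip; ``widths_um``
    is the full width at each height (non-decreasing).
    """

    heights_um: np.ndarray
    widths_um: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.heights_um, dtype=float)
        w = np.asarray(self.widths_um, dtype=float)
        object.__setattr__(self, "heights_um", h)
        object.__setattr__(self, "widths_um", w)
        if h.ndim != 1 or h.shape != w.shape:
            raise ValueError("heights and widths must be 1D arrays of equal length")
        if np.any(h < 0) or np.any(np.diff(h) <= 0):
            raise ValueError("heights must be non-negative and strictly increasing")
        if np.any(w < 0) or np.any(np.diff(w) < -1e-9):
            raise ValueError("widths must be non-negative and non-decreasing")


@dataclass(frozen=True)
class TracedSurfaceResult:
    """Tip-path profile and the usable-surface bookkeeping that goes with it."""

    positions_mm: np.ndarray
    traced_heights_um: np.ndarray
    tip_radius_um: float
    slope_eval_step_um: float = SLOPE_EVAL_STEP_UM


@dataclass(frozen=True)
class ExpOffsetFit:
    """Parameters of n_a(r_a) = A * exp(-r_a / lam) + c."""

    amplitude: float
    decay_length_um: float
    offset: float
    residual_rms: float


@dataclass(frozen=True)
class PenetrationCurveFit:
    """Cubic force->depth map constrained through the origin.

    depth_um(F) = c1*F + c2*F**2 + c3*F**3 with F in bodyweights.
    """

    coeffs: tuple[float, float, float]
    force_range_bw: tuple[float, float]

    def __call__(self, force_bw) -> np.ndarray:
        return evaluate_penetration(self, force_bw)


def trace_surface(
    profile: SurfaceProfile, tip_radius_um: float, *, strict: bool = False
) -> TracedSurfaceResult:
    """Path of the lowest point of a circular tip rolled over the profile.

    The traced height at x is ``max over |x'-x| <= r_a of
    [y(x') + sqrt(r_a^2 - (x-x')^2)] - r_a``: the tip rests on whichever
    nearby sample holds it highest.  With ``tip_radius_um == 0`` the traced
    surface is the profile itself.
    """
    if tip_radius_um < 0:
        raise ValueError("tip_radius_um must be non-negative")
    heights = profile.heights
    positions = profile.positions
    if tip_radius_um == 0:
        return TracedSurfaceResult(positions.copy(), heights.copy(), 0.0)

    spacing_um = profile.spacing_um
    if spacing_um > tip_radius_um / 5.0:
        msg = (
            f"profile spacing {spacing_um:.3g} um is coarse relative to tip radius "
            f"{tip_radius_um:.3g} um (recommended spacing <= r_a/5)"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)

    half_window = int(math.floor(tip_radius_um / spacing_um))
    offsets = np.arange(-half_window, half_window + 1)
    # circle ordinate above each window offset; clip guards fp round-off at the rim
    circ = np.sqrt(np.clip(tip_radius_um**2 - (offsets * spacing_um) ** 2, 0.0, None))
    n = heights.size
    traced = np.full(n, -np.inf)
    for off, c in zip(offsets, circ):
        lo = max(0, -off)
        hi = min(n, n - off)
        if lo >= hi:
            continue
        cand = heights[lo + off : hi + off] + c
        np.maximum(traced[lo:hi], cand, out=traced[lo:hi])
    traced -= tip_radius_um
    return TracedSurfaceResult(positions.copy(), traced, float(tip_radius_um))


def penetration_slope(depth_ratio: float) -> float:
    """Slope from the tip's lowest point to the highest sphere-substrate contact.

    For a rigid sphere of radius R indented to depth d = DR * R into an
    elastic half-space, the contact half-width is a = R * sqrt(DR) and the
    chord slope from the tip bottom to the contact edge is
    ``(1 - sqrt(1 - DR)) / sqrt(DR)``, tending to 0 as DR -> 0.
    """
    if not 0.0 <= depth_ratio < 1.0:
        raise ValueError("depth_ratio must lie in [0, 1)")
    if depth_ratio == 0.0:
        return 0.0
    return (1.0 - math.sqrt(1.0 - depth_ratio)) / math.sqrt(depth_ratio)


def effective_theta(theta_min_deg: float, depth_ratio: float) -> float:
    """Friction angle threshold after the penetration-slope correction.

    The angle corresponding to the penetration slope is subtracted from
    theta_min; the result is clamped at zero.
    """
    theta_pen = math.degrees(math.atan(penetration_slope(depth_ratio)))
    return max(0.0, theta_min_deg - theta_pen)


def depth_ratio(depth_um: float, tip_radius_um: float) -> float:
    """Penetration depth divided by tip radius."""
    if tip_radius_um <= 0:
        raise ValueError("tip_radius_um must be positive")
    if depth_um < 0:
        raise ValueError("depth_um must be non-negative")
    return depth_um / tip_radius_um


def usable_surface(
    traced: TracedSurfaceResult,
    tip: ClawTipModel,
    drag_direction: int = 1,
    *,
    both_directions: bool = False,
) -> float:
    """Fraction of the traced surface steep enough to hold a claw statically.

    Slopes are evaluated over ``slope_eval_step_um`` horizontal distances
    (the traced surface is resampled by linear interpolation if coarser).
    Only faces rising in the drag direction count: a claw dragged in +x
    hooks slopes that climb toward +x.  A face counts when its slope angle
    strictly exceeds the penetration-corrected threshold.
    """
    if drag_direction not in (+1, -1):
        raise ValueError("drag_direction must be +1 or -1")
    if abs(traced.tip_radius_um - tip.tip_radius_um) > 1e-9 and traced.tip_radius_um != 0.0:
        raise ValueError("traced surface was computed with a different tip radius")

    step_um = traced.slope_eval_step_um
    pos_um = traced.positions_mm * 1000.0
    spacing_um = pos_um[1] - pos_um[0]
    if spacing_um > step_um * (1 + 1e-9):
        warnings.warn(
            f"profile spacing {spacing_um:.3g} um coarser than slope step {step_um} um; "
            "interpolating",
            stacklevel=2,
        )
    n_seg = int(math.floor((pos_um[-1] - pos_um[0]) / step_um))
    if n_seg < 1:
        raise ValueError("traced surface shorter than one slope-evaluation step")
    grid = pos_um[0] + step_um * np.arange(n_seg + 1)
    h = np.interp(grid, pos_um, traced.traced_heights_um)
    slopes = np.diff(h) / step_um
    theta_eff = effective_theta(tip.theta_min_deg, tip.depth_ratio)
    tan_thr = math.tan(math.radians(theta_eff))
    if both_directions:
        usable = np.abs(slopes) > tan_thr
    else:
        usable = (drag_direction * slopes) > tan_thr
    return float(np.count_nonzero(usable)) / slopes.size


def sweep_usable_surface(
    profile: SurfaceProfile,
    tip_radii_um,
    theta_mins_deg,
    dr_policy: str = "zero",
    *,
    dr_value: float = 0.0,
    dr_reference_radius_um: float | None = None,
    dr_reference: float | None = None,
    drag_direction: int = 1,
):
    """Tabulate n_a over tip radii and friction-angle thresholds.

    ``dr_policy`` is one of:

    - ``"zero"``: no penetration (DR = 0 everywhere);
    - ``"fixed"``: DR = ``dr_value`` at every tip radius;
    - ``"isometric"``: DR scales linearly with tip radius through the
      reference pair (``dr_reference_radius_um``, ``dr_reference``), the
      scaling expected when penetration force grows with body mass.

    Returns a list of dict rows (r_a_um, theta_min_deg, depth_ratio, n_a).
    """
    rows = []
    for r_a in tip_radii_um:
        traced = trace_surface(profile, float(r_a))
        if dr_policy == "zero":
            dr = 0.0
        elif dr_policy == "fixed":
            dr = float(dr_value)
        elif dr_policy == "isometric":
            if dr_reference_radius_um is None or dr_reference is None:
                raise ValueError("isometric policy needs dr_reference_radius_um and dr_reference")
            dr = float(dr_reference) * float(r_a) / float(dr_reference_radius_um)
        else:
            raise ValueError(f"unknown dr_policy: {dr_policy!r}")
        if not 0.0 <= dr < 1.0:
            raise ValueError(f"depth ratio {dr} out of range at tip radius {r_a}")
        for theta in theta_mins_deg:
            tip = ClawTipModel(tip_radius_um=float(r_a), depth_ratio=dr, theta_min_deg=float(theta))
            n_a = usable_surface(traced, tip, drag_direction=drag_direction)
            rows.append(
                {
                    "r_a_um": float(r_a),
                    "theta_min_deg": float(theta),
                    "depth_ratio": dr,
                    "n_a": n_a,
                }
            )
    return rows


def fit_exponential_offset(tip_radii_um, n_a_values) -> ExpOffsetFit:
    """Least-squares fit of n_a(r_a) = A * exp(-r_a / lam) + c."""
    r = np.asarray(tip_radii_um, dtype=float)
    y = np.asarray(n_a_values, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 points to fit amplitude, decay, and offset")

    def model(x, amp, lam, c):
        return amp * np.exp(-x / lam) + c

    span = max(r.max() - r.min(), r.max(), 1.0)
    amp0 = max(y.max() - y.min(), 1e-6)
    p0 = (amp0, span / 2.0, float(y.min()))
    popt, _ = curve_fit(
        model, r, y, p0=p0, maxfev=20000, bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf])
    )
    resid = y - model(r, *popt)
    return ExpOffsetFit(
        amplitude=float(popt[0]),
        decay_length_um=float(popt[1]),
        offset=float(popt[2]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def fit_sphere_tip(claw: ClawProfile, height_limit_um: float) -> float:
    """Radius of the least-squares circle through the near-tip width samples.

    Uses the circle relation (w/2)^2 = 2*R*h - h^2 on samples with
    h <= height_limit, which is linear in R:
    R = sum(h * ((w/2)^2 + h^2)) / (2 * sum(h^2)).
    """
    mask = claw.heights_um <= height_limit_um
    h = claw.heights_um[mask]
    w = claw.widths_um[mask]
    keep = h > 0
    h, w = h[keep], w[keep]
    if h.size < 1:
        raise ValueError("no samples with 0 < h <= height_limit_um")
    half_w_sq = (w / 2.0) ** 2
    return float(np.sum(h * (half_w_sq + h**2)) / (2.0 * np.sum(h**2)))


def fit_penetration_curve(forces_bw, depths_um) -> PenetrationCurveFit:
    """Cubic fit of indentation depth against normal force, zero intercept."""
    f = np.asarray(forces_bw, dtype=float)
    d = np.asarray(depths_um, dtype=float)
    if f.size != d.size or f.size < 3:
        raise ValueError("need at least 3 (force, depth) pairs")
    if np.any(f < 0):
        raise ValueError("forces must be non-negative")
    basis = np.column_stack([f, f**2, f**3])
    coeffs, *_ = np.linalg.lstsq(basis, d, rcond=None)
    return PenetrationCurveFit(
        coeffs=(float(coeffs[0]), float(coeffs[1]), float(coeffs[2])),
        force_range_bw=(float(f.min()), float(f.max())),
    )


def evaluate_penetration(fit: PenetrationCurveFit, force_bw) -> np.ndarray:
    """Depth (um) predicted at the given force(s); warns outside the fitted range."""
    f = np.asarray(force_bw, dtype=float)
    lo, hi = fit.force_range_bw
    if np.any(f > hi) or np.any(f < 0):
        warnings.warn(
            f"evaluating penetration fit outside [0, {hi}] bw is extrapolation",
            stacklevel=2,
        )
    c1, c2, c3 = fit.coeffs
    out = c1 * f + c2 * f**2 + c3 * f**3
    return out if out.ndim else float(out)
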