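"""Unit conversions and small geometric helpers shared across modules.

All forces in this package are expressed in bodyweight units (bw): the
force equal to the animal's weight.  Torques are bw*mm.
"""

from __future__ import annotations

import math

G_STANDARD = 9.81
"""Standard gravitational acceleration, m/s^2."""


def newtons_to_bw(force_n: float, body_mass_kg: float, g: float = G_STANDARD) -> float:
    """Convert a force in newtons to bodyweight units for a given body mass."""
    if body_mass_kg <= 0:
        raise ValueError("body_mass_kg must be positive")
    return force_n / (body_mass_kg * g)


def bw_to_newtons(force_bw: float, body_mass_kg: float, g: float = G_STANDARD) -> float:
    """Convert a force in bodyweight units to newtons."""
    if body_mass_kg <= 0:
        raise ValueError("body_mass_kg must be positive")
    return force_bw * body_mass_kg * g


def arc_to_central_angle_deg(arc_length_mm: float, radius_mm: float) -> float:
    """Central angle (degrees) subtended by an arc of given length on a circle.

    Useful for expressing a circumferential drag distance on a cylindrical
    perch as the angular span of surface tangent directions encountered.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    return math.degrees(arc_length_mm / radius_mm)


def inches_to_mm(inches: float) -> float:
    return inches * 25.4


def fraction_as_percent(numerator: float, denominator: float) -> float:
    """100 * numerator / denominator, guarding against a zero denominator."""
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    return 100.0 * numerator / denominator
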