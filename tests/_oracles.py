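"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: tip-path
tracing is a per-position python loop over the window formula, the
penetration slope is built from an explicit circle construction, and
grasp feasibility is decided by enumerating basic solutions of the
friction-cone edge-generator system.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_trace(positions_mm, heights_um, tip_radius_um):
    """Direct max-over-window tip-path formula, one position at a time."""
    pos_um = np.asarray(positions_mm, dtype=float) * 1000.0
    h = np.asarray(heights_um, dtype=float)
    r = float(tip_radius_um)
    out = np.empty_like(h)
    for i in range(h.size):
        dx = pos_um - pos_um[i]
        mask = np.abs(dx) <= r
        out[i] = np.max(h[mask] + np.sqrt(r**2 - dx[mask] ** 2)) - r
    return out


def geometric_penetration_slope(depth_ratio: float) -> float:
    """Slope via explicit construction: circle of radius R indented by d.

    Contact half-width a = sqrt(R*d); slope of the chord from the tip
    bottom (0, -R) to the contact point (a, -sqrt(R^2 - a^2)).
    """
    big_r = 1.0
    d = depth_ratio * big_r
    a = math.sqrt(big_r * d)
    x1, y1 = 0.0, -big_r
    x2, y2 = a, -math.sqrt(big_r**2 - a**2)
    return (y2 - y1) / (x2 - x1)


def sawtooth_usable_fraction(face_angle_deg: float, theta_eff_deg: float) -> float:
    """Expected n_a for a symmetric triangular profile with +-face_angle faces
    traced by a vanishing tip: half the segments rise in the drag direction,
    and they count iff the face angle exceeds the threshold."""
    return 0.5 if face_angle_deg > theta_eff_deg else 0.0


def exponential_max_expectation(scale: float, n: int) -> float:
    """E[max of n iid Exponential(scale)] = scale * (1 + 1/2 + ... + 1/n)."""
    return scale * sum(1.0 / i for i in range(1, n + 1))


def uniform_max_expectation(low: float, high: float, n: int) -> float:
    """E[max of n iid Uniform(low, high)] = low + (high - low) * n / (n + 1)."""
    return low + (high - low) * n / (n + 1.0)


def make_grasp_oracle(layout, tol: float = 1e-7):
    """Exact feasibility oracle by basic-solution enumeration.

    In 2D each Coulomb cone is spanned by its two edge generators
    d +- mu*s, so every contact force is a non-negative combination of
    those edges.  Claw caps become slack equalities.  The query wrench is
    feasible iff the standard-form system (A x = b, x >= 0) has a
    solution, which (A having full row rank) happens iff some basic
    solution is non-negative; all column subsets are enumerated.
    """
    names = layout.contact_names
    _, nrm, tan = layout.contact_geometry()
    b_x, _ = layout.body_axes()
    radius = layout.perch_radius_mm
    side1 = {n for n in names if layout.contact_angles_deg[n] < 0} | {"P2"}
    side2 = {n for n in names if layout.contact_angles_deg[n] > 0} | {"P2"}

    cols = []
    claw_idx = []
    for i, name in enumerate(names):
        mu = layout.contact_mu(name)
        for sgn in (+1.0, -1.0):
            d = nrm[i] + sgn * mu * tan[i]
            w1 = 1.0 if name in side1 else 0.0
            w2 = 1.0 if name in side2 else 0.0
            cols.append([d[0], d[1], radius * sgn * mu, w1 * (b_x @ d), w2 * (b_x @ d)])
        if name.startswith("C"):
            claw_idx.append(i)
    a5 = np.array(cols).T  # (5, 10): edge-generator wrench/squeeze contributions
    ncap = len(claw_idx)
    a_full = np.zeros((5 + ncap, 10 + ncap))
    a_full[:5, :10] = a5
    caps = np.zeros(ncap)
    for j, ci in enumerate(claw_idx):
        a_full[5 + j, 2 * ci] = 1.0
        a_full[5 + j, 2 * ci + 1] = 1.0
        a_full[5 + j, 10 + j] = 1.0
        caps[j] = layout.contact_cap(names[ci])

    m, nv = a_full.shape
    bases = list(itertools.combinations(range(nv), m))
    mats = np.stack([a_full[:, list(bs)] for bs in bases])
    pinvs = np.linalg.pinv(mats)

    def feasible(query) -> bool:
        f_ext = np.array([query.f_x, query.f_y])
        fx_b = float(b_x @ f_ext)
        b = np.concatenate(
            [
                [
                    query.f_x,
                    query.f_y,
                    query.t_z,
                    query.f_sqz + max(fx_b, 0.0),
                    -query.f_sqz + min(fx_b, 0.0),
                ],
                caps,
            ]
        )
        x = pinvs @ b
        resid = np.abs(mats @ x[..., None] - b[:, None]).max(axis=(1, 2))
        ok = (resid < tol) & np.all(x > -1e-9, axis=1)
        return bool(np.any(ok))

    return feasible
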