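"""2D rigid-body static-grasp feasibility, wrench space, and safety margins.

The foot is modelled as five contacts on a circular perch: a centre toe
pad (P2), mirrored toe pads (P1/P3), and mirrored claws (C1/C2).  A
queried external wrench (F_x, F_y, T_z) is feasible when contact forces
exist that balance it subject to force/torque equilibrium, two squeeze
(internal force) constraints along the foot's lateral axis, Coulomb
friction cones at every contact, non-negative normals, and a cap on claw
normal force.  In 2D every constraint is linear, so feasibility is
resolved exactly as a linear program minimising total normal force.

Frames: queries are expressed in the perch frame n (n_y vertically up
from the perch centre O).  The foot frame b is rotated by the landing
angle about the perch axis; b_y points from O toward the ankle.  The
squeeze constraints act along b_x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "ContactLayout",
    "WrenchQuery",
    "ContactForceSolution",
    "SafetyMargins",
    "build_layout",
    "check_feasible",
    "wrench_space",
    "safety_margin",
    "safety_margins_all",
    "margins_over_trace",
]

# contact angles (deg from foot-centre ray) keyed by perch diameter in inches
_LAYOUT_ANGLES = {
    0.75: {"pad": 45.0, "claw": 85.0},
    1.5: {"pad": 20.0, "claw": 45.0},
}

FEASIBILITY_TOL = 1e-8
DEFAULT_CLAW_CAP_BW = 3.0


@dataclass(frozen=True)
class ContactLayout:
    """Five-contact foot-perch geometry plus friction and load limits.

    ``contact_angles_deg`` maps contact name -> angle from the foot-centre
    ray, positive toward +b_x.  The layout must be mirror-symmetric:
    P2 at 0, P1/P3 and C1/C2 at opposite angles.
    """

    perch_radius_mm: float
    contact_angles_deg: dict = field(
        default_factory=lambda: {"C1": 85.0, "P1": 45.0, "P2": 0.0, "P3": -45.0, "C2": -85.0}
    )
    landing_angle_deg: float = 0.0
    mu_pad: float = 0.5
    mu_claw: float = 2.0
    claw_normal_cap_bw: float = DEFAULT_CLAW_CAP_BW
    split_center_pad: bool = False  # halve P2's b_x force between squeeze sides

    def __post_init__(self) -> None:
        if self.perch_radius_mm <= 0:
            raise ValueError("perch_radius_mm must be positive")
        if self.mu_pad < 0 or self.mu_claw < 0:
            raise ValueError("friction coefficients must be non-negative")
        if self.claw_normal_cap_bw <= 0:
            raise ValueError("claw_normal_cap_bw must be positive")
        ang = self.contact_angles_deg
        expected = {"C1", "P1", "P2", "P3", "C2"}
        if set(ang) != expected:
            raise ValueError(f"contact_angles_deg must have keys {sorted(expected)}")
        if abs(ang["P2"]) > 1e-9:
            raise ValueError("P2 must sit on the foot-centre ray (0 deg)")
        if abs(ang["P1"] + ang["P3"]) > 1e-9 or abs(ang["C1"] + ang["C2"]) > 1e-9:
            raise ValueError("P1/P3 and C1/C2 must be mirrored about the foot-centre ray")

    @property
    def contact_names(self) -> tuple:
        return ("C1", "P1", "P2", "P3", "C2")

    def contact_mu(self, name: str) -> float:
        return self.mu_claw if name.startswith("C") else self.mu_pad

    def contact_cap(self, name: str) -> float:
        return self.claw_normal_cap_bw if name.startswith("C") else np.inf

    def contact_geometry(self):
        """Per-contact unit vectors in the perch frame.

        Returns (positions_mm, normal_dirs, tangent_dirs): the normal
        direction points from the contact toward the perch centre; the
        tangent is the counter-clockwise perch tangent, so a shear force
        t * tangent exerts torque about O of t * perch_radius.
        """
        gamma = math.radians(self.landing_angle_deg)
        pos, nrm, tan = [], [], []
        for name in self.contact_names:
            alpha = math.radians(self.contact_angles_deg[name])
            # foot-centre ray at angle gamma from vertical; contact alpha from that ray
            phi = gamma + alpha  # angle from +n_y, positive toward +n_x at gamma=0
            u = np.array([math.sin(phi), math.cos(phi)])  # O -> contact unit vector
            pos.append(self.perch_radius_mm * u)
            nrm.append(-u)
            tan.append(np.array([-u[1], u[0]]))
        return np.array(pos), np.array(nrm), np.array(tan)

    def body_axes(self):
        """Foot-frame unit vectors (b_x, b_y) expressed in the perch frame."""
        gamma = math.radians(self.landing_angle_deg)
        b_y = np.array([math.sin(gamma), math.cos(gamma)])
        b_x = np.array([b_y[1], -b_y[0]])
        return b_x, b_y


@dataclass(frozen=True)
class WrenchQuery:
    """External wrench on the foot (perch frame) plus internal squeeze force."""

    f_x: float
    f_y: float
    t_z: float = 0.0  # bw*mm
    f_sqz: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.f_x, self.f_y, self.t_z, self.f_sqz):
            if not math.isfinite(v):
                raise ValueError("wrench components must be finite")
        if self.f_sqz < 0:
            raise ValueError("squeeze force must be non-negative")


@dataclass(frozen=True)
class ContactForceSolution:
    feasible: bool
    normals_bw: np.ndarray | None
    shears_bw: np.ndarray | None
    objective_bw: float | None
    status: str
    max_residual: float = 0.0


@dataclass(frozen=True)
class SafetyMargins:
    sm_x: float | None = None
    sm_y: float | None = None
    sm_t: float | None = None
    tolerance: float = 1e-3
    query_feasible: bool = True
    unbounded: dict = field(default_factory=dict)


def build_layout(
    perch_diameter_in: float,
    landing_angle_deg: float = 0.0,
    mu_pad: float = 0.5,
    mu_claw: float = 2.0,
    claw_normal_cap_bw: float = DEFAULT_CLAW_CAP_BW,
    split_center_pad: bool = False,
) -> ContactLayout:
    """Standard five-contact layout for a supported perch diameter.

    Only 0.75" and 1.5" perches are modelled.  On the smallest (0.25")
    perch the foot wraps fully around and grasping is limited by muscular
    and structural constraints rather than surface friction, so it is
    rejected explicitly.
    """
    key = None
    for k in _LAYOUT_ANGLES:
        if abs(perch_diameter_in - k) < 1e-9:
            key = k
    if key is None:
        raise ValueError(
            f"perch diameter {perch_diameter_in}\" is not modelled (supported: 0.75, 1.5); "
            "a fully wrapped small perch is limited by muscular/structural constraints, "
            "not surface friction"
        )
    ang = _LAYOUT_ANGLES[key]
    return ContactLayout(
        perch_radius_mm=perch_diameter_in * 25.4 / 2.0,
        contact_angles_deg={
            "C1": ang["claw"],
            "P1": ang["pad"],
            "P2": 0.0,
            "P3": -ang["pad"],
            "C2": -ang["claw"],
        },
        landing_angle_deg=landing_angle_deg,
        mu_pad=mu_pad,
        mu_claw=mu_claw,
        claw_normal_cap_bw=claw_normal_cap_bw,
        split_center_pad=split_center_pad,
    )


def _assemble_lp(layout: ContactLayout, query: WrenchQuery):
    """Build the LP arrays.  Variables: [n_1..n_5, t_1..t_5]."""
    names = layout.contact_names
    _, nrm, tan = layout.contact_geometry()
    b_x, _ = layout.body_axes()
    radius = layout.perch_radius_mm
    nc = len(names)

    # equality rows: Fx, Fy balance; torque about O; squeeze side 1; squeeze side 2
    a_eq = np.zeros((5, 2 * nc))
    b_eq = np.zeros(5)
    for i in range(nc):
        a_eq[0, i] = nrm[i, 0]
        a_eq[0, nc + i] = tan[i, 0]
        a_eq[1, i] = nrm[i, 1]
        a_eq[1, nc + i] = tan[i, 1]
        a_eq[2, nc + i] = radius  # normals pass through O: zero moment arm
    b_eq[0] = query.f_x
    b_eq[1] = query.f_y
    b_eq[2] = query.t_z

    # squeeze constraints along b_x; external force expressed in foot frame.
    # Contacts press toward the perch centre, so the side whose normals have
    # positive b_x components (the -b_x side of the foot) carries +F_sqz.
    f_ext = np.array([query.f_x, query.f_y])
    fx_b = float(b_x @ f_ext)
    side1 = {n for n in names if layout.contact_angles_deg[n] < 0} | {"P2"}
    side2 = {n for n in names if layout.contact_angles_deg[n] > 0} | {"P2"}
    for i, name in enumerate(names):
        w1 = 1.0 if name in side1 else 0.0
        w2 = 1.0 if name in side2 else 0.0
        if layout.split_center_pad and name == "P2":
            w1 = w2 = 0.5
        a_eq[3, i] += w1 * float(b_x @ nrm[i])
        a_eq[3, nc + i] += w1 * float(b_x @ tan[i])
        a_eq[4, i] += w2 * float(b_x @ nrm[i])
        a_eq[4, nc + i] += w2 * float(b_x @ tan[i])
    b_eq[3] = query.f_sqz + max(fx_b, 0.0)
    b_eq[4] = -query.f_sqz + min(fx_b, 0.0)

    # friction cones: +-t_i - mu_i n_i <= 0
    a_ub = np.zeros((2 * nc, 2 * nc))
    b_ub = np.zeros(2 * nc)
    for i, name in enumerate(names):
        mu = layout.contact_mu(name)
        a_ub[2 * i, nc + i] = 1.0
        a_ub[2 * i, i] = -mu
        a_ub[2 * i + 1, nc + i] = -1.0
        a_ub[2 * i + 1, i] = -mu

    bounds = [(0.0, layout.contact_cap(name)) for name in names] + [(None, None)] * nc
    cost = np.concatenate([np.ones(nc), np.zeros(nc)])
    return cost, a_ub, b_ub, a_eq, b_eq, bounds


def check_feasible(layout: ContactLayout, query: WrenchQuery) -> ContactForceSolution:
    """Solve the static-grasp LP for one wrench query.

    Returns the minimum-total-normal contact force set when feasible, or a
    certificate of infeasibility.  Solver failures are reported distinctly
    from proven infeasibility.
    """
    cost, a_ub, b_ub, a_eq, b_eq, bounds = _assemble_lp(layout, query)
    res = linprog(cost, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status == 0:
        nc = len(layout.contact_names)
        x = res.x
        resid = float(np.max(np.abs(a_eq @ x - b_eq)))
        return ContactForceSolution(
            feasible=True,
            normals_bw=x[:nc].copy(),
            shears_bw=x[nc:].copy(),
            objective_bw=float(res.fun),
            status="optimal",
            max_residual=resid,
        )
    if res.status == 2:
        return ContactForceSolution(False, None, None, None, "infeasible")
    return ContactForceSolution(False, None, None, None, f"solver-error({res.status}): {res.message}")


def wrench_space(
    layout: ContactLayout,
    fx_grid,
    fy_grid,
    tz_grid,
    f_sqz: float = 0.0,
) -> np.ndarray:
    """Boolean feasibility volume over the (F_x, F_y, T_z) grid.

    Axis order of the result is (fx, fy, tz).  Slicing at fixed T_z gives
    the 2D force-plane cross-sections of the stable region.
    """
    fx_grid = np.asarray(fx_grid, dtype=float)
    fy_grid = np.asarray(fy_grid, dtype=float)
    tz_grid = np.asarray(tz_grid, dtype=float)
    vol = np.zeros((fx_grid.size, fy_grid.size, tz_grid.size), dtype=bool)
    for i, fx in enumerate(fx_grid):
        for j, fy in enumerate(fy_grid):
            for k, tz in enumerate(tz_grid):
                sol = check_feasible(layout, WrenchQuery(fx, fy, tz, f_sqz))
                vol[i, j, k] = sol.feasible
    return vol


def _margin_one_sense(
    layout: ContactLayout,
    query: WrenchQuery,
    direction: np.ndarray,
    cap: float,
    tol: float,
) -> tuple[float, bool]:
    """Bisect the added load along ``direction`` = (dFx, dFy, dTz) until infeasible."""

    def feasible_at(step: float) -> bool:
        q = WrenchQuery(
            query.f_x + step * direction[0],
            query.f_y + step * direction[1],
            query.t_z + step * direction[2],
            query.f_sqz,
        )
        return check_feasible(layout, q).feasible

    if not feasible_at(0.0):
        return 0.0, False
    if feasible_at(cap):
        return cap, True
    lo, hi = 0.0, cap
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if feasible_at(mid):
            lo = mid
        else:
            hi = mid
    return lo, False


def safety_margin(
    layout: ContactLayout,
    query: WrenchQuery,
    direction: str,
    tol: float = 1e-3,
    cap: float = 100.0,
) -> SafetyMargins:
    """Extra load sustainable along one foot-frame direction before slip.

    ``direction`` is "x", "y", or "T".  SM_x and SM_T take the minimum
    over the + and - senses; SM_y is searched along +b_y only (away from
    the perch — pulling into the perch is not the failure of interest).
    A query that is itself infeasible reports margin 0 with a flag.
    """
    base = check_feasible(layout, query)
    if not base.feasible:
        return SafetyMargins(
            **{f"sm_{direction.lower()}": 0.0}, tolerance=tol, query_feasible=False
        )
    b_x, b_y = layout.body_axes()
    unbounded = {}
    if direction == "x":
        senses = [np.array([b_x[0], b_x[1], 0.0]), np.array([-b_x[0], -b_x[1], 0.0])]
    elif direction == "y":
        senses = [np.array([b_y[0], b_y[1], 0.0])]
    elif direction == "T":
        senses = [np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])]
    else:
        raise ValueError("direction must be 'x', 'y', or 'T'")
    vals = []
    hit_cap = False
    for d in senses:
        v, capped = _margin_one_sense(layout, query, d, cap, tol)
        vals.append(v)
        hit_cap = hit_cap or capped
    margin = float(min(vals))
    key = {"x": "sm_x", "y": "sm_y", "T": "sm_t"}[direction]
    if hit_cap and margin >= cap:
        unbounded[key] = True
    return SafetyMargins(**{key: margin}, tolerance=tol, query_feasible=True, unbounded=unbounded)


def safety_margins_all(
    layout: ContactLayout, query: WrenchQuery, tol: float = 1e-3, cap: float = 100.0
) -> SafetyMargins:
    """SM_x, SM_y, and SM_T for one query."""
    parts = [safety_margin(layout, query, d, tol=tol, cap=cap) for d in ("x", "y", "T")]
    unbounded = {}
    for p in parts:
        unbounded.update(p.unbounded)
    return SafetyMargins(
        sm_x=parts[0].sm_x,
        sm_y=parts[1].sm_y,
        sm_t=parts[2].sm_t,
        tolerance=tol,
        query_feasible=all(p.query_feasible for p in parts),
        unbounded=unbounded,
    )


def margins_over_trace(
    layout: ContactLayout,
    time_s,
    f_x,
    f_y,
    t_z,
    f_sqz,
    claws_in_contact=None,
    tol: float = 1e-2,
    cap: float = 20.0,
):
    """Per-timestep safety margins for a landing force trace.

    Margins are emitted only at timesteps where ``claws_in_contact`` is
    true (all claws engaged); elsewhere the row holds NaNs.  Returns a
    list of dict rows.
    """
    time_s = np.asarray(time_s, dtype=float)
    chans = [np.asarray(c, dtype=float) for c in (f_x, f_y, t_z, f_sqz)]
    if claws_in_contact is None:
        claws_in_contact = np.ones(time_s.size, dtype=bool)
    claws_in_contact = np.asarray(claws_in_contact, dtype=bool)
    rows = []
    for i, t in enumerate(time_s):
        row = {"time_s": float(t), "sm_x": np.nan, "sm_y": np.nan, "sm_t": np.nan}
        if claws_in_contact[i]:
            q = WrenchQuery(chans[0][i], chans[1][i], chans[2][i], max(chans[3][i], 0.0))
            sm = safety_margins_all(layout, q, tol=tol, cap=cap)
            row.update({"sm_x": sm.sm_x, "sm_y": sm.sm_y, "sm_t": sm.sm_t})
        rows.append(row)
    return rows
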