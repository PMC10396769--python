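"""Simplified hip musculoskeletal model: scaling, wrapping, inverse dynamics,
polynomial muscle recruitment, and hip joint reaction force.

The model is deliberately reduced to the level at which the governing
equations act: a single hip joint, a stance-limb segment carrying the ground
reaction, and a configurable set of muscle elements in four functional
groups (extensors, flexors, abductors, adductors, plus rotator accents).
Muscle forces are distributed by minimising the polynomial criterion

    G(f) = sum_i (f_i / N_i)^p,   subject to  C f = r,  f_i >= 0,

with p = 3 by default ("cubic polynomial" recruitment), where N_i is the
momentary strength of muscle i, C collects moment arms about the hip and
r the net hip moment from inverse dynamics.  The hip joint reaction force
(HRF) is the contact force that closes the force balance once muscle forces
are known, reported in body-weight (BW) multiples.

Coordinate convention (pelvis-aligned): x anterior, y vertical up,
z lateral, origin at the hip joint centre.  Units: m, kg, s, N, N*m.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .gait_processing import GaitCycleCurves, PhaseSet

G_ACCEL = 9.81  # m/s^2


class DomainError(ValueError):
    """Parameter combination outside the model's physical domain."""


class GeometryError(ValueError):
    """Invalid muscle/wrapping geometry."""


class InfeasibleRecruitmentError(RuntimeError):
    """No non-negative muscle forces can balance the requested moments."""

    def __init__(self, residual: float, r: np.ndarray):
        self.residual = residual
        super().__init__(
            f"recruitment infeasible: best equality residual {residual:.3e} "
            f"for moment demand {np.array2string(r, precision=3)}"
        )


# ---------------------------------------------------------------------------
# Strength scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingParams:
    """Length/mass/fat scaling of generic model strength to a subject.

    ``F = F0 * (k_m / k_L) * (R_muscle_subject / R_muscle_generic)`` with
    ``R_muscle = 0.5 - R_fat``: strength grows with mass, shrinks with
    stature at fixed mass, and scales with the lean fraction relative to
    the generic model.
    """

    F0: float                    # generic maximum muscle strength, N
    k_m: float = 1.0             # subject/generic body-mass ratio
    k_L: float = 1.0             # subject/generic body-height ratio
    R_fat_subject: float = 0.25
    R_fat_generic: float = 0.25

    def __post_init__(self) -> None:
        if self.k_m <= 0 or self.k_L <= 0:
            raise DomainError("mass and height ratios must be positive")
        for r in (self.R_fat_subject, self.R_fat_generic):
            if not 0.0 <= r < 0.5:
                raise DomainError("fat ratio must lie in [0, 0.5) so muscle ratio stays positive")


def scale_strength(params: ScalingParams) -> float:
    """Subject-specific maximum muscle strength in N."""
    r_subj = 0.5 - params.R_fat_subject
    r_gen = 0.5 - params.R_fat_generic
    return params.F0 * (params.k_m / params.k_L) * (r_subj / r_gen)


# ---------------------------------------------------------------------------
# Attachment morphing
# ---------------------------------------------------------------------------

def morph_attachments(
    generic_points: np.ndarray,
    generic_landmarks: np.ndarray,
    subject_landmarks: np.ndarray,
) -> np.ndarray:
    """Map generic attachment points into subject space by a landmark-fit
    affine transform (least squares on >= 4 non-coplanar landmark pairs)."""
    gp = np.atleast_2d(np.asarray(generic_points, dtype=float))
    gl = np.asarray(generic_landmarks, dtype=float)
    sl = np.asarray(subject_landmarks, dtype=float)
    if gl.shape != sl.shape or gl.shape[0] < 4 or gl.shape[1] != 3:
        raise GeometryError("need matching landmark sets of >= 4 points in 3-D")
    A = np.hstack([gl, np.ones((gl.shape[0], 1))])
    if np.linalg.matrix_rank(A) < 4:
        raise GeometryError("landmarks are coplanar/degenerate; affine fit is rank-deficient")
    T, *_ = np.linalg.lstsq(A, sl, rcond=None)
    return np.hstack([gp, np.ones((gp.shape[0], 1))]) @ T


# ---------------------------------------------------------------------------
# Muscle elements and cylinder wrapping
# ---------------------------------------------------------------------------

@dataclass
class MuscleElement:
    """Straight-line or cylinder-wrapped muscle path with a strength N_i."""

    name: str
    group: str                       # extensor | flexor | abductor | adductor
    origin: np.ndarray               # pelvic attachment, m
    insertion: np.ndarray            # femoral attachment, m
    strength_N: float
    wrap_cylinder: dict | None = None  # {point, axis, radius}

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.insertion = np.asarray(self.insertion, dtype=float)
        if self.strength_N <= 0:
            raise DomainError(f"muscle {self.name}: strength must be positive")
        if np.allclose(self.origin, self.insertion):
            raise GeometryError(f"muscle {self.name}: origin equals insertion")


VALID_GROUPS = ("extensor", "flexor", "abductor", "adductor")


def wrap_path(muscle: MuscleElement) -> dict:
    """Shortest path of a muscle over its wrapping cylinder (if any).

    If the straight origin-insertion segment clears the cylinder, the path
    is straight.  Otherwise the path is tangent - helical arc - tangent;
    developing the cylinder plus the two tangent planes into a flat sheet
    turns that path into a straight line, so its length is

        sqrt(L_xy^2 + dz^2)

    with L_xy the in-plane tangent-arc-tangent length and dz the axial
    travel.  Returns path length and the unit lines of action at both ends.
    """
    p0, p1 = muscle.origin, muscle.insertion
    if muscle.wrap_cylinder is None:
        return _straight_path(p0, p1)
    c = np.asarray(muscle.wrap_cylinder["point"], dtype=float)
    axis = np.asarray(muscle.wrap_cylinder["axis"], dtype=float)
    R = float(muscle.wrap_cylinder["radius"])
    axis = axis / np.linalg.norm(axis)

    def decompose(p):
        rel = p - c
        z = float(rel @ axis)
        xy = rel - z * axis
        return xy, z

    xy0, z0 = decompose(p0)
    xy1, z1 = decompose(p1)
    d0, d1 = np.linalg.norm(xy0), np.linalg.norm(xy1)
    if d0 < R - 1e-12 or d1 < R - 1e-12:
        raise GeometryError(f"muscle {muscle.name}: endpoint inside wrapping cylinder")

    # Does the planar projection of the straight segment hit the circle?
    if not _segment_hits_circle(xy0, xy1, R):
        return _straight_path(p0, p1)

    # Planar tangent-arc-tangent construction (shorter of the two wraps).
    e1 = np.array([v for v in _plane_basis(axis)])
    u0 = np.array([xy0 @ e1[0], xy0 @ e1[1]])
    u1 = np.array([xy1 @ e1[0], xy1 @ e1[1]])
    best = None
    for sense in (+1.0, -1.0):
        t0, q0 = _tangent_point(u0, R, sense)
        t1, q1 = _tangent_point(u1, R, -sense)
        arc = _arc_angle(q0, q1, sense)
        L_xy = t0 + t1 + R * arc
        if best is None or L_xy < best[0]:
            best = (L_xy, q0, q1, t0, t1)
    L_xy, q0, q1, t0, t1 = best
    dz = z1 - z0
    length = float(np.hypot(L_xy, dz))

    # lines of action: tangent directions at the endpoints, with the axial
    # component distributed along the developed path.
    def lift(u2, z):
        return c + u2[0] * e1[0] + u2[1] * e1[1] + z * axis

    frac0 = t0 / L_xy if L_xy > 0 else 0.0
    frac1 = t1 / L_xy if L_xy > 0 else 0.0
    tp0 = lift(q0, z0 + dz * frac0)
    tp1 = lift(q1, z1 - dz * frac1)
    dir_origin = _unit(tp0 - p0)
    dir_insertion = _unit(tp1 - p1)
    return {
        "length_m": length,
        "wrapped": True,
        "dir_at_origin": dir_origin,
        "dir_at_insertion": dir_insertion,
    }


def _straight_path(p0: np.ndarray, p1: np.ndarray) -> dict:
    d = _unit(p1 - p0)
    return {
        "length_m": float(np.linalg.norm(p1 - p0)),
        "wrapped": False,
        "dir_at_origin": d,
        "dir_at_insertion": -d,
    }


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _plane_basis(axis: np.ndarray):
    a = np.array([1.0, 0.0, 0.0])
    if abs(axis @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(axis, a))
    e2 = np.cross(axis, e1)
    return e1, e2


def _segment_hits_circle(xy0: np.ndarray, xy1: np.ndarray, R: float) -> bool:
    d = xy1 - xy0
    denom = float(d @ d)
    if denom == 0.0:
        return float(np.linalg.norm(xy0)) < R
    t = float(np.clip(-(xy0 @ d) / denom, 0.0, 1.0))
    closest = xy0 + t * d
    return float(np.linalg.norm(closest)) < R * (1 - 1e-12)


def _tangent_point(u: np.ndarray, R: float, sense: float) -> tuple[float, np.ndarray]:
    """Tangent length from planar point u to circle radius R and the tangent
    contact point, choosing the contact on the given rotational sense."""
    d = float(np.linalg.norm(u))
    t = np.sqrt(max(d * d - R * R, 0.0))
    alpha = np.arctan2(u[1], u[0])
    beta = np.arccos(np.clip(R / d, -1.0, 1.0))
    contact_angle = alpha + sense * beta
    q = R * np.array([np.cos(contact_angle), np.sin(contact_angle)])
    return t, q


def _arc_angle(q0: np.ndarray, q1: np.ndarray, sense: float) -> float:
    """Arc swept from contact q0 to q1 travelling in rotational ``sense``
    (+1 counter-clockwise), in [0, 2*pi)."""
    a0 = np.arctan2(q0[1], q0[0])
    a1 = np.arctan2(q1[1], q1[0])
    return float(np.mod((a1 - a0) * sense, 2 * np.pi))


def effective_line_of_action(muscle: MuscleElement) -> np.ndarray:
    """Unit pull direction on the femur (at the insertion, toward the path)."""
    return wrap_path(muscle)["dir_at_insertion"]


# ---------------------------------------------------------------------------
# Default muscle set
# ---------------------------------------------------------------------------

def default_muscle_set(strength_scale: float = 1.0) -> list[MuscleElement]:
    """Twelve-element peri-ilium muscle set in four functional groups.

    Representative attachment coordinates (m, hip centre at origin) give
    physiologically signed moment arms; together the elements positively
    span all three hip moment axes so any bounded moment demand is
    recruitable.  Strengths are of the order of maximal isometric forces.
    """
    s = strength_scale
    M = MuscleElement
    return [
        M("gluteus_medius_ant", "abductor", [0.02, 0.06, 0.055], [0.005, -0.055, 0.075], 1200 * s),
        M("gluteus_medius_post", "abductor", [-0.03, 0.06, 0.050], [0.0, -0.055, 0.075], 1000 * s),
        M("gluteus_minimus", "abductor", [0.0, 0.04, 0.060], [0.0, -0.05, 0.070], 600 * s),
        M("tensor_fasciae_latae", "abductor", [0.04, 0.05, 0.055], [0.015, -0.09, 0.060], 300 * s),
        M("iliopsoas", "flexor", [-0.01, 0.07, 0.020], [-0.005, -0.06, 0.020], 1500 * s,
          wrap_cylinder={"point": [0.035, 0.0, 0.02], "axis": [0.0, 0.0, 1.0], "radius": 0.02}),
        M("rectus_femoris", "flexor", [0.04, 0.01, 0.030], [0.035, -0.12, 0.035], 900 * s),
        M("gluteus_maximus_sup", "extensor", [-0.06, 0.05, 0.030], [-0.03, -0.06, 0.050], 1500 * s),
        M("gluteus_maximus_inf", "extensor", [-0.07, 0.01, 0.020], [-0.02, -0.08, 0.040], 1000 * s),
        M("hamstrings", "extensor", [-0.05, -0.02, 0.020], [-0.03, -0.15, 0.030], 1300 * s),
        M("adductor_longus", "adductor", [0.03, -0.03, -0.060], [0.005, -0.12, 0.010], 800 * s),
        M("adductor_magnus", "adductor", [-0.02, -0.05, -0.060], [-0.005, -0.10, 0.010], 1200 * s),
        M("piriformis", "extensor", [-0.06, 0.03, 0.0], [0.0, -0.04, 0.070], 400 * s),
    ]


def moment_arm_matrix(muscles: list[MuscleElement], hip_center: np.ndarray | None = None) -> np.ndarray:
    """3 x n matrix of hip moment arms: column i = (a_i - hip) x u_i with
    a_i the femoral attachment and u_i the unit pull direction on the femur."""
    hip = np.zeros(3) if hip_center is None else np.asarray(hip_center, dtype=float)
    cols = []
    for m in muscles:
        u = effective_line_of_action(m)
        cols.append(np.cross(m.insertion - hip, u))
    return np.array(cols).T


# ---------------------------------------------------------------------------
# Inverse dynamics (single stance-limb segment)
# ---------------------------------------------------------------------------

@dataclass
class SegmentParams:
    """Stance-limb segment used in the Newton-Euler hip moment balance."""

    limb_mass_kg: float             # whole stance limb (thigh+shank+foot)
    limb_length_m: float            # hip centre to ground
    com_fraction: float = 0.45      # COM distance from hip / limb length
    gyration_fraction: float = 0.35  # radius of gyration about hip / length

    @classmethod
    def from_body(cls, body_mass_kg: float, height_ratio: float = 1.0) -> "SegmentParams":
        # anthropometric limb mass fraction ~16.1% of body mass, limb
        # length ~0.53 of stature for a 1.7 m generic subject
        return cls(
            limb_mass_kg=0.161 * body_mass_kg,
            limb_length_m=0.9 * height_ratio,
        )

    @property
    def inertia_about_hip(self) -> float:
        r = self.gyration_fraction * self.limb_length_m
        return self.limb_mass_kg * r * r


def _central_diff(y: np.ndarray, dt: float, order: int = 2) -> np.ndarray:
    """Second derivative by central differences; one-sided at the ends."""
    d2 = np.empty_like(y)
    d2[1:-1] = (y[2:] - 2 * y[1:-1] + y[:-2]) / dt**2
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    return d2


def limb_direction(angles_deg: np.ndarray) -> np.ndarray:
    """Unit vector along the limb (hip to ground) from hip angles.

    Sagittal flexion rotates about +z, ab/adduction about +x, axial rotation
    about +y (which leaves the limb axis unchanged for a straight limb).
    Applied to the downward reference direction (0, -1, 0).
    """
    sag = np.deg2rad(angles_deg[:, 0])
    fro = np.deg2rad(angles_deg[:, 1])
    # Rz(sag) @ Rx(fro) @ (0,-1,0)
    x = np.sin(sag) * np.cos(fro)
    y = -np.cos(sag) * np.cos(fro)
    z = np.sin(fro)
    return np.column_stack([x, y, z])


def inverse_dynamics(
    curves: GaitCycleCurves,
    segment: SegmentParams | None = None,
    cycle_duration_s: float | None = None,
) -> np.ndarray:
    """Net hip moment (N*m, 3 axes) per cycle sample.

    Newton-Euler balance on the single stance-limb segment: the muscles must
    supply  r = I*alpha - m_gm - m_grf - m_grm  where the external moments
    are taken about the hip centre.  Ground reactions are applied at the
    point directly below the hip; centre-of-pressure excursion is carried by
    the ground-reaction moment channel.
    """
    if curves.grf_N is None:
        raise ValueError("curves lack ground reaction forces")
    seg = segment or SegmentParams.from_body(curves.body_mass_kg)
    T = cycle_duration_s
    if T is None:
        bounds = curves.meta.get("cycle_bounds_s")
        T = (bounds[1] - bounds[0]) if bounds else 1.1
    n = curves.percent.size
    dt = T / (n - 1)

    # external moment of GRF about hip: lever = ground point - hip
    lever = np.array([0.0, -seg.limb_length_m, 0.0])
    m_grf = np.cross(lever, curves.grf_N)
    m_grm = curves.grm_Nm

    # gravity + inertia of the limb segment
    d = limb_direction(curves.angles_deg)
    com = seg.com_fraction * seg.limb_length_m * d
    m_gravity = np.cross(com, np.array([0.0, -seg.limb_mass_kg * G_ACCEL, 0.0]))

    ang = np.deg2rad(curves.angles_deg)
    alpha = np.column_stack([_central_diff(ang[:, i], dt) for i in range(3)])
    # per-axis angular momentum balance with a single scalar inertia
    axis_map = np.column_stack([alpha[:, 1], alpha[:, 2], alpha[:, 0]])  # (x,y,z) <- (frontal, transverse, sagittal)
    inertial = seg.inertia_about_hip * axis_map

    return inertial - m_grf - m_grm - m_gravity


def limb_inertial_force(
    curves: GaitCycleCurves, segment: SegmentParams, cycle_duration_s: float
) -> np.ndarray:
    """m * a of the limb COM per sample, from finite differences."""
    n = curves.percent.size
    dt = cycle_duration_s / (n - 1)
    d = limb_direction(curves.angles_deg)
    com = segment.com_fraction * segment.limb_length_m * d
    acc = np.column_stack([_central_diff(com[:, i], dt) for i in range(3)])
    return segment.limb_mass_kg * acc


# ---------------------------------------------------------------------------
# Muscle recruitment
# ---------------------------------------------------------------------------

@dataclass
class RecruitmentProblem:
    """min sum_i (f_i/N_i)^p  s.t.  C f = r,  f >= 0."""

    C: np.ndarray                    # (m, n) equilibrium coefficients
    r: np.ndarray                    # (m,) external + inertia load
    N: np.ndarray                    # (n,) muscle strengths
    p: float = 3.0

    def __post_init__(self) -> None:
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.r = np.asarray(self.r, dtype=float).ravel()
        self.N = np.asarray(self.N, dtype=float).ravel()
        if self.C.shape != (self.r.size, self.N.size):
            raise ValueError("C must be (len(r), len(N))")
        if self.p < 1:
            raise DomainError("recruitment exponent p must be >= 1")
        if np.any(self.N <= 0):
            raise DomainError("muscle strengths must be positive")


def _dual_forces(lam: np.ndarray, C: np.ndarray, N: np.ndarray, p: float) -> np.ndarray:
    """KKT-stationary forces for multiplier lam: f_i from
    p f_i^{p-1} / N_i^p = (C^T lam)_i, clipped at the f >= 0 bound."""
    s = np.maximum(C.T @ lam, 0.0)
    return N ** (p / (p - 1.0)) * (s / p) ** (1.0 / (p - 1.0))


def recruit_muscles(
    problem: RecruitmentProblem,
    tol: float = 1e-8,
    warm_lambda: np.ndarray | None = None,
) -> dict:
    """Solve the polynomial recruitment problem.

    Primary path is a dual (Lagrange-multiplier) root solve exploiting the
    closed-form stationarity f_i = N_i^{p/(p-1)} ((C^T lam)_i / p)^{1/(p-1)},
    which reduces the problem to len(r) unknowns; an SLSQP solve on the
    primal is the fallback.  Returns forces, multipliers and KKT residual.
    """
    C, r, N, p = problem.C, problem.r, problem.N, problem.p
    m, n = C.shape

    if np.allclose(r, 0.0):
        return {"forces": np.zeros(n), "lambda": np.zeros(m), "residual": 0.0}

    # feasibility: non-negative least squares must reach r
    f_nnls, rnorm = optimize.nnls(C, r)
    if rnorm > 1e-6 * (1.0 + np.linalg.norm(r, np.inf)):
        raise InfeasibleRecruitmentError(rnorm, r)

    if p == 1.0:
        # linear program limit: nnls solution already satisfies Cf=r
        return {"forces": f_nnls, "lambda": np.zeros(m), "residual": float(rnorm)}

    def residual_fn(lam):
        return C @ _dual_forces(lam, C, N, p) - r

    lam0 = warm_lambda
    if lam0 is None:
        lam0 = np.linalg.lstsq(C @ C.T + 1e-12 * np.eye(m), r, rcond=None)[0]
        # scale so force magnitudes are in the right ballpark
        f0 = _dual_forces(lam0, C, N, p)
        nf = np.linalg.norm(C @ f0)
        if nf > 0:
            lam0 = lam0 * (np.linalg.norm(r) / nf) ** (p - 1.0)

    sol = optimize.root(residual_fn, lam0, method="hybr", tol=1e-12)
    f = _dual_forces(sol.x, C, N, p)
    res = np.linalg.norm(C @ f - r, np.inf) / (1.0 + np.linalg.norm(r, np.inf))
    if not sol.success or res > 1e-6:
        f, lam, res = _recruit_slsqp(problem, f_nnls)
        return {"forces": f, "lambda": lam, "residual": float(res)}
    return {"forces": f, "lambda": sol.x, "residual": float(res)}


def _recruit_slsqp(problem: RecruitmentProblem, f0: np.ndarray):
    C, r, N, p = problem.C, problem.r, problem.N, problem.p
    n = N.size

    def obj(f):
        return float(np.sum((f / N) ** p))

    def grad(f):
        return p * (f / N) ** (p - 1.0) / N

    cons = {"type": "eq", "fun": lambda f: C @ f - r, "jac": lambda f: C}
    res = optimize.minimize(
        obj, np.maximum(f0, 1e-9), jac=grad, method="SLSQP",
        bounds=[(0.0, None)] * n, constraints=[cons],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    f = np.maximum(res.x, 0.0)
    rr = np.linalg.norm(C @ f - r, np.inf) / (1.0 + np.linalg.norm(r, np.inf))
    if rr > 1e-6:
        raise InfeasibleRecruitmentError(rr, r)
    lam = np.linalg.lstsq(C.T, grad(f), rcond=None)[0] if n >= C.shape[0] else np.zeros(C.shape[0])
    return f, lam, rr


# ---------------------------------------------------------------------------
# Hip reaction force and grouping
# ---------------------------------------------------------------------------

def hip_reaction_force(
    muscle_forces: np.ndarray,
    lines_of_action: np.ndarray,
    external_force: np.ndarray,
    body_mass_kg: float,
    inertial_force: np.ndarray | None = None,
    limb_weight: float = 0.0,
) -> dict:
    """Joint contact force on the femoral head from the pelvis, in BW.

    Force balance on the stance limb:
        R + F_grf + sum_i f_i u_i - W_limb = m a
    so  R = m a + W_limb_vec - F_grf - sum f_i u_i.  Reported as vector and
    magnitude normalised by body weight (mass * g).
    """
    f = np.asarray(muscle_forces, dtype=float)
    U = np.atleast_2d(np.asarray(lines_of_action, dtype=float))
    ext = np.asarray(external_force, dtype=float)
    ma = np.zeros(3) if inertial_force is None else np.asarray(inertial_force, dtype=float)
    weight_vec = np.array([0.0, -limb_weight, 0.0])
    R = ma - weight_vec - ext - (U.T @ f if f.size else np.zeros(3))
    bw = body_mass_kg * G_ACCEL
    return {
        "vector_N": R,
        "vector_bw": R / bw,
        "magnitude_bw": float(np.linalg.norm(R) / bw),
    }


def group_muscle_forces(
    forces_per_sample: np.ndarray,
    muscles: list[MuscleElement],
    body_mass_kg: float,
    phase_set: PhaseSet | None = None,
    percent: np.ndarray | None = None,
) -> dict:
    """Per-group summed muscle-force curves in BW, plus per-phase means."""
    F = np.atleast_2d(np.asarray(forces_per_sample, dtype=float))
    if F.shape[1] != len(muscles):
        raise ValueError("force matrix has wrong number of muscles")
    for m in muscles:
        if m.group not in VALID_GROUPS:
            raise KeyError(f"unknown muscle group '{m.group}' for {m.name}")
    bw = body_mass_kg * G_ACCEL
    curves = {}
    for g in VALID_GROUPS:
        cols = [i for i, m in enumerate(muscles) if m.group == g]
        curves[g] = F[:, cols].sum(axis=1) / bw if cols else np.zeros(F.shape[0])
    out = {"curves_bw": curves}
    if phase_set is not None:
        if percent is None:
            percent = np.linspace(0.0, 100.0, F.shape[0])
        masks = phase_set.masks(percent)
        out["phase_means_bw"] = {
            g: [float(c[mk].mean()) if mk.any() else 0.0 for mk in masks]
            for g, c in curves.items()
        }
    return out


# ---------------------------------------------------------------------------
# Full IDA pipeline over a gait cycle
# ---------------------------------------------------------------------------

@dataclass
class IDAResult:
    """Per-sample inverse-dynamics + recruitment output for one gait cycle."""

    percent: np.ndarray
    net_moments_Nm: np.ndarray       # (101, 3)
    muscle_forces_N: np.ndarray      # (101, n_muscles)
    muscle_names: list[str]
    hrf_vectors_bw: np.ndarray       # (101, 3)
    hrf_magnitude_bw: np.ndarray     # (101,)
    group_curves_bw: dict
    phase_aggregates: dict           # per-phase mean HRF vector (BW) etc.
    body_mass_kg: float
    meta: dict = field(default_factory=dict)


def _lowpass_angles(curves: GaitCycleCurves, cutoff_hz: float, T: float) -> GaitCycleCurves:
    """Gaussian low-pass of the angle curves (standard kinematic smoothing
    before numerical differentiation; ~6 Hz is the gait-lab convention)."""
    from scipy.ndimage import gaussian_filter1d

    dt = T / (curves.percent.size - 1)
    sigma = 0.1325 / cutoff_hz / dt     # -3 dB point of a Gaussian kernel
    smoothed = gaussian_filter1d(curves.angles_deg, sigma, axis=0, mode="wrap")
    return GaitCycleCurves(
        percent=curves.percent, angles_deg=smoothed, grf_N=curves.grf_N,
        grm_Nm=curves.grm_Nm, body_mass_kg=curves.body_mass_kg, meta=curves.meta,
    )


def run_ida(
    curves: GaitCycleCurves,
    muscles: list[MuscleElement] | None = None,
    segment: SegmentParams | None = None,
    p: float = 3.0,
    phase_set: PhaseSet | None = None,
    angle_filter_hz: float | None = 6.0,
) -> IDAResult:
    """Inverse dynamics -> recruitment -> HRF for every cycle sample.

    Angle curves are low-pass filtered (default 6 Hz, ``None`` disables)
    before differentiation, as measured kinematics otherwise inject large
    spurious inertial moments.  Produces the per-phase aggregates (mean HRF
    vector and group muscle forces over each RLA phase) consumed by the
    finite-element load builder.
    """
    muscles = muscles if muscles is not None else default_muscle_set()
    seg = segment or SegmentParams.from_body(curves.body_mass_kg)
    phase_set = phase_set or PhaseSet()
    bounds = curves.meta.get("cycle_bounds_s")
    T = (bounds[1] - bounds[0]) if bounds else 1.1
    if angle_filter_hz is not None:
        curves = _lowpass_angles(curves, angle_filter_hz, T)

    r_all = inverse_dynamics(curves, seg, T)
    C = moment_arm_matrix(muscles)
    U = np.array([effective_line_of_action(m) for m in muscles])
    N = np.array([m.strength_N for m in muscles])
    ma = limb_inertial_force(curves, seg, T)
    limb_w = seg.limb_mass_kg * G_ACCEL

    n = curves.percent.size
    F = np.zeros((n, len(muscles)))
    hrf_vec = np.zeros((n, 3))
    hrf_mag = np.zeros(n)
    warm = None
    for i in range(n):
        prob = RecruitmentProblem(C=C, r=r_all[i], N=N, p=p)
        sol = recruit_muscles(prob, warm_lambda=warm)
        warm = sol["lambda"]
        F[i] = sol["forces"]
        h = hip_reaction_force(F[i], U, curves.grf_N[i], curves.body_mass_kg,
                               inertial_force=ma[i], limb_weight=limb_w)
        hrf_vec[i] = h["vector_bw"]
        hrf_mag[i] = h["magnitude_bw"]

    groups = group_muscle_forces(F, muscles, curves.body_mass_kg, phase_set, curves.percent)
    masks = phase_set.masks(curves.percent)
    bw = curves.body_mass_kg * G_ACCEL
    # per-group resultant force vectors (pull on the femur) per sample
    group_vec = {}
    for g in VALID_GROUPS:
        cols = [i for i, m in enumerate(muscles) if m.group == g]
        group_vec[g] = (F[:, cols] @ U[cols]) / bw if cols else np.zeros((n, 3))
    phase_aggregates = {
        "hrf_vector_bw": [hrf_vec[mk].mean(axis=0).tolist() for mk in masks],
        "hrf_magnitude_bw": [float(hrf_mag[mk].mean()) for mk in masks],
        "group_forces_bw": groups.get("phase_means_bw", {}),
        "group_force_vectors_bw": {
            g: [v[mk].mean(axis=0).tolist() for mk in masks] for g, v in group_vec.items()
        },
        "phase_names": list(phase_set.names),
    }
    return IDAResult(
        percent=curves.percent,
        net_moments_Nm=r_all,
        muscle_forces_N=F,
        muscle_names=[m.name for m in muscles],
        hrf_vectors_bw=hrf_vec,
        hrf_magnitude_bw=hrf_mag,
        group_curves_bw=groups["curves_bw"],
        phase_aggregates=phase_aggregates,
        body_mass_kg=curves.body_mass_kg,
        meta={"p": p, "cycle_duration_s": T},
    )
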