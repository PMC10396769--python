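"""Strength scaling, attachment morphing, wrapping, inverse dynamics,
polynomial recruitment and hip-reaction-force balance."""

import numpy as np
import pytest
from scipy import optimize

from paofix import gait_processing as gp
from paofix import msk_model as mm


class TestScaleStrength:
    def test_identity_ratios_return_generic_strength(self):
        p = mm.ScalingParams(F0=1234.5)
        assert mm.scale_strength(p) == pytest.approx(1234.5)

    def test_mass_height_fat_scaling(self):
        p = mm.ScalingParams(F0=1000.0, k_m=1.2, k_L=1.1,
                             R_fat_subject=0.30, R_fat_generic=0.25)
        # 1000 * (1.2/1.1) * (0.20/0.25)
        assert mm.scale_strength(p) == pytest.approx(872.7272727, rel=1e-9)

    def test_linear_in_generic_strength(self):
        p1 = mm.ScalingParams(F0=500.0, k_m=1.3, k_L=0.9, R_fat_subject=0.2)
        p2 = mm.ScalingParams(F0=1000.0, k_m=1.3, k_L=0.9, R_fat_subject=0.2)
        assert mm.scale_strength(p2) == pytest.approx(2 * mm.scale_strength(p1))

    def test_fat_ratio_domain_enforced(self):
        with pytest.raises(mm.DomainError):
            mm.ScalingParams(F0=1.0, R_fat_subject=0.5)


class TestMorphAttachments:
    landmarks = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1.0]])

    def test_identity_landmarks_leave_points_unchanged(self):
        pts = np.array([[0.3, 0.4, 0.5], [1.0, -2.0, 0.1]])
        out = mm.morph_attachments(pts, self.landmarks, self.landmarks)
        assert np.allclose(out, pts, atol=1e-12)

    def test_uniform_scale_recovered(self):
        pts = np.array([[0.2, 0.7, -0.3]])
        out = mm.morph_attachments(pts, self.landmarks, 1.1 * self.landmarks)
        assert np.allclose(out, 1.1 * pts, atol=1e-12)

    def test_random_affine_recovered_to_machine_precision(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        b = rng.normal(size=3)
        gl = rng.normal(size=(6, 3))
        sl = gl @ A.T + b
        pts = rng.normal(size=(4, 3))
        out = mm.morph_attachments(pts, gl, sl)
        assert np.allclose(out, pts @ A.T + b, atol=1e-9)

    def test_coplanar_landmarks_rejected(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(mm.GeometryError):
            mm.morph_attachments(np.zeros((1, 3)), flat, flat)


def _numeric_wrap_oracle(p0, p1, center, axis, R, n=4000):
    """Dense shortest path over the cylinder: discretize candidate contact
    angle pairs and heights; independent of the analytic construction."""
    axis = np.asarray(axis) / np.linalg.norm(axis)
    e1 = np.array([1.0, 0, 0]) if abs(axis[0]) < 0.9 else np.array([0, 1.0, 0])
    e1 = np.cross(axis, e1); e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    def surf(theta, z):
        return center + R * (np.cos(theta) * e1 + np.sin(theta) * e2) + z * axis

    def seg_clearance(a, b):
        """Min distance of segment ab to the cylinder axis (sampled)."""
        ts = np.linspace(0, 1, 200)[:, None]
        pts = a + ts * (b - a)
        rel = pts - center
        rel -= np.outer(rel @ axis, axis)
        return np.linalg.norm(rel, axis=1).min()

    # path: p0 -> surface(theta0, z0s) -> geodesic -> surface(theta1, z1s) -> p1,
    # straight legs penalized if they cut into the cylinder
    def total(params):
        th0, th1, z0s, z1s = params
        a, b = surf(th0, z0s), surf(th1, z1s)
        dth = np.arctan2(np.sin(th1 - th0), np.cos(th1 - th0))
        geo = np.hypot(R * dth, z1s - z0s)
        length = np.linalg.norm(a - p0) + geo + np.linalg.norm(p1 - b)
        pen = max(R - seg_clearance(p0, a), 0.0) + max(R - seg_clearance(b, p1), 0.0)
        return length + 100.0 * pen

    best = np.inf
    rng = np.random.default_rng(1)
    x = rng.uniform([-np.pi, -np.pi, -0.05, -0.05], [np.pi, np.pi, 0.05, 0.05], (60, 4))
    for x0 in x:
        res = optimize.minimize(total, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
        best = min(best, res.fun)
    return best


class TestWrapPath:
    def test_unobstructed_path_is_straight(self):
        m = mm.MuscleElement("m", "flexor", [0.1, 0.1, 0], [0.1, -0.1, 0], 100.0,
                             wrap_cylinder={"point": [0, 0, 0], "axis": [0, 0, 1], "radius": 0.02})
        wp = mm.wrap_path(m)
        assert not wp["wrapped"]
        assert wp["length_m"] == pytest.approx(0.2)

    def test_diametric_surface_points_give_half_circumference(self):
        m = mm.MuscleElement("m", "flexor", [0.02, 0, 0], [-0.02, 0, 0], 100.0,
                             wrap_cylinder={"point": [0, 0, 0], "axis": [0, 0, 1], "radius": 0.02})
        assert mm.wrap_path(m)["length_m"] == pytest.approx(np.pi * 0.02, rel=1e-12)

    def test_general_case_matches_numeric_shortest_path(self):
        p0, p1 = np.array([0.06, 0.0, 0.01]), np.array([-0.05, 0.01, 0.03])
        m = mm.MuscleElement("m", "flexor", p0, p1, 100.0,
                             wrap_cylinder={"point": [0, 0, 0], "axis": [0, 0, 1], "radius": 0.02})
        wp = mm.wrap_path(m)
        assert wp["wrapped"]
        oracle = _numeric_wrap_oracle(p0, p1, np.zeros(3), [0, 0, 1], 0.02)
        assert wp["length_m"] == pytest.approx(oracle, abs=1e-6)

    def test_endpoint_inside_cylinder_rejected(self):
        m = mm.MuscleElement("m", "flexor", [0.005, 0, 0], [-0.05, 0, 0], 100.0,
                             wrap_cylinder={"point": [0, 0, 0], "axis": [0, 0, 1], "radius": 0.02})
        with pytest.raises(mm.GeometryError):
            mm.wrap_path(m)


def make_curves(angles, grf, grm, mass=70.0, T=1.0):
    n = angles.shape[0]
    return gp.GaitCycleCurves(
        percent=np.linspace(0, 100, n), angles_deg=angles, grf_N=grf,
        grm_Nm=grm, body_mass_kg=mass, meta={"cycle_bounds_s": (0.0, T)},
    )


def _newton_euler_oracle(curves, seg, T):
    """Independent re-derivation of the stance-limb moment balance."""
    n = curves.percent.size
    dt = T / (n - 1)
    ang = np.deg2rad(curves.angles_deg)
    alpha = np.zeros_like(ang)
    alpha[1:-1] = (ang[2:] - 2 * ang[1:-1] + ang[:-2]) / dt**2
    alpha[0], alpha[-1] = alpha[1], alpha[-2]
    sag, fro = ang[:, 0], ang[:, 1]
    d = np.column_stack([np.sin(sag) * np.cos(fro),
                         -np.cos(sag) * np.cos(fro), np.sin(fro)])
    com = seg.com_fraction * seg.limb_length_m * d
    I = seg.inertia_about_hip
    r = np.zeros((n, 3))
    lever = np.array([0.0, -seg.limb_length_m, 0.0])
    for i in range(n):
        m_grf = np.cross(lever, curves.grf_N[i])
        m_grav = np.cross(com[i], [0.0, -seg.limb_mass_kg * 9.81, 0.0])
        inertial = I * np.array([alpha[i, 1], alpha[i, 2], alpha[i, 0]])
        r[i] = inertial - m_grf - curves.grm_Nm[i] - m_grav
    return r


class TestInverseDynamics:
    def test_no_loads_massless_limb_gives_zero_moments(self):
        n = 101
        curves = make_curves(np.zeros((n, 3)), np.zeros((n, 3)), np.zeros((n, 3)))
        seg = mm.SegmentParams(limb_mass_kg=1e-12, limb_length_m=0.9)
        r = mm.inverse_dynamics(curves, seg)
        assert np.allclose(r, 0.0, atol=1e-9)

    def test_static_single_leg_stance_frontal_moment(self):
        # vertical GRF W whose centre of pressure sits a lever d medial of
        # the hip: frontal-plane demand = W * d (carried by the GRM channel)
        n, W, d = 101, 700.0, 0.08
        grf = np.zeros((n, 3)); grf[:, 1] = W
        grm = np.zeros((n, 3)); grm[:, 0] = d * W      # (cop x F)_x for z_cop = -d
        curves = make_curves(np.zeros((n, 3)), grf, grm)
        seg = mm.SegmentParams(limb_mass_kg=1e-12, limb_length_m=0.9)
        r = mm.inverse_dynamics(curves, seg)
        assert np.allclose(r[:, 0], -W * d, rtol=1e-12)

    def test_dynamic_trial_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        n = 101
        t = np.linspace(0, 1, n)
        ang = np.column_stack([20 * np.sin(2 * np.pi * t),
                               8 * np.cos(2 * np.pi * t),
                               5 * np.sin(4 * np.pi * t)])
        grf = rng.normal(0, 100, (n, 3))
        grm = rng.normal(0, 10, (n, 3))
        curves = make_curves(ang, grf, grm)
        seg = mm.SegmentParams.from_body(70.0)
        r = mm.inverse_dynamics(curves, seg, 1.0)
        oracle = _newton_euler_oracle(curves, seg, 1.0)
        assert np.allclose(r, oracle, rtol=1e-8, atol=1e-10)


def _slsqp_recruitment_oracle(C, r, N, p):
    n = N.size

    def obj(f):
        return float(np.sum((f / N) ** p))

    res = optimize.minimize(
        obj, np.full(n, 1.0), method="SLSQP", bounds=[(0, None)] * n,
        constraints=[{"type": "eq", "fun": lambda f: C @ f - r}],
        options={"maxiter": 1000, "ftol": 1e-16},
    )
    return res.x


class TestRecruitment:
    def test_single_muscle_forced_by_equality(self):
        prob = mm.RecruitmentProblem(C=[[0.05]], r=[10.0], N=[500.0])
        f = mm.recruit_muscles(prob)["forces"]
        assert f[0] == pytest.approx(200.0, rel=1e-9)

    def test_identical_muscles_split_equally(self):
        prob = mm.RecruitmentProblem(C=[[0.04, 0.04]], r=[8.0], N=[600.0, 600.0])
        f = mm.recruit_muscles(prob)["forces"]
        assert f[0] == pytest.approx(f[1], rel=1e-9)
        assert 0.04 * f.sum() == pytest.approx(8.0, rel=1e-9)

    def test_equal_arm_strength_ratio_follows_closed_form(self):
        # for p = 3 and equal arms: f_i proportional to N_i^(3/2)
        prob = mm.RecruitmentProblem(C=[[0.05, 0.05]], r=[10.0], N=[200.0, 100.0], p=3.0)
        f = mm.recruit_muscles(prob)["forces"]
        assert f[0] / f[1] == pytest.approx(2 ** 1.5, rel=1e-9)
        oracle = _slsqp_recruitment_oracle(np.array([[0.05, 0.05]]), np.array([10.0]),
                                           np.array([200.0, 100.0]), 3.0)
        assert np.allclose(f, oracle, rtol=1e-5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_closed_form_family_random_strengths(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        N = rng.uniform(100, 2000, n)
        arm = 0.06
        prob = mm.RecruitmentProblem(C=[[arm] * n], r=[12.0], N=N, p=3.0)
        f = mm.recruit_muscles(prob)["forces"]
        expected = N ** 1.5
        assert np.allclose(f / f.sum(), expected / expected.sum(), rtol=1e-8)

    def test_solution_invariant_under_muscle_reordering(self):
        rng = np.random.default_rng(4)
        C = rng.normal(size=(3, 8)) * 0.05
        N = rng.uniform(200, 1500, 8)
        r = C @ rng.uniform(0, 300, 8)      # feasible by construction
        f = mm.recruit_muscles(mm.RecruitmentProblem(C=C, r=r, N=N))["forces"]
        perm = rng.permutation(8)
        f_perm = mm.recruit_muscles(
            mm.RecruitmentProblem(C=C[:, perm], r=r, N=N[perm]))["forces"]
        assert np.allclose(f[perm], f_perm, rtol=1e-5, atol=1e-6)

    def test_positive_homogeneity_in_load(self):
        rng = np.random.default_rng(2)
        C = rng.normal(size=(3, 6)) * 0.05
        N = rng.uniform(300, 1200, 6)
        r = C @ rng.uniform(0, 200, 6)
        f1 = mm.recruit_muscles(mm.RecruitmentProblem(C=C, r=r, N=N))["forces"]
        f2 = mm.recruit_muscles(mm.RecruitmentProblem(C=C, r=2.5 * r, N=N))["forces"]
        assert np.allclose(f2, 2.5 * f1, rtol=1e-6, atol=1e-6)
        assert np.allclose(C @ f2, 2.5 * r, atol=1e-8 * (1 + np.abs(r).max()))

    def test_equilibrium_residual_tolerance(self, healthy_noiseless_ida):
        _, curves, ida = healthy_noiseless_ida
        C = mm.moment_arm_matrix(mm.default_muscle_set())
        res = np.abs(C @ ida.muscle_forces_N.T - ida.net_moments_Nm.T).max(axis=0)
        tol = 1e-6 * (1 + np.abs(ida.net_moments_Nm).max(axis=1))
        assert np.all(res <= tol)

    def test_infeasible_problem_raises_with_diagnostics(self):
        # one muscle with a positive arm cannot produce a negative moment
        prob = mm.RecruitmentProblem(C=[[0.05]], r=[-10.0], N=[500.0])
        with pytest.raises(mm.InfeasibleRecruitmentError) as err:
            mm.recruit_muscles(prob)
        assert err.value.residual > 0


class TestHipReactionForce:
    def test_no_muscles_no_loads_zero(self):
        out = mm.hip_reaction_force(np.zeros(0), np.zeros((0, 3)), np.zeros(3), 70.0)
        assert out["magnitude_bw"] == 0.0

    def test_single_leg_stance_statics_oracle(self):
        # supported weight (5/6) BW at 0.10 m lever, vertical abductor with
        # 0.05 m arm: abductor force 2*(5/6)BW, contact = sum of both
        mass = 72.0
        W = mass * 9.81
        supported = 5.0 / 6.0 * W
        abductor = supported * 0.10 / 0.05
        out = mm.hip_reaction_force(
            muscle_forces=np.array([abductor]),
            lines_of_action=np.array([[0.0, 1.0, 0.0]]),
            external_force=np.array([0.0, supported, 0.0]),
            body_mass_kg=mass,
        )
        expected = (supported + abductor) / W
        assert out["magnitude_bw"] == pytest.approx(expected, rel=1e-12)

    def test_linearity_in_loads(self):
        f = np.array([300.0, 150.0])
        U = np.array([[0, 1.0, 0], [0.2, 0.9, 0.1]])
        ext = np.array([10.0, 500.0, -20.0])
        a = mm.hip_reaction_force(f, U, ext, 70.0)
        b = mm.hip_reaction_force(2 * f, U, 2 * ext, 70.0)
        assert np.allclose(b["vector_N"], 2 * a["vector_N"])


class TestGroupForces:
    def test_single_group_curve_equals_total(self):
        muscles = [m for m in mm.default_muscle_set() if m.group == "abductor"]
        F = np.abs(np.random.default_rng(0).normal(200, 50, (11, len(muscles))))
        out = mm.group_muscle_forces(F, muscles, 70.0)
        bw = 70.0 * 9.81
        assert np.allclose(out["curves_bw"]["abductor"], F.sum(axis=1) / bw)
        assert np.allclose(out["curves_bw"]["flexor"], 0.0)

    def test_zero_forces_zero_curves(self):
        muscles = mm.default_muscle_set()
        out = mm.group_muscle_forces(np.zeros((5, len(muscles))), muscles, 70.0)
        for curve in out["curves_bw"].values():
            assert np.allclose(curve, 0.0)

    def test_known_group_sums_exact(self):
        muscles = mm.default_muscle_set()
        rng = np.random.default_rng(1)
        F = np.abs(rng.normal(100, 30, (7, len(muscles))))
        out = mm.group_muscle_forces(F, muscles, 65.0)
        bw = 65.0 * 9.81
        for g in mm.VALID_GROUPS:
            cols = [i for i, m in enumerate(muscles) if m.group == g]
            assert np.allclose(out["curves_bw"][g], F[:, cols].sum(axis=1) / bw)

    def test_unknown_group_label_rejected(self):
        bad = mm.default_muscle_set()
        bad[0].group = "wings"
        with pytest.raises(KeyError):
            mm.group_muscle_forces(np.zeros((3, len(bad))), bad, 70.0)


class TestDefaultModelShape:
    def test_moment_arms_positively_span_all_axes(self):
        C = mm.moment_arm_matrix(mm.default_muscle_set())
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            _, resid = optimize.nnls(C, d)
            assert resid < 1e-8

    def test_healthy_hrf_is_m_shaped(self, healthy_noiseless_ida):
        _, curves, ida = healthy_noiseless_ida
        stance = ida.hrf_magnitude_bw[:63]
        maxima = gp._local_maxima(stance)
        assert len(maxima) == 2

    def test_postop_first_peak_sharper_than_healthy(self):
        from paofix import synthetic_data as sd

        curv = {}
        for group in ("healthy", "postop"):
            profile = sd.profile_for_group(group, seed=1, noise_sd=0.0,
                                           hrf_peak1_mean=3.0, hrf_peak1_sd=0.0,
                                           hrf_peak2_mean=2.2, hrf_peak2_sd=0.0)
            trial = sd.generate_gait_trial(profile)
            ida = mm.run_ida(gp.normalize_to_cycle(trial))
            h = ida.hrf_magnitude_bw
            i = int(np.argmax(h[:35]))
            curv[group] = -(h[i + 1] - 2 * h[i] + h[i - 1])
        assert curv["postop"] > curv["healthy"]
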