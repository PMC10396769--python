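"""Material mapping, load distribution, tet4 elasticity verification, I/O."""

import numpy as np
import pytest

from conftest import box_mesh, uniform_materials
from paofix import fe_solver as fe
from paofix import io as pio


def _point_triangle_distance_oracle(p, tri):
    """Exact point-triangle distance via region classification (independent
    of the package's clamped-barycentric implementation)."""
    a, b, c = tri
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return np.linalg.norm(p - a)
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return np.linalg.norm(p - b)
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return np.linalg.norm(p - c)
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        t = d1 / (d1 - d3)
        return np.linalg.norm(p - (a + t * ab))
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        t = d2 / (d2 - d6)
        return np.linalg.norm(p - (a + t * ac))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return np.linalg.norm(p - (b + t * (c - b)))
    denom = 1.0 / (va + vb + vc)
    v, w = vb * denom, vc * denom
    return np.linalg.norm(p - (a + v * ab + w * ac))


class TestHuToDensity:
    def test_cutoff_value_maps_to_zero(self):
        assert fe.hu_to_density(-1.0) == 0.0

    def test_below_cutoff_maps_to_zero(self):
        assert fe.hu_to_density(-500.0) == 0.0
        assert np.all(fe.hu_to_density(np.array([-1.0, -2.0, -1000.0])) == 0.0)

    def test_hu_1000_reference_value(self):
        # (1000 + 1.4246) * 0.001 / 1.058
        assert fe.hu_to_density(1000.0) == pytest.approx(0.946526087, rel=1e-8)

    def test_never_negative_and_continuous_scale(self):
        hu = np.linspace(-200, 2000, 500)
        rho = fe.hu_to_density(hu)
        assert np.all(rho >= 0)
        assert np.all(np.diff(rho) >= 0)

    def test_non_finite_rejected(self):
        with pytest.raises(fe.MappingError):
            fe.hu_to_density(np.nan)


class TestDensityToModulus:
    def test_zero_density_hits_floor(self):
        assert fe.density_to_modulus(0.0) == fe.DEFAULT_E_MIN

    def test_unit_density_returns_prefactor(self):
        assert fe.density_to_modulus(1.0, a=3000.0, b=1.7) == pytest.approx(3000.0)

    def test_monotone_in_density(self):
        rho = np.linspace(0, 2, 300)
        E = fe.density_to_modulus(rho)
        assert np.all(np.diff(E) >= 0)

    def test_bad_law_parameters_rejected(self):
        with pytest.raises(fe.ConfigurationError):
            fe.density_to_modulus(1.0, a=-5.0)


class TestAssignMaterials:
    @pytest.fixture()
    def cut_mesh(self):
        """Small box with a mid-plane 'osteotomy' surface and one screw set."""
        mesh = box_mesh((20.0, 10.0, 10.0), (8, 4, 4))
        cent = mesh.element_centroids()
        side = cent[:, 0] > 10.0
        faces = mesh.elements[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
        owner = np.repeat(np.arange(mesh.n_elements), 4)
        key = np.sort(faces, axis=1)
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        pairs = {}
        for fi, el in zip(inv, owner):
            pairs.setdefault(fi, []).append(el)
        tris = [uniq[fi] for fi, els in pairs.items()
                if len(els) == 2 and side[els[0]] != side[els[1]]]
        mesh.surfaces = {"osteotomy": np.asarray(tris)}
        mesh.element_sets = {"screw_a": np.arange(5)}
        return mesh

    def test_degradation_one_equals_no_callus(self, cut_mesh):
        hu = np.full(cut_mesh.n_elements, 800.0)
        a = fe.assign_materials(cut_mesh, hu, degradation=1.0)
        b = fe.assign_materials(cut_mesh, hu, callus_margin_mm=0.0)
        assert np.allclose(a.E, b.E)

    def test_zero_margin_flags_nothing(self, cut_mesh):
        hu = np.full(cut_mesh.n_elements, 800.0)
        out = fe.assign_materials(cut_mesh, hu, callus_margin_mm=0.0)
        assert not out.callus_mask.any()

    def test_callus_set_matches_brute_force_distance_filter(self, cut_mesh):
        hu = np.full(cut_mesh.n_elements, 800.0)
        margin = 4.0
        out = fe.assign_materials(cut_mesh, hu, callus_margin_mm=margin)
        tris = cut_mesh.nodes[cut_mesh.surfaces["osteotomy"]]
        cents = cut_mesh.element_centroids()
        dist = np.array([
            min(_point_triangle_distance_oracle(p, t) for t in tris) for p in cents
        ])
        expected = (dist <= margin) & ~out.screw_mask
        assert np.array_equal(out.callus_mask, expected)

    def test_screw_elements_get_implant_material(self, cut_mesh):
        hu = np.full(cut_mesh.n_elements, 800.0)
        out = fe.assign_materials(cut_mesh, hu)
        assert np.all(out.E[:5] == fe.DEFAULT_SCREW_E)
        assert np.all(out.rho[:5] == 0.0)

    def test_missing_osteotomy_surface_rejected(self):
        mesh = box_mesh((4, 4, 4), (2, 2, 2))
        hu = np.full(mesh.n_elements, 500.0)
        with pytest.raises(fe.ConfigurationError):
            fe.assign_materials(mesh, hu, callus_margin_mm=5.0)


class TestLoadDistribution:
    def test_single_node_region_takes_entire_force(self):
        coords = np.array([[1.0, 2.0, 3.0]])
        nf = fe.distribute_force(np.array([0]), coords, np.array([5.0, -2.0, 1.0]))
        assert np.allclose(nf, [[5.0, -2.0, 1.0]])

    def test_zero_force_gives_zero_loads(self, small_pelvis_mesh):
        lc = fe.build_load_case(small_pelvis_mesh, 1,
                                {"joint_contact": np.zeros(3)})
        assert np.allclose(lc.nodal_forces, 0.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_region_static_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(12, 3)) * 10
        nodes = np.arange(12)
        force = rng.normal(size=3) * 100
        moment = rng.normal(size=3) * 50
        nf = fe.distribute_force(nodes, coords, force, moment)
        assert np.allclose(nf.sum(axis=0), force, atol=1e-9)
        rel = coords - coords.mean(axis=0)
        m = np.cross(rel, nf).sum(axis=0)
        assert np.allclose(m, moment, atol=1e-8)

    def test_empty_region_rejected(self):
        with pytest.raises(fe.MappingError):
            fe.distribute_force(np.array([], dtype=int), np.zeros((0, 3)), np.zeros(3))

    def test_unknown_region_name_rejected(self, small_pelvis_mesh):
        with pytest.raises(fe.MappingError):
            fe.build_load_case(small_pelvis_mesh, 1, {"nope": np.ones(3)})


class TestLinearElasticity:
    def test_zero_load_zero_field(self, bar):
        mesh, mat = bar
        lc = fe.LoadCase(1, np.zeros((mesh.n_nodes, 3)), mesh.node_sets["fixed"])
        res = fe.solve_linear_elasticity(mesh, mat, lc)
        assert np.allclose(res.displacements, 0.0)
        assert np.allclose(res.von_mises, 0.0)

    def test_uniaxial_bar_stress_and_tip_displacement(self, bar):
        mesh, mat = bar
        tip = mesh.node_sets["tip"]
        F, A, L, E = 40.0, 4.0, 10.0, 1000.0
        nodal = np.zeros((mesh.n_nodes, 3))
        nodal[tip, 0] = F / len(tip)
        lc = fe.LoadCase(1, nodal, mesh.node_sets["fixed"])
        res = fe.solve_linear_elasticity(mesh, mat, lc)
        assert res.stress[:, 0].mean() == pytest.approx(F / A, rel=0.02)
        assert res.displacements[tip, 0].mean() == pytest.approx(F * L / (E * A), rel=0.02)

    def test_patch_constant_strain_to_machine_precision(self, bar):
        mesh, mat = bar
        model = fe.FEModel(mesh, mat)
        A = np.array([[1e-3, 2e-4, 0.0], [0.0, 5e-4, 1e-4], [2e-4, 0.0, 3e-4]])
        u = mesh.nodes @ A.T
        ue = u[mesh.elements].reshape(mesh.n_elements, 12)
        strain = np.einsum("eij,ej->ei", model.B, ue)
        expected = np.array([A[0, 0], A[1, 1], A[2, 2],
                             A[0, 1] + A[1, 0], A[1, 2] + A[2, 1], A[0, 2] + A[2, 0]])
        assert np.abs(strain - expected).max() < 1e-14

    def test_global_equilibrium_reactions_balance_loads(self, bar):
        mesh, mat = bar
        rng = np.random.default_rng(0)
        nodal = np.zeros((mesh.n_nodes, 3))
        free = np.setdiff1d(np.arange(mesh.n_nodes), mesh.node_sets["fixed"])
        nodal[free] = rng.normal(size=(free.size, 3))
        lc = fe.LoadCase(1, nodal, mesh.node_sets["fixed"])
        res = fe.solve_linear_elasticity(mesh, mat, lc)
        total = nodal.sum(axis=0) + res.reactions.sum(axis=0)
        assert np.abs(total).max() <= 1e-8 * (1 + np.abs(nodal).sum())

    def test_linearity_in_load(self, bar):
        mesh, mat = bar
        nodal = np.zeros((mesh.n_nodes, 3))
        nodal[mesh.node_sets["tip"], 1] = 3.0
        lc = fe.LoadCase(1, nodal, mesh.node_sets["fixed"])
        model = fe.FEModel(mesh, mat)
        a = model.solve(lc)
        b = model.solve(lc.scaled(2.0))
        assert np.allclose(b.displacements, 2 * a.displacements)
        assert np.allclose(b.stress, 2 * a.stress)

    def test_refinement_reduces_bar_stress_error(self):
        # uniform refinement family; error measured away from the clamped
        # face whose constrained contraction is singular
        stress_err, disp_err = [], []
        for div in [(5, 1, 1), (10, 2, 2), (20, 4, 4)]:
            mesh = box_mesh((10.0, 2.0, 2.0), div)
            mat = uniform_materials(mesh)
            fixed = np.where(np.isclose(mesh.nodes[:, 0], 0.0))[0]
            tip = np.where(np.isclose(mesh.nodes[:, 0], 10.0))[0]
            nodal = np.zeros((mesh.n_nodes, 3))
            nodal[tip, 0] = 40.0 / len(tip)
            res = fe.solve_linear_elasticity(
                mesh, mat, fe.LoadCase(1, nodal, fixed))
            cent = mesh.element_centroids()
            interior = (cent[:, 0] > 2.5) & (cent[:, 0] < 7.5)
            stress_err.append(np.abs(res.stress[interior, 0] - 10.0).max())
            disp_err.append(abs(res.displacements[tip, 0].mean() - 0.1))
        assert stress_err[0] > stress_err[1] > stress_err[2]
        assert disp_err[0] > disp_err[1] > disp_err[2]

    def test_unconstrained_system_raises(self, bar):
        mesh, mat = bar
        lc = fe.LoadCase(1, np.zeros((mesh.n_nodes, 3)), np.array([], dtype=int))
        with pytest.raises(fe.SolverError):
            fe.solve_linear_elasticity(mesh, mat, lc)


class TestFieldMetrics:
    def test_hydrostatic_stress_has_zero_von_mises(self):
        s = np.array([[5.0, 5.0, 5.0, 0, 0, 0]])
        assert fe.von_mises_stress(s)[0] == pytest.approx(0.0, abs=1e-12)

    def test_uniaxial_von_mises(self):
        s = np.array([[100.0, 0, 0, 0, 0, 0]])
        assert fe.von_mises_stress(s)[0] == pytest.approx(100.0)

    def test_pure_shear_von_mises(self):
        s = np.array([[0, 0, 0, 10.0, 0, 0]])
        assert fe.von_mises_stress(s)[0] == pytest.approx(10 * np.sqrt(3), rel=1e-12)

    def test_principal_strains_sorted_and_rotation_invariant(self):
        rng = np.random.default_rng(0)
        eps = rng.normal(size=(5, 6)) * 1e-3
        p = fe.principal_strains(eps)
        assert np.all(np.diff(p, axis=1) <= 1e-15)
        # trace preserved
        assert np.allclose(p.sum(axis=1), eps[:, :3].sum(axis=1))


class TestMeshIO:
    def test_inp_roundtrip_preserves_mesh_and_sets(self, tmp_path, small_pelvis_mesh):
        path = tmp_path / "mesh.inp"
        pio.write_inp(small_pelvis_mesh, path)
        back = pio.read_inp(path)
        assert np.allclose(back.nodes, small_pelvis_mesh.nodes)
        assert np.array_equal(back.elements, small_pelvis_mesh.elements)
        for name, ids in small_pelvis_mesh.element_sets.items():
            assert np.array_equal(np.sort(back.element_sets[name]), np.sort(ids))
        for name, ids in small_pelvis_mesh.node_sets.items():
            assert np.array_equal(np.sort(back.node_sets[name]), np.sort(ids))

    def test_vtk_file_structure(self, tmp_path, bar):
        mesh, mat = bar
        nodal = np.zeros((mesh.n_nodes, 3))
        nodal[mesh.node_sets["tip"], 0] = 1.0
        res = fe.solve_linear_elasticity(mesh, mat, fe.LoadCase(1, nodal, mesh.node_sets["fixed"]))
        path = tmp_path / "out.vtk"
        pio.write_vtk(mesh, path, res)
        text = path.read_text().splitlines()
        assert text[0].startswith("# vtk DataFile")
        assert f"POINTS {mesh.n_nodes} double" in text
        assert f"CELLS {mesh.n_elements} {5 * mesh.n_elements}" in text
        assert "VECTORS displacement double" in text
        assert "SCALARS von_mises double 1" in text

    def test_gait_trial_roundtrip(self, tmp_path):
        from paofix import synthetic_data as sd

        trial = sd.generate_gait_trial(sd.profile_for_group("healthy", seed=2))
        path = tmp_path / "trial.csv"
        pio.write_gait_trial(trial, path)
        back = pio.read_gait_trial(path)
        assert np.allclose(back.grf_N, trial.grf_N)
        assert np.allclose(back.angles_deg, trial.angles_deg)
        assert back.body_mass_kg == trial.body_mass_kg
        assert back.events["heel_strikes"] == [0.0, 1.1]
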