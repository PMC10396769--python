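"""Linear tetrahedral finite elements with CT-density material mapping.

The pelvis-fragment-screw construct is meshed with 4-node tetrahedra
(constant-strain elements, single integration point at the centroid).
Bone material follows the CT chain

    HU -> apparent density rho [g/cm^3] -> elastic modulus E [MPa]

with the density mapping

    rho = (HU + 1.4246) * 0.001 / 1.058   for HU > -1
    rho = 0                               for HU <= -1

and a configurable power law E = a * rho^b (bone and screws are treated as
continuous, homogeneous, isotropic and linearly elastic).  A band of
elements within a configurable margin of the osteotomy surface is weakened
by a degradation factor to represent healing callus; screw elements carry
the implant material and are bonded to bone by sharing nodes.

Units: mm - N - MPa; densities g/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


class ConfigurationError(ValueError):
    pass


class MappingError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------

@dataclass
class TetMesh:
    """Labeled tet4 mesh: nodes (mm), connectivity, named node/element sets."""

    nodes: np.ndarray                # (n_nodes, 3) mm
    elements: np.ndarray             # (n_elem, 4) int
    node_sets: dict = field(default_factory=dict)     # name -> int array
    element_sets: dict = field(default_factory=dict)  # name -> int array
    surfaces: dict = field(default_factory=dict)      # name -> (n_tri, 3) node triples
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        if self.elements.size and (self.elements.min() < 0 or self.elements.max() >= len(self.nodes)):
            raise ValueError("element connectivity references invalid nodes")
        vols = self.element_volumes()
        if np.any(vols <= 0):
            raise ValueError(f"{int((vols <= 0).sum())} elements have non-positive volume")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_volumes(self) -> np.ndarray:
        x = self.nodes[self.elements]
        d = x[:, 1:] - x[:, :1]
        return np.abs(np.linalg.det(d)) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def boundary_faces(self) -> np.ndarray:
        """Triangular faces appearing in exactly one element (the surface)."""
        f = _all_faces(self.elements)
        key = np.sort(f, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return f[counts[inv] == 1]

    def boundary_element_mask(self) -> np.ndarray:
        """True for elements owning at least one boundary face."""
        f = _all_faces(self.elements)
        owner = np.repeat(np.arange(self.n_elements), 4)
        key = np.sort(f, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        mask = np.zeros(self.n_elements, dtype=bool)
        mask[owner[counts[inv] == 1]] = True
        return mask


_FACE_IDX = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])


def _all_faces(elements: np.ndarray) -> np.ndarray:
    return elements[:, _FACE_IDX].reshape(-1, 3)


# ---------------------------------------------------------------------------
# Material mapping
# ---------------------------------------------------------------------------

#: HU -> density calibration (apparent BMD in g/cm^3)
HU_DENSITY_OFFSET = 1.4246
HU_DENSITY_SCALE = 0.001
HU_DENSITY_DIVISOR = 1.058
HU_DENSITY_CUTOFF = -1.0

#: density -> modulus power law E = a * rho^b (MPa), literature pelvic/femoral
#: mapping; E_min keeps near-void elements numerically benign.
DEFAULT_MODULUS_A = 2017.3
DEFAULT_MODULUS_B = 2.46
DEFAULT_E_MIN = 1.0
DEFAULT_POISSON_BONE = 0.3

#: titanium-alloy screws, bonded to bone
DEFAULT_SCREW_E = 110000.0
DEFAULT_SCREW_NU = 0.3

DEFAULT_CALLUS_DEGRADATION = 0.3
DEFAULT_CALLUS_MARGIN_MM = 10.0


def hu_to_density(hu) -> np.ndarray | float:
    """Apparent bone mineral density (g/cm^3) from a CT Hounsfield value.

    rho = (HU + 1.4246) * 0.001 / 1.058 above the HU = -1 cutoff, zero at or
    below it (air/soft tissue maps to zero density).
    """
    hu_arr = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu_arr)):
        raise MappingError("HU values must be finite")
    rho = np.where(
        hu_arr > HU_DENSITY_CUTOFF,
        (hu_arr + HU_DENSITY_OFFSET) * HU_DENSITY_SCALE / HU_DENSITY_DIVISOR,
        0.0,
    )
    rho = np.maximum(rho, 0.0)
    return float(rho) if np.isscalar(hu) or rho.ndim == 0 else rho


def density_to_modulus(
    rho,
    a: float = DEFAULT_MODULUS_A,
    b: float = DEFAULT_MODULUS_B,
    e_min: float = DEFAULT_E_MIN,
):
    """Elastic modulus E = max(a * rho^b, e_min) in MPa, monotone in rho."""
    if a <= 0 or b <= 0:
        raise ConfigurationError("power-law parameters a, b must be positive")
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr < 0):
        raise MappingError("density must be non-negative")
    E = np.maximum(a * rho_arr**b, e_min)
    return float(E) if np.isscalar(rho) or E.ndim == 0 else E


@dataclass
class MaterialField:
    """Per-element modulus, Poisson ratio and provenance flags."""

    E: np.ndarray                    # MPa
    nu: np.ndarray
    rho: np.ndarray                  # g/cm^3 (0 for screw elements)
    screw_mask: np.ndarray
    callus_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.E <= 0):
            raise ValueError("all moduli must be positive")
        if np.any((self.nu <= 0) | (self.nu >= 0.5)):
            raise ValueError("Poisson ratios must lie in (0, 0.5)")


def _point_triangle_distances(points: np.ndarray, tri_vertices: np.ndarray) -> np.ndarray:
    """Min distance from each point to a set of triangles (vectorized over points)."""
    a, b, c = tri_vertices[:, 0], tri_vertices[:, 1], tri_vertices[:, 2]
    ab, ac = b - a, c - a
    out = np.full(len(points), np.inf)
    for i in range(len(tri_vertices)):
        d = _pt_tri(points, a[i], ab[i], ac[i])
        out = np.minimum(out, d)
    return out


def _pt_tri(p: np.ndarray, a: np.ndarray, ab: np.ndarray, ac: np.ndarray) -> np.ndarray:
    ap = p - a
    d1, d2 = ap @ ab, ap @ ac
    d00, d01, d11 = ab @ ab, ab @ ac, ac @ ac
    denom = d00 * d11 - d01 * d01
    v = (d11 * d1 - d01 * d2) / denom
    w = (d00 * d2 - d01 * d1) / denom
    inside = (v >= 0) & (w >= 0) & (v + w <= 1)
    closest = a + np.outer(v, ab) + np.outer(w, ac)
    d_plane = np.linalg.norm(p - closest, axis=1)
    # outside the triangle the nearest point lies on an edge
    d_edges = np.minimum.reduce([
        _pt_segment(p, a, ab),
        _pt_segment(p, a, ac),
        _pt_segment(p, a + ab, ac - ab),
    ])
    return np.where(inside, d_plane, d_edges)


def _pt_segment(p: np.ndarray, a: np.ndarray, d: np.ndarray) -> np.ndarray:
    t = np.clip((p - a) @ d / (d @ d), 0.0, 1.0)
    closest = a + np.outer(t, d)
    return np.linalg.norm(p - closest, axis=1)


def assign_materials(
    mesh: TetMesh,
    hu: np.ndarray,
    callus_margin_mm: float = DEFAULT_CALLUS_MARGIN_MM,
    degradation: float = DEFAULT_CALLUS_DEGRADATION,
    screw_E: float = DEFAULT_SCREW_E,
    screw_nu: float = DEFAULT_SCREW_NU,
    nu_bone: float = DEFAULT_POISSON_BONE,
    modulus_a: float = DEFAULT_MODULUS_A,
    modulus_b: float = DEFAULT_MODULUS_B,
) -> MaterialField:
    """Per-element material field from HU values, callus band and screws.

    Bone elements map HU -> rho -> E; elements whose centroid lies within
    ``callus_margin_mm`` of the osteotomy surface have E multiplied by
    ``degradation`` (healing callus); screw-set elements get the implant
    material regardless of HU.
    """
    if callus_margin_mm < 0:
        raise ConfigurationError("callus margin must be non-negative")
    if not 0 < degradation <= 1:
        raise ConfigurationError("degradation must lie in (0, 1]")
    hu = np.asarray(hu, dtype=float)
    if hu.shape != (mesh.n_elements,):
        raise ValueError("hu must be one value per element")

    screw_mask = np.zeros(mesh.n_elements, dtype=bool)
    for name, ids in mesh.element_sets.items():
        if name.startswith("screw"):
            screw_mask[np.asarray(ids, dtype=int)] = True

    rho = hu_to_density(hu)
    E = density_to_modulus(rho, a=modulus_a, b=modulus_b)
    nu = np.full(mesh.n_elements, nu_bone)

    callus_mask = np.zeros(mesh.n_elements, dtype=bool)
    if callus_margin_mm > 0:
        tri = mesh.surfaces.get("osteotomy")
        if tri is None or len(tri) == 0:
            raise ConfigurationError("callus margin requested but mesh has no osteotomy surface")
        dist = _point_triangle_distances(mesh.element_centroids(), mesh.nodes[np.asarray(tri, dtype=int)])
        callus_mask = (dist <= callus_margin_mm) & ~screw_mask
        E = np.where(callus_mask, E * degradation, E)

    E = np.where(screw_mask, screw_E, E)
    nu = np.where(screw_mask, screw_nu, nu)
    rho = np.where(screw_mask, 0.0, rho)
    return MaterialField(E=E, nu=nu, rho=rho, screw_mask=screw_mask, callus_mask=callus_mask)


# ---------------------------------------------------------------------------
# Load cases
# ---------------------------------------------------------------------------

@dataclass
class LoadCase:
    """Nodal loads + fixed boundary for one gait phase."""

    phase_id: int                    # 1-8
    nodal_forces: np.ndarray         # (n_nodes, 3) N
    fixed_nodes: np.ndarray          # node indices with all DOF fixed
    frame: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def scaled(self, factor: float) -> "LoadCase":
        return LoadCase(
            phase_id=self.phase_id,
            nodal_forces=self.nodal_forces * factor,
            fixed_nodes=self.fixed_nodes,
            frame=self.frame,
            meta={**self.meta, "scale": factor},
        )


#: Pelvis reference frame used for all load cases: origin at the midpoint of
#: the posterior superior iliac spines, XY the vertical plane through the
#: pubic-symphysis midpoint, XZ parallel to the ground.
DEFAULT_PELVIS_FRAME = {
    "origin": "PSIS midpoint",
    "xy_plane": "through pubic symphysis midpoint, perpendicular to ground",
    "xz_plane": "parallel to ground",
    "axes": {"x": "anterior", "y": "vertical up", "z": "lateral"},
}


def distribute_force(
    region_nodes: np.ndarray,
    node_coords: np.ndarray,
    force: np.ndarray,
    moment: np.ndarray | None = None,
) -> np.ndarray:
    """Nodal forces over a region, statically equivalent to (force, moment).

    The force is shared equally, which makes the net moment about the region
    node-centroid zero; a minimum-norm couple distribution (least squares on
    the cross-product system) adds any requested moment.
    """
    region_nodes = np.asarray(region_nodes, dtype=int)
    if region_nodes.size == 0:
        raise MappingError("cannot distribute a force over an empty region")
    coords = node_coords[region_nodes]
    nf = np.tile(np.asarray(force, dtype=float) / region_nodes.size, (region_nodes.size, 1))
    if moment is not None and np.any(np.asarray(moment) != 0):
        rel = coords - coords.mean(axis=0)
        n = region_nodes.size
        A = np.zeros((6, 3 * n))
        for i in range(n):
            A[:3, 3 * i:3 * i + 3] = _skew(rel[i])
            A[3:, 3 * i:3 * i + 3] = np.eye(3)
        rhs = np.concatenate([np.asarray(moment, dtype=float), np.zeros(3)])
        g, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        nf += g.reshape(n, 3)
    return nf


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0.0]])


def build_load_case(
    mesh: TetMesh,
    phase_id: int,
    region_forces: dict,
    fixed_set: str = "fixed",
    frame: dict | None = None,
) -> LoadCase:
    """Assemble a phase load case from {region name: force vector [N]} (or
    (force, moment) tuples), distributing each over its coupling region with
    exact static equivalence."""
    if fixed_set not in mesh.node_sets or len(mesh.node_sets[fixed_set]) == 0:
        raise ConfigurationError(f"mesh lacks a non-empty fixed node set '{fixed_set}'")
    nodal = np.zeros((mesh.n_nodes, 3))
    for region, load in region_forces.items():
        if region not in mesh.node_sets:
            raise MappingError(f"no coupling region named '{region}' in mesh")
        nodes = np.asarray(mesh.node_sets[region], dtype=int)
        if nodes.size == 0:
            raise MappingError(f"coupling region '{region}' is empty")
        if isinstance(load, tuple):
            force, moment = load
        else:
            force, moment = load, None
        nodal[nodes] += distribute_force(nodes, mesh.nodes, np.asarray(force, dtype=float), moment)
    return LoadCase(
        phase_id=phase_id,
        nodal_forces=nodal,
        fixed_nodes=np.asarray(mesh.node_sets[fixed_set], dtype=int),
        frame=frame or dict(DEFAULT_PELVIS_FRAME),
    )


# ---------------------------------------------------------------------------
# Linear elasticity solve
# ---------------------------------------------------------------------------

@dataclass
class FieldResult:
    """Solved displacement/strain/stress fields (single-point tet4)."""

    displacements: np.ndarray        # (n_nodes, 3) mm
    stress: np.ndarray               # (n_elem, 6) Voigt xx yy zz xy yz zx, MPa
    strain: np.ndarray               # (n_elem, 6) Voigt (engineering shear)
    von_mises: np.ndarray            # (n_elem,)
    principal_strains: np.ndarray    # (n_elem, 3) sorted descending
    reactions: np.ndarray            # (n_nodes, 3), nonzero on fixed nodes
    meta: dict = field(default_factory=dict)


def _element_B_matrices(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Constant strain-displacement matrices B (n_elem, 6, 12) and volumes."""
    x = mesh.nodes[mesh.elements]          # (ne, 4, 3)
    d = (x[:, 1:] - x[:, :1]).transpose(0, 2, 1)   # (ne, 3, 3) columns = edge vectors
    detJ = np.linalg.det(d)
    vol = np.abs(detJ) / 6.0
    dinv = np.linalg.inv(d)
    # rows of dinv^T ... gradients of N1..N3 wrt x; N0 closes partition of unity
    grads = np.empty((len(x), 4, 3))
    grads[:, 1:, :] = dinv
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    B = np.zeros((len(x), 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B, vol


def _elastic_D(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Isotropic elasticity matrices (n_elem, 6, 6), engineering shear."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((E.size, 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
    for i in range(3, 6):
        D[:, i, i] = mu
    return D


class FEModel:
    """Assembled stiffness for one mesh + material field, reusable across
    load cases and load scaling (yield iterations re-use the factorization)."""

    def __init__(self, mesh: TetMesh, materials: MaterialField):
        self.mesh = mesh
        self.materials = materials
        self.B, self.volumes = _element_B_matrices(mesh)
        self.D = _elastic_D(materials.E, materials.nu)
        self.K = self._assemble()
        self._factorized: dict = {}

    def _assemble(self) -> sp.csr_matrix:
        ne = self.mesh.n_elements
        Ke = np.einsum("eji,ejk,ekl,e->eil", self.B, self.D, self.B, self.volumes)
        dof = (3 * self.mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 12)
        rows = np.repeat(dof, 12, axis=1).ravel()
        cols = np.tile(dof, (1, 12)).ravel()
        K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(3 * self.mesh.n_nodes,) * 2)
        return K.tocsr()

    def solve(self, loadcase: LoadCase) -> FieldResult:
        return solve_linear_elasticity(self.mesh, self.materials, loadcase, model=self)


def solve_linear_elasticity(
    mesh: TetMesh,
    materials: MaterialField,
    loadcase: LoadCase,
    model: FEModel | None = None,
) -> FieldResult:
    """Assemble (or reuse) the tet4 stiffness, solve K u = F with the fixed
    DOF eliminated, and recover centroid stresses, strains and reactions."""
    if model is None:
        model = FEModel(mesh, materials)
    K = model.K
    ndof = 3 * mesh.n_nodes
    fixed = np.asarray(loadcase.fixed_nodes, dtype=int)
    if fixed.size == 0:
        raise SolverError("fixed node set is empty: rigid-body modes are unconstrained")
    fixed_dof = (3 * fixed[:, None] + np.arange(3)).ravel()
    free = np.setdiff1d(np.arange(ndof), fixed_dof)
    F = loadcase.nodal_forces.ravel()

    key = (fixed.tobytes(),)
    if key not in model._factorized:
        Kff = K[np.ix_(free, free)].tocsc()
        try:
            model._factorized[key] = (free, spla.factorized(Kff))
        except RuntimeError as exc:  # singular
            raise SolverError(f"singular reduced stiffness: {exc}") from exc
    free_idx, solve_ff = model._factorized[key]
    u = np.zeros(ndof)
    u[free_idx] = solve_ff(F[free_idx])
    if not np.all(np.isfinite(u)):
        raise SolverError("solver produced non-finite displacements (insufficient constraints?)")

    resid = np.linalg.norm((K @ u - F)[free_idx])
    ref = max(np.linalg.norm(F[free_idx]), 1e-30)
    reactions = (K @ u - F).reshape(-1, 3)
    keep = np.zeros(mesh.n_nodes, dtype=bool)
    keep[fixed] = True
    reactions[~keep] = 0.0

    ue = u.reshape(-1, 3)[mesh.elements].reshape(mesh.n_elements, 12)
    strain = np.einsum("eij,ej->ei", model.B, ue)
    stress = np.einsum("eij,ej->ei", model.D, strain)
    return FieldResult(
        displacements=u.reshape(-1, 3),
        stress=stress,
        strain=strain,
        von_mises=von_mises_stress(stress),
        principal_strains=principal_strains(strain),
        reactions=reactions,
        meta={"relative_residual": float(resid / ref), "phase_id": loadcase.phase_id},
    )


def von_mises_stress(stress_voigt: np.ndarray) -> np.ndarray:
    """sqrt(1/2 [(s1-s2)^2 + (s2-s3)^2 + (s3-s1)^2 + 6(t12^2+t23^2+t31^2)])."""
    s = np.atleast_2d(stress_voigt)
    sx, sy, sz, txy, tyz, tzx = s.T
    vm = np.sqrt(0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
                 + 3.0 * (txy**2 + tyz**2 + tzx**2))
    return vm if np.asarray(stress_voigt).ndim == 2 else float(vm[0])


def principal_strains(strain_voigt: np.ndarray) -> np.ndarray:
    """Eigenvalues of the strain tensor, sorted descending per element.

    Input uses engineering shear components (gamma = 2*eps)."""
    s = np.atleast_2d(strain_voigt)
    n = s.shape[0]
    T = np.zeros((n, 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = s[:, 0], s[:, 1], s[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = s[:, 3] / 2
    T[:, 1, 2] = T[:, 2, 1] = s[:, 4] / 2
    T[:, 0, 2] = T[:, 2, 0] = s[:, 5] / 2
    vals = np.linalg.eigvalsh(T)[:, ::-1]
    return vals if np.asarray(strain_voigt).ndim == 2 else vals[0]


def field_metrics(result: FieldResult) -> dict:
    """Integration-point von Mises stress and sorted principal strains."""
    return {
        "von_mises_MPa": result.von_mises,
        "principal_strains": result.principal_strains,
    }
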