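"""Shared fixtures: structured bar meshes, uniform materials, cached IDA."""

from __future__ import annotations

import numpy as np
import pytest

from paofix import fe_solver as fe
from paofix import gait_processing as gp
from paofix import msk_model as mm
from paofix import synthetic_data as sd

KUHN_CORNERS = [(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1),
                (1, 0, 0), (1, 0, 1), (1, 1, 0), (1, 1, 1)]
KUHN_TETS = [(0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7),
             (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7)]


def box_mesh(lengths=(10.0, 2.0, 2.0), divisions=(10, 2, 2)) -> fe.TetMesh:
    """Structured tet4 box used for bar / patch verification problems."""
    nx, ny, nz = divisions
    axes = [np.linspace(0, lengths[i], divisions[i] + 1) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                ids = [nid(i + c[0], j + c[1], k + c[2]) for c in KUHN_CORNERS]
                for t in KUHN_TETS:
                    tets.append([ids[a] for a in t])
    return fe.TetMesh(nodes=nodes, elements=np.asarray(tets, dtype=int))


def uniform_materials(mesh: fe.TetMesh, E=1000.0, nu=0.3) -> fe.MaterialField:
    n = mesh.n_elements
    return fe.MaterialField(
        E=np.full(n, float(E)), nu=np.full(n, float(nu)), rho=np.zeros(n),
        screw_mask=np.zeros(n, dtype=bool), callus_mask=np.zeros(n, dtype=bool),
    )


@pytest.fixture(scope="session")
def bar():
    """10 x 2 x 2 mm uniform bar with fixed/tip node sets (E = 1000 MPa)."""
    mesh = box_mesh()
    mesh.node_sets = {
        "fixed": np.where(np.isclose(mesh.nodes[:, 0], 0.0))[0],
        "tip": np.where(np.isclose(mesh.nodes[:, 0], 10.0))[0],
    }
    return mesh, uniform_materials(mesh)


@pytest.fixture(scope="session")
def healthy_noiseless_ida():
    """Full gait -> IDA chain for the noiseless healthy profile (cached)."""
    profile = sd.profile_for_group("healthy", seed=1, noise_sd=0.0)
    trial = sd.generate_gait_trial(profile)
    curves = gp.normalize_to_cycle(trial)
    return trial, curves, mm.run_ida(curves)


@pytest.fixture(scope="session")
def postop_aggregates():
    """Phase aggregates of a typical noiseless postoperative subject."""
    profile = sd.profile_for_group("postop", seed=0, noise_sd=0.0)
    trial = sd.generate_gait_trial(profile)
    curves = gp.normalize_to_cycle(trial)
    ida = mm.run_ida(curves)
    return ida.phase_aggregates


@pytest.fixture(scope="session")
def small_pelvis_mesh():
    spec = sd.SyntheticGeometrySpec(fixation="IS", target_edge_size_mm=5.0)
    return sd.generate_pelvis_mesh(spec)
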