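"""Shared fixtures: small meshes, forward operators and a phantom
simulation reused across the suite (session-scoped; the FEM solves are
the expensive part)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from myosim import anatomy as A
from myosim import forward as F
from myosim import mesh as M
from myosim.analytic import ValidationConfig
from myosim.pipeline import Simulation
from myosim.sources import SourceParams


@pytest.fixture(scope="session")
def small_cylinder():
    """Small homogeneous cylinder with assembled stiffness and four
    surface point electrodes (at exact boundary vertices)."""
    spec = M.CylinderPhantomSpec(radii=(0.03,), length=0.12, edge_length=0.006)
    mesh = M.build_cylinder_phantom(spec)
    mesh = M.assign_conductivity(
        mesh, M.ConductivityModel({M.muscle_region(0): M.IsotropicConductivity(0.5)})
    )
    a = F.assemble_stiffness(mesh)
    bverts = mesh.boundary_vertices()
    # boundary vertices on the lateral surface, spread in angle and z
    pos = mesh.vertices[bverts]
    lateral = bverts[np.hypot(pos[:, 0], pos[:, 1]) > 0.029]
    pick = lateral[:: max(1, len(lateral) // 4)][:4]
    electrodes = [F.PointElectrode(tuple(mesh.vertices[v])) for v in pick]
    es = F.build_selection(mesh, electrodes)
    k = F.solve_adjoint(a, es)
    v_basis, verts = F.basis_solutions(k, mesh)
    op = F.ForwardOperator(mesh, es, k, v_basis, verts)
    return {
        "mesh": mesh,
        "A": a,
        "es": es,
        "K": k,
        "op": op,
        "electrode_vertices": pick,
    }


@pytest.fixture(scope="session")
def phantom_op():
    """Coarse four-layer phantom with the 16-electrode validation array."""
    cfg = ValidationConfig()
    mesh = cfg.conductivity_model().assign(cfg.phantom_mesh("coarse"))
    op = F.compute_forward_operator(
        mesh, [F.PointElectrode(tuple(p)) for p in cfg.electrode_positions()]
    )
    return cfg, op


@pytest.fixture(scope="session")
def phantom_sim(phantom_op):
    """Simulation over the coarse phantom with a small multi-MU pool."""
    cfg, op = phantom_op
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pop = A.UnitCirclePopulation.generate(
            n_fibres=3000, n_mu=50, size_min=5, size_max=300, rng_seed=11
        )
        geom = A.MuscleGeometry(
            section=A.AnnularSectorSection(0.0095, 0.0185, -0.6, 0.6),
            length=0.14,
            origin=(0.0, 0.0, -0.07),
        )
        pool = A.morph_to_muscle(pop, geom, rng_seed=11)
    sim = Simulation(op, SourceParams())
    sim.set_pool(pool)
    sim.muaps()  # warm the template cache once for the whole session
    return sim


def homogeneous_transfer(electrodes: np.ndarray, points: np.ndarray, sigma: float):
    """Free-space transfer matrix (n_e, n_z): 1/(4 pi sigma d)."""
    d = np.linalg.norm(
        np.asarray(electrodes)[:, None, :] - np.asarray(points)[None, :, :], axis=2
    )
    return 1.0 / (4.0 * np.pi * sigma * d)
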