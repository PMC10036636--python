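"""FEM assembly, electrode selection, adjoint lead fields, point location."""

import numpy as np
import pytest

from myosim import forward as F
from myosim import mesh as M


def _element_stiffness_oracle(coords, sigma):
    """Brute-force P1 element matrix: constant gradients from the affine
    map, one-point quadrature (exact for P1)."""
    v0 = coords[0]
    e = (coords[1:] - v0).T  # 3x3
    vol = abs(np.linalg.det(e)) / 6.0
    grads = np.zeros((4, 3))
    inv = np.linalg.inv(e)
    grads[1:] = inv  # rows are gradients of lambda_1..3
    grads[0] = -grads[1:].sum(axis=0)
    ke = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            ke[i, j] = vol * grads[i] @ sigma @ grads[j]
    return ke


class TestAssembly:
    def test_single_regular_tet_has_zero_row_sums(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        mesh = M.VolumeMesh(verts, np.array([[0, 1, 2, 3]]), np.array([M.muscle_region(0)]))
        mesh = M.assign_conductivity(mesh, M.ConductivityModel({M.muscle_region(0): 1.0}))
        a = F.assemble_stiffness(mesh).toarray()
        assert np.allclose(a.sum(axis=1), 0.0, atol=1e-14)
        assert np.allclose(a, a.T)

    def test_assembly_matches_per_element_oracle(self):
        rng = np.random.default_rng(7)
        spec = M.CylinderPhantomSpec(radii=(0.01,), length=0.01, edge_length=0.006)
        mesh = M.build_cylinder_phantom(spec)
        aniso = M.AnisotropicConductivity(0.4, 0.1, direction=(0.6, 0.0, 0.8))
        mesh = M.assign_conductivity(mesh, M.ConductivityModel({M.muscle_region(0): aniso}))
        a = F.assemble_stiffness(mesh).toarray()
        ref = np.zeros_like(a)
        for t in range(mesh.n_tets):
            ke = _element_stiffness_oracle(
                mesh.vertices[mesh.tets[t]], mesh.conductivity[t]
            )
            for i in range(4):
                for j in range(4):
                    ref[mesh.tets[t, i], mesh.tets[t, j]] += ke[i, j]
        assert np.abs(a - ref).max() < 1e-12

    def test_stiffness_exactly_symmetric_and_null_space(self, small_cylinder):
        a = small_cylinder["A"]
        assert abs(a - a.T).max() == 0.0
        ones = np.ones(a.shape[0])
        assert np.abs(a @ ones).max() < 1e-10 * np.abs(a.diagonal()).max()


class TestSelection:
    def test_electrode_at_vertex_gives_unit_row(self, small_cylinder):
        es = small_cylinder["es"]
        s = es.selection.toarray()
        for row, v in zip(s, small_cylinder["electrode_vertices"]):
            assert row[v] == pytest.approx(1.0)
            assert row.sum() == pytest.approx(1.0)

    def test_electrode_at_face_centroid_gets_barycentric_thirds(self, small_cylinder):
        mesh = small_cylinder["mesh"]
        faces = mesh.boundary_faces()
        tri = mesh.vertices[faces]
        # a lateral face (not on an end cap)
        fi = int(np.argmax(np.ptp(tri[:, :, 2], axis=1)))
        centroid = tri[fi].mean(axis=0)
        es = F.build_selection(mesh, [F.PointElectrode(tuple(centroid))])
        row = es.selection.toarray()[0]
        nz = np.flatnonzero(row)
        assert sorted(nz) == sorted(faces[fi])
        assert np.allclose(row[nz], 1.0 / 3.0, atol=1e-6)

    def test_patch_weights_sum_to_one_with_local_support(self, small_cylinder):
        mesh = small_cylinder["mesh"]
        centre = mesh.vertices[small_cylinder["electrode_vertices"][0]]
        es = F.build_selection(mesh, [F.PatchElectrode(tuple(centre), radius=0.008)])
        row = es.selection.toarray()[0]
        assert row.sum() == pytest.approx(1.0)
        nz = np.flatnonzero(row)
        assert np.all(np.linalg.norm(mesh.vertices[nz] - centre, axis=1) <= 0.008)

    def test_far_electrode_rejected_with_distance(self, small_cylinder):
        mesh = small_cylinder["mesh"]
        with pytest.raises(ValueError, match="mm from the boundary"):
            F.build_selection(mesh, [F.PointElectrode((0.06, 0.0, 0.0))])


class TestAdjoint:
    def test_one_solve_per_electrode(self, small_cylinder):
        before = F.solve_counter.count
        F.solve_adjoint(small_cylinder["A"], small_cylinder["es"])
        assert F.solve_counter.count - before == small_cylinder["es"].n_electrodes

    def test_adjoint_equals_per_source_direct_solves(self, small_cylinder):
        """V_basis from the adjoint lead field must match brute-force
        per-source solves S A^+ b(vertex), column by column."""
        mesh, a, es, k = (
            small_cylinder["mesh"],
            small_cylinder["A"],
            small_cylinder["es"],
            small_cylinder["K"],
        )
        lu = F._pinned_factor(a)
        rng = np.random.default_rng(3)
        for v in rng.choice(mesh.n_vertices, 12, replace=False):
            b = np.zeros(mesh.n_vertices)
            b[v] = 1.0
            b -= b.mean()
            b[0] = 0.0
            x = lu.solve(b)
            x -= x.mean()
            direct = es.selection @ x
            assert np.abs(direct - k[:, v]).max() < 1e-7 * max(np.abs(direct).max(), 1)

    def test_reciprocity_between_vertex_electrodes(self, small_cylinder):
        k = small_cylinder["K"]
        vi, vj = small_cylinder["electrode_vertices"][:2]
        assert k[0, vj] == pytest.approx(k[1, vi], abs=1e-7 * abs(k[0, vj]) + 1e-12)

    def test_solutions_are_zero_mean(self, small_cylinder):
        assert np.abs(small_cylinder["K"].mean(axis=1)).max() < 1e-12

    def test_basis_restriction_selects_muscle_columns(self, small_cylinder):
        mesh, k = small_cylinder["mesh"], small_cylinder["K"]
        v_basis, verts = F.basis_solutions(k, mesh)
        assert v_basis.shape == (k.shape[0], len(verts))
        assert np.array_equal(v_basis[:, 10], k[:, verts[10]])
        # all-regions restriction recovers the full lead field
        v_all, verts_all = F.basis_solutions(k, mesh, source_region=M.muscle_region(0))
        assert len(verts_all) == mesh.n_vertices  # single-region mesh

    def test_empty_source_region_rejected(self, small_cylinder):
        with pytest.raises(ValueError, match="no tetrahedra"):
            F.basis_solutions(
                small_cylinder["K"], small_cylinder["mesh"], source_region=M.BONE
            )


class TestPointLocation:
    def test_vertex_maps_to_basis_vector(self, small_cylinder):
        mesh = small_cylinder["mesh"]
        v = mesh.tets[5, 2]
        loc = F.locate_point(mesh, mesh.vertices[v])
        corner = np.where(mesh.tets[loc.tet] == v)[0]
        assert corner.size == 1
        expected = np.zeros(4)
        expected[corner[0]] = 1.0
        assert np.allclose(loc.lam, expected, atol=1e-9)

    def test_centroid_maps_to_quarter_weights(self, small_cylinder):
        mesh = small_cylinder["mesh"]
        centroid = mesh.vertices[mesh.tets[17]].mean(axis=0)
        loc = F.locate_point(mesh, centroid)
        assert np.allclose(loc.lam, 0.25, atol=1e-9)

    def test_random_interior_points_reconstruct_exactly(self, small_cylinder):
        mesh = small_cylinder["mesh"]
        rng = np.random.default_rng(5)
        r = 0.025 * np.sqrt(rng.uniform(size=100))
        th = rng.uniform(0, 2 * np.pi, 100)
        z = rng.uniform(-0.055, 0.055, 100)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), z])
        tets, lams = F.locate_batch(mesh, pts)
        rebuilt = np.einsum("na,nad->nd", lams, mesh.vertices[mesh.tets[tets]])
        assert np.abs(rebuilt - pts).max() < 1e-12

    def test_point_outside_mesh_rejected(self, small_cylinder):
        with pytest.raises(ValueError, match="outside"):
            F.locate_point(small_cylinder["mesh"], np.array([0.1, 0.0, 0.0]))

    def test_point_potential_at_basis_vertex_returns_column(self, small_cylinder):
        mesh, op = small_cylinder["mesh"], small_cylinder["op"]
        v = mesh.tets[40, 0]
        loc = F.locate_point(mesh, mesh.vertices[v])
        phi = F.point_potential(op.v_basis, op.basis_vertices, mesh, loc)
        col = np.searchsorted(op.basis_vertices, v)
        assert np.allclose(phi, op.v_basis[:, col])

    def test_interior_point_potential_matches_fresh_direct_solve(self, small_cylinder):
        """Barycentric interpolation of basis solutions equals a direct
        solve with the barycentric right-hand side."""
        mesh, a, es, op = (
            small_cylinder["mesh"],
            small_cylinder["A"],
            small_cylinder["es"],
            small_cylinder["op"],
        )
        lu = F._pinned_factor(a)
        rng = np.random.default_rng(9)
        r = 0.02 * np.sqrt(rng.uniform(size=5))
        th = rng.uniform(0, 2 * np.pi, 5)
        z = rng.uniform(-0.04, 0.04, 5)
        for p in np.column_stack([r * np.cos(th), r * np.sin(th), z]):
            loc = F.locate_point(mesh, p)
            interp = F.point_potential(op.v_basis, op.basis_vertices, mesh, loc)
            b = np.zeros(mesh.n_vertices)
            b[mesh.tets[loc.tet]] = loc.lam
            b -= b.mean()
            b[0] = 0.0
            x = lu.solve(b)
            x -= x.mean()
            direct = es.selection @ x
            assert np.abs(interp - direct).max() < 1e-7 * max(np.abs(direct).max(), 1e-12)

    def test_gauge_shift_leaves_differential_signals_unchanged(self, small_cylinder):
        op = small_cylinder["op"]
        rng = np.random.default_rng(1)
        pts = np.array([[0.005, 0.002, 0.01], [0.003, -0.004, -0.02]])
        base = op.potentials_at(pts)
        shifted = F.ForwardOperator(
            op.mesh,
            op.electrode_set,
            op.k,
            op.v_basis + rng.normal(),  # constant added to every basis column
            op.basis_vertices,
        )
        pert = shifted.potentials_at(pts)
        assert np.allclose(np.diff(base, axis=0), np.diff(pert, axis=0), atol=1e-12)


class TestHomogeneousLimit:
    def test_point_source_matches_free_space_closed_form(self):
        """Potential differences around a deep point source follow
        1/(4 pi sigma d) within 5% on a locally refined mesh."""
        R, L = 0.04, 0.16
        radial = tuple(
            np.concatenate([np.arange(0.001, 0.0121, 0.001), [0.016, 0.021, 0.027, 0.033, 0.04]])
        )
        fine = np.arange(0.0, 0.0301, 0.0012)
        tail = np.linspace(0.03, 0.08, 8)[1:]
        zpos = np.concatenate([fine, tail])
        zfull = np.unique(np.concatenate([0.08 - zpos[::-1], 0.08 + zpos]))
        spec = M.CylinderPhantomSpec(
            radii=(R,),
            length=L,
            edge_length=0.003,
            radial_positions=radial,
            axial_positions=tuple(zfull),
            n_theta=int(2 * np.pi * R / 0.003),
        )
        mesh = M.build_cylinder_phantom(spec)
        mesh = M.assign_conductivity(mesh, M.ConductivityModel({M.muscle_region(0): 0.5}))
        a = F.assemble_stiffness(mesh)
        lu = F._pinned_factor(a)
        src = np.array([0.0, 0.0, -0.012])
        loc = F.locate_point(mesh, src)
        b = np.zeros(mesh.n_vertices)
        b[mesh.tets[loc.tet]] = loc.lam
        b -= b.mean()
        b[0] = 0.0
        x = lu.solve(b)
        dists = (0.009, 0.012, 0.018)
        fem, ana = [], []
        for d in dists:
            pl = F.locate_point(mesh, src + np.array([0.0, 0.0, d]))
            fem.append(x[mesh.tets[pl.tet]] @ pl.lam)
            ana.append(1.0 / (4 * np.pi * 0.5 * d))
        for i in range(len(dists)):
            for j in range(i + 1, len(dists)):
                ratio = (fem[i] - fem[j]) / (ana[i] - ana[j])
                assert ratio == pytest.approx(1.0, abs=0.05)
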