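"""FEM forward solver and adjoint lead fields for the volume conductor.

The quasi-static Poisson problem ``div(sigma grad phi) = -I`` with
homogeneous Neumann boundary conditions is discretized with P1 (piecewise
linear) Galerkin elements on the tetrahedral mesh, giving the sparse
symmetric stiffness system ``A v = b``.  ``A`` has the constant vector in
its null space; uniqueness is restored by the zero-sum (zero-mean) gauge.

Instead of solving one system per candidate source, the adjoint method is
used: with the electrode selection matrix ``S`` (one row per electrode),
the lead field ``K = S A^+`` is obtained from ``A K^T = S^T``, i.e. one
linear solve per *electrode*.  Potentials of a unit point source at any
interior location then follow by barycentric interpolation of the basis
solutions ``V_basis = K B`` (columns restricted to source-region
vertices).  Electrode rows of ``S^T`` are mean-centred before solving so
the singular system is consistent; monopolar lead fields are therefore
average-referenced, which is immaterial for differential montages.

The default linear solver is a sparse direct factorization of the
gauge-pinned system, shared across all electrode right-hand sides; a
Jacobi/ILU-preconditioned conjugate-gradient solver is available as an
option for larger meshes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .mesh import VolumeMesh

__all__ = [
    "assemble_stiffness",
    "PointElectrode",
    "PatchElectrode",
    "ElectrodeSet",
    "build_selection",
    "solve_adjoint",
    "basis_solutions",
    "BarycentricLocation",
    "locate_point",
    "locate_points",
    "point_potential",
    "ForwardOperator",
    "compute_forward_operator",
    "SolveCounter",
    "solve_counter",
]


class SolveCounter:
    """Counts linear-system solves, used to assert the staged-reuse
    contract (changing fibre/MU/drive parameters must trigger no new
    forward solves)."""

    def __init__(self) -> None:
        self.count = 0

    def add(self, n: int = 1) -> None:
        self.count += int(n)


#: Module-level counter incremented by every adjoint/direct solve.
solve_counter = SolveCounter()


# --- stiffness assembly ------------------------------------------------------


def _p1_gradients(mesh: VolumeMesh):
    """Constant P1 basis gradients per tet: (n_t, 4, 3), plus volumes."""
    coords = mesh.tet_coords()
    e = coords[:, 1:] - coords[:, :1]  # (n_t, 3, 3) edge matrix
    det = np.linalg.det(e)
    vol = det / 6.0
    inv = np.linalg.inv(e)  # rows of inv.T are grads of lambda_1..3
    g = np.empty((mesh.n_tets, 4, 3))
    g[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    return g, vol


def assemble_stiffness(mesh: VolumeMesh) -> sp.csr_matrix:
    """Assemble the P1 stiffness matrix A_ij = int sigma grad wi . grad wj.

    The mesh must carry per-tet conductivity tensors.  The result is
    exactly symmetric; constants lie in its null space (zero row sums) up
    to round-off.
    """
    if mesh.conductivity is None:
        raise ValueError("mesh has no conductivity tensors; call assign_conductivity first")
    g, vol = _p1_gradients(mesh)
    if np.any(vol <= 0):
        bad = int(np.argmin(vol))
        raise ValueError(f"degenerate tetrahedron {bad} (non-positive volume)")
    sg = np.einsum("tab,tib->tia", mesh.conductivity, g)
    ke = np.einsum("tia,tja->tij", sg, g) * vol[:, None, None]
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    a = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(mesh.n_vertices,) * 2).tocsr()
    return (a + a.T) * 0.5


# --- electrodes and selection matrix ----------------------------------------


@dataclass(frozen=True)
class PointElectrode:
    """Point electrode at a 3-D position on (or near) the outer surface."""

    position: tuple
    label: str = ""


@dataclass(frozen=True)
class PatchElectrode:
    """Circular patch electrode: potentials averaged (area-lumped) over
    boundary vertices within ``radius`` of ``centre``."""

    centre: tuple
    radius: float
    label: str = ""


@dataclass
class ElectrodeSet:
    electrodes: list
    selection: sp.csr_matrix  # (n_e, n_v), rows non-negative, summing to 1

    @property
    def n_electrodes(self) -> int:
        return self.selection.shape[0]


def _boundary_geometry(mesh: VolumeMesh):
    faces = mesh.boundary_faces()
    tri = mesh.vertices[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    return faces, tri, areas


def build_selection(
    mesh: VolumeMesh, electrodes, snap_tol: float = 1e-3
) -> ElectrodeSet:
    """Build the selection matrix S mapping vertex potentials to electrodes.

    Point electrodes snap to the nearest boundary face (within
    ``snap_tol`` metres, default 1 mm): a unit row if at a vertex,
    otherwise barycentric weights over the face.  Patch electrodes
    average over covered boundary vertices with area-lumped weights.
    """
    faces, tri, areas = _boundary_geometry(mesh)
    bverts = np.unique(faces)
    # lumped vertex areas (1/3 of each incident boundary face)
    vert_area = np.zeros(mesh.n_vertices)
    np.add.at(vert_area, faces.ravel(), np.repeat(areas / 3.0, 3))
    face_centroids = tri.mean(axis=1)
    tree = cKDTree(face_centroids)

    rows, cols, vals = [], [], []
    for k, el in enumerate(electrodes):
        if isinstance(el, PatchElectrode):
            centre = np.asarray(el.centre, dtype=float)
            close = bverts[
                np.linalg.norm(mesh.vertices[bverts] - centre, axis=1) <= el.radius
            ]
            if close.size == 0:
                raise ValueError(
                    f"patch electrode {k} at {centre} covers no boundary vertices"
                )
            w = vert_area[close]
            w = w / w.sum()
            rows.extend([k] * len(close))
            cols.extend(close.tolist())
            vals.extend(w.tolist())
            continue
        pos = np.asarray(el.position, dtype=float)
        # candidate faces by centroid distance
        _, cand = tree.query(pos, k=min(24, len(faces)))
        cand = np.atleast_1d(cand)
        best = None
        for fi in cand:
            a, b, c = tri[fi]
            # project onto the face plane, barycentric coordinates
            n = np.cross(b - a, c - a)
            nn = n / np.linalg.norm(n)
            d = np.dot(pos - a, nn)
            p = pos - d * nn
            t = np.column_stack([b - a, c - a])
            try:
                uv, *_ = np.linalg.lstsq(t, p - a, rcond=None)
            except np.linalg.LinAlgError:
                continue
            lam = np.array([1.0 - uv.sum(), uv[0], uv[1]])
            # distance to the triangle (clip barycentrics)
            lam_c = np.clip(lam, 0.0, None)
            lam_c = lam_c / lam_c.sum()
            closest = lam_c @ tri[fi]
            dist = np.linalg.norm(pos - closest)
            if best is None or dist < best[0]:
                best = (dist, fi, lam_c)
        dist, fi, lam = best
        if dist > snap_tol:
            raise ValueError(
                f"electrode {k} at {pos} is {dist * 1e3:.2f} mm from the boundary "
                f"(snap tolerance {snap_tol * 1e3:.2f} mm)"
            )
        # snap to a vertex when essentially on it
        on_vertex = lam > 1.0 - 1e-9
        if on_vertex.any():
            j = faces[fi][int(np.argmax(lam))]
            rows.append(k)
            cols.append(int(j))
            vals.append(1.0)
        else:
            keep = lam > 1e-12
            w = lam[keep] / lam[keep].sum()
            rows.extend([k] * int(keep.sum()))
            cols.extend(faces[fi][keep].tolist())
            vals.extend(w.tolist())
    s = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(electrodes), mesh.n_vertices)
    )
    return ElectrodeSet(list(electrodes), s)


# --- adjoint solves ----------------------------------------------------------


def _pinned_factor(a: sp.csr_matrix):
    """LU factorization of A with the gauge pinned at vertex 0.

    For a consistent (mean-centred) right-hand side the pinned solution
    solves the full singular system exactly; solutions are re-centred to
    zero mean afterwards."""
    coo = a.tocoo()
    keep = (coo.row != 0) & (coo.col != 0)
    rows = np.concatenate([coo.row[keep], [0]])
    cols = np.concatenate([coo.col[keep], [0]])
    vals = np.concatenate([coo.data[keep], [1.0]])
    ac = sp.csc_matrix((vals, (rows, cols)), shape=a.shape)
    return spla.splu(ac)


def solve_adjoint(
    a: sp.csr_matrix,
    electrode_set: ElectrodeSet,
    tol: float = 1e-8,
    max_iter: int = 5000,
    method: str = "direct",
) -> np.ndarray:
    """Solve A K^T = S^T for the lead-field matrix K (n_e x n_v).

    One linear solve per electrode.  Right-hand sides are mean-centred
    (consistency of the singular Neumann system); each solution is gauged
    to zero mean.  ``method`` is ``"direct"`` (sparse LU, default) or
    ``"cg"`` (Jacobi-preconditioned conjugate gradients with constant-mode
    deflation).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    s = electrode_set.selection
    n_e, n_v = s.shape
    rhs = np.asarray(s.todense(), dtype=float).T  # (n_v, n_e)
    rhs = rhs - rhs.mean(axis=0, keepdims=True)
    k = np.empty((n_e, n_v))
    if method == "direct":
        lu = _pinned_factor(a)
        for j in range(n_e):
            b = rhs[:, j].copy()
            b[0] = 0.0  # pinned dof
            x = lu.solve(b)
            k[j] = x - x.mean()
            solve_counter.add()
    elif method == "cg":
        d = a.diagonal().copy()
        d[d <= 0] = 1.0
        m_inv = spla.LinearOperator(a.shape, matvec=lambda x: x / d)
        for j in range(n_e):
            b = rhs[:, j]
            x, info = spla.cg(a, b, rtol=tol * 1e-2, maxiter=max_iter, M=m_inv)
            x = x - x.mean()
            k[j] = x
            solve_counter.add()
            if info > 0:
                res = np.linalg.norm(a @ x - b) / np.linalg.norm(b)
                if res > tol:
                    raise RuntimeError(
                        f"CG failed to converge for electrode {j}: "
                        f"relative residual {res:.2e} after {max_iter} iterations"
                    )
    else:
        raise ValueError(f"unknown solver method {method!r}")
    # verify residuals
    worst = 0.0
    for j in range(n_e):
        r = np.linalg.norm(a @ k[j] - rhs[:, j]) / np.linalg.norm(rhs[:, j])
        worst = max(worst, r)
    if worst > 10 * tol:
        raise RuntimeError(f"adjoint solve residual {worst:.2e} exceeds tolerance")
    return k


def basis_solutions(k: np.ndarray, mesh: VolumeMesh, source_region=None) -> tuple:
    """Restrict the lead field to basis-source columns (V_basis = K B).

    ``source_region`` is a region code, an iterable of codes, or None for
    all muscle regions.  Returns ``(v_basis, basis_vertices)`` where
    column ``j`` of ``v_basis`` is the electrode response to a unit point
    source at ``basis_vertices[j]`` (ascending vertex order).
    """
    if source_region is None:
        verts = mesh.muscle_vertices()
    else:
        verts = mesh.region_vertices(source_region)
    return k[:, verts], verts


# --- point location and interpolation ---------------------------------------


@dataclass(frozen=True)
class BarycentricLocation:
    tet: int
    lam: np.ndarray  # 4 barycentric coordinates, >= -1e-10, sum 1

    def __post_init__(self) -> None:
        lam = np.asarray(self.lam, dtype=float)
        if lam.shape != (4,):
            raise ValueError("barycentric coordinates must have length 4")
        if lam.min() < -1e-8 or abs(lam.sum() - 1.0) > 1e-8:
            raise ValueError("invalid barycentric coordinates")
        object.__setattr__(self, "lam", lam)


_BARY_TOL = 1e-10


class _TetLocator:
    """KD-tree over tet centroids plus cached barycentric matrices."""

    def __init__(self, mesh: VolumeMesh) -> None:
        self.tree = cKDTree(mesh.centroids())
        coords = mesh.tet_coords()
        e = np.transpose(coords[:, 1:] - coords[:, :1], (0, 2, 1))
        self.inv = np.linalg.inv(e)  # (n_t, 3, 3)
        self.origin = coords[:, 0]  # (n_t, 3)


def _tet_locator(mesh: VolumeMesh) -> _TetLocator:
    if mesh._centroid_tree is None:
        mesh._centroid_tree = _TetLocator(mesh)
    return mesh._centroid_tree


def locate_batch(mesh: VolumeMesh, pts: np.ndarray, k_init: int = 8) -> tuple:
    """Vectorized point location.

    Returns (tets, lams): (n,) int array and (n, 4) barycentric array.
    Points on shared faces resolve to the lowest containing tet index;
    points outside the mesh raise.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    loc = _tet_locator(mesh)
    n = len(pts)
    tets_out = np.full(n, -1, dtype=np.int64)
    lam_out = np.zeros((n, 4))
    pending = np.arange(n)
    k = min(k_init, mesh.n_tets)
    while pending.size:
        for lo in range(0, len(pending), 50_000):
            idx = pending[lo : lo + 50_000]
            _, cand = loc.tree.query(pts[idx], k=k)
            cand = cand.reshape(len(idx), k)
            cand.sort(axis=1)  # lowest containing tet index wins
            rhs = pts[idx][:, None, :] - loc.origin[cand]
            lam123 = np.einsum("mkab,mkb->mka", loc.inv[cand], rhs)
            lam = np.empty((len(idx), k, 4))
            lam[..., 1:] = lam123
            lam[..., 0] = 1.0 - lam123.sum(axis=-1)
            ok = lam.min(axis=-1) >= -_BARY_TOL
            found = ok.any(axis=1)
            first = np.argmax(ok, axis=1)
            rows = np.where(found)[0]
            tets_out[idx[rows]] = cand[rows, first[rows]]
            chosen = np.clip(lam[rows, first[rows]], 0.0, None)
            lam_out[idx[rows]] = chosen / chosen.sum(axis=1, keepdims=True)
        pending = pending[tets_out[pending] < 0]
        if pending.size:
            if k >= mesh.n_tets:
                raise ValueError(f"point {pts[pending[0]]} is outside the mesh")
            k = min(8 * k, mesh.n_tets)
    return tets_out, lam_out


def locate_points(mesh: VolumeMesh, pts: np.ndarray, k_init: int = 8) -> list:
    """Locate points in the mesh; returns a list of BarycentricLocation."""
    tets, lams = locate_batch(mesh, pts, k_init)
    return [BarycentricLocation(int(t), l) for t, l in zip(tets, lams)]


def locate_point(mesh: VolumeMesh, r) -> BarycentricLocation:
    return locate_points(mesh, np.asarray(r, dtype=float)[None, :])[0]


def point_potential(
    v_basis: np.ndarray,
    basis_vertices: np.ndarray,
    mesh: VolumeMesh,
    loc: BarycentricLocation,
) -> np.ndarray:
    """Per-electrode potentials (V per unit source current) of a point
    source at ``loc``, by barycentric combination of basis solutions."""
    verts = mesh.tets[loc.tet]
    cols = np.searchsorted(basis_vertices, verts)
    if (
        cols.max() >= len(basis_vertices)
        or np.any(basis_vertices[np.minimum(cols, len(basis_vertices) - 1)] != verts)
    ):
        raise ValueError(
            f"tet {loc.tet} has vertices outside the basis-source region"
        )
    return v_basis[:, cols] @ loc.lam


# --- bundled operator --------------------------------------------------------


@dataclass
class ForwardOperator:
    """Lead field plus basis solutions for one conductor/electrode layout."""

    mesh: VolumeMesh
    electrode_set: ElectrodeSet
    k: np.ndarray
    v_basis: np.ndarray
    basis_vertices: np.ndarray
    tol: float = 1e-8

    @property
    def n_electrodes(self) -> int:
        return self.k.shape[0]

    def potentials_at(self, pts: np.ndarray) -> np.ndarray:
        """(n_e, n_pts) potentials of unit point sources at ``pts``."""
        tets, lams = locate_batch(self.mesh, pts)
        verts = self.mesh.tets[tets]  # (n, 4)
        cols = np.searchsorted(self.basis_vertices, verts)
        bad = (cols >= len(self.basis_vertices)) | (
            self.basis_vertices[np.minimum(cols, len(self.basis_vertices) - 1)] != verts
        )
        if bad.any():
            j = int(np.where(bad.any(axis=1))[0][0])
            raise ValueError(
                f"point {np.asarray(pts)[j]} lies in a tet outside the "
                "basis-source region"
            )
        out = np.zeros((self.n_electrodes, len(tets)))
        for a in range(4):
            out += self.v_basis[:, cols[:, a]] * lams[None, :, a]
        return out

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("K", data=self.k)
            f.create_dataset("V_basis", data=self.v_basis)
            f.create_dataset("basis_vertices", data=self.basis_vertices)
            f.attrs["gauge"] = "zero-mean (average reference)"
            f.attrs["tol"] = self.tol

    @staticmethod
    def load(path, mesh: VolumeMesh, electrode_set: ElectrodeSet) -> "ForwardOperator":
        import h5py

        with h5py.File(path, "r") as f:
            return ForwardOperator(
                mesh,
                electrode_set,
                f["K"][()],
                f["V_basis"][()],
                f["basis_vertices"][()],
                float(f.attrs.get("tol", 1e-8)),
            )


def compute_forward_operator(
    mesh: VolumeMesh,
    electrodes,
    source_region=None,
    tol: float = 1e-8,
    method: str = "direct",
    snap_tol: float = 1e-3,
) -> ForwardOperator:
    """Assemble, solve the adjoint systems and bundle the forward operator."""
    a = assemble_stiffness(mesh)
    es = build_selection(mesh, electrodes, snap_tol=snap_tol)
    k = solve_adjoint(a, es, tol=tol, method=method)
    v_basis, verts = basis_solutions(k, mesh, source_region)
    return ForwardOperator(mesh, es, k, v_basis, verts, tol)
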