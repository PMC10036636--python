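"""Tetrahedral volume-conductor meshes and tissue conductivities.

The conductor domain (bone, muscle, fat, skin) is discretized as a
tetrahedral mesh with one region label and one symmetric 3x3 conductivity
tensor per tetrahedron.  Muscle tissue is anisotropic: the tensor is
``sigma_t * I + (sigma_l - sigma_t) * d d^T`` with ``d`` the local fibre
direction.  All quantities are SI (metres, S/m).

A multi-layer cylinder phantom (the classical four-layer bone / muscle /
fat / skin geometry used to validate EMG volume-conductor solvers against
the layered-cylinder analytic model) is built directly by a structured
mesher: a graded triangulation of the cross-section disc is extruded along
the axis and each prism is split into three tetrahedra with a globally
consistent diagonal rule, so the mesh is conforming and watertight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "BONE",
    "FAT",
    "SKIN",
    "muscle_region",
    "is_muscle",
    "region_name",
    "VolumeMesh",
    "IsotropicConductivity",
    "AnisotropicConductivity",
    "ConductivityModel",
    "CylinderPhantomSpec",
    "build_cylinder_phantom",
    "load_mesh",
    "save_mesh",
    "DEFAULT_CONDUCTIVITIES",
]

# --- region label vocabulary (closed enumeration, muscle ids >= 0) ----------

BONE = 0
FAT = 1
SKIN = 2
_MUSCLE_BASE = 10


def muscle_region(muscle_id: int = 0) -> int:
    """Region code of muscle ``muscle_id`` (ids are small non-negative ints)."""
    if muscle_id < 0:
        raise ValueError("muscle_id must be non-negative")
    return _MUSCLE_BASE + int(muscle_id)


def is_muscle(region: int | np.ndarray) -> bool | np.ndarray:
    return np.asarray(region) >= _MUSCLE_BASE if isinstance(region, np.ndarray) else region >= _MUSCLE_BASE


def region_name(region: int) -> str:
    if region == BONE:
        return "bone"
    if region == FAT:
        return "fat"
    if region == SKIN:
        return "skin"
    if region >= _MUSCLE_BASE:
        return f"muscle({region - _MUSCLE_BASE})"
    raise ValueError(f"unknown region code {region}")


# --- mesh container ----------------------------------------------------------


@dataclass
class VolumeMesh:
    """Tetrahedral mesh with per-tet region labels and conductivity tensors.

    Parameters
    ----------
    vertices : (n_v, 3) float array, metres.
    tets : (n_t, 4) int array of vertex indices, oriented so the signed
        volume is positive (repaired at construction).
    region : (n_t,) int array of region codes.
    conductivity : (n_t, 3, 3) float array of symmetric tensors in S/m, or
        None until :func:`ConductivityModel.assign` is called.
    """

    vertices: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    conductivity: np.ndarray | None = None
    _centroid_tree: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.region = np.ascontiguousarray(self.region, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n_v, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise ValueError("tets must be (n_t, 4)")
        if self.region.shape != (self.tets.shape[0],):
            raise ValueError("one region label per tet required")
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= len(self.vertices)):
            raise ValueError("tet vertex index out of range")
        self._fix_orientation()

    def _fix_orientation(self) -> None:
        vol = self.signed_volumes()
        flipped = vol < 0
        if np.any(flipped):
            t = self.tets[flipped]
            t[:, [2, 3]] = t[:, [3, 2]]
            self.tets[flipped] = t
        vol = np.abs(vol)
        if self.tets.size and vol.min() <= 0:
            bad = int(np.argmin(vol))
            raise ValueError(f"degenerate tetrahedron {bad} with zero volume")

    # -- geometry ------------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_coords(self) -> np.ndarray:
        """(n_t, 4, 3) coordinates of tet corners."""
        return self.vertices[self.tets]

    def signed_volumes(self) -> np.ndarray:
        c = self.tet_coords()
        e = c[:, 1:] - c[:, :1]
        return np.linalg.det(e) / 6.0

    def volumes(self) -> np.ndarray:
        return np.abs(self.signed_volumes())

    def centroids(self) -> np.ndarray:
        return self.tet_coords().mean(axis=1)

    def boundary_faces(self) -> np.ndarray:
        """(n_f, 3) vertex triples of faces belonging to exactly one tet."""
        faces = self.tets[:, [[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return faces[counts[inv] == 1]

    def boundary_vertices(self) -> np.ndarray:
        return np.unique(self.boundary_faces())

    def region_vertices(self, regions: int | Iterable[int]) -> np.ndarray:
        """Sorted vertex ids incident to any tet of the given region(s)."""
        if isinstance(regions, (int, np.integer)):
            regions = [int(regions)]
        mask = np.isin(self.region, list(regions))
        if not mask.any():
            raise ValueError(f"no tetrahedra in regions {list(regions)}")
        return np.unique(self.tets[mask])

    def muscle_vertices(self, muscle_id: int | None = None) -> np.ndarray:
        if muscle_id is None:
            mask = self.region >= _MUSCLE_BASE
            if not mask.any():
                raise ValueError("mesh has no muscle region")
            return np.unique(self.tets[mask])
        return self.region_vertices(muscle_region(muscle_id))


# --- conductivity ------------------------------------------------------------


@dataclass(frozen=True)
class IsotropicConductivity:
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("conductivity must be strictly positive")


@dataclass(frozen=True)
class AnisotropicConductivity:
    """Longitudinal/transverse pair plus a fibre-direction field.

    ``direction`` is a unit 3-vector or a callable mapping (n, 3) tet
    centroids to (n, 3) unit vectors.
    """

    sigma_l: float
    sigma_t: float
    direction: object = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.sigma_l <= 0 or self.sigma_t <= 0:
            raise ValueError("conductivity must be strictly positive")

    def directions_at(self, centroids: np.ndarray) -> np.ndarray:
        if callable(self.direction):
            d = np.asarray(self.direction(centroids), dtype=float)
        else:
            d = np.broadcast_to(np.asarray(self.direction, dtype=float), centroids.shape).copy()
        norms = np.linalg.norm(d, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("fibre direction vectors must have unit norm (tol 1e-9)")
        return d


@dataclass
class ConductivityModel:
    """Per-region conductivity specification.

    ``regions`` maps region codes to :class:`IsotropicConductivity` or
    :class:`AnisotropicConductivity` (the latter normally for muscle).
    """

    regions: dict

    def assign(self, mesh: VolumeMesh) -> VolumeMesh:
        present = np.unique(mesh.region)
        missing = [region_name(int(r)) for r in present if int(r) not in self.regions]
        if missing:
            raise ValueError(f"no conductivity specified for regions: {', '.join(missing)}")
        tensors = np.zeros((mesh.n_tets, 3, 3))
        centroids = mesh.centroids()
        eye = np.eye(3)
        for code in present:
            sel = mesh.region == code
            model = self.regions[int(code)]
            if isinstance(model, (int, float)):
                model = IsotropicConductivity(float(model))
            if isinstance(model, IsotropicConductivity):
                tensors[sel] = model.sigma * eye
            elif isinstance(model, AnisotropicConductivity):
                d = model.directions_at(centroids[sel])
                tensors[sel] = model.sigma_t * eye + (model.sigma_l - model.sigma_t) * (
                    d[:, :, None] * d[:, None, :]
                )
            else:
                raise TypeError(f"unsupported conductivity spec {model!r}")
        out = replace(mesh, conductivity=tensors)
        out._centroid_tree = mesh._centroid_tree
        return out


def assign_conductivity(mesh: VolumeMesh, model: ConductivityModel) -> VolumeMesh:
    """Return a mesh with per-tet conductivity tensors filled in."""
    return model.assign(mesh)


#: Conventional literature values (S/m); the longitudinal/transverse muscle
#: ratio of 5 is a standard choice.  Configurable everywhere they are used.
DEFAULT_CONDUCTIVITIES = {
    BONE: IsotropicConductivity(0.02),
    FAT: IsotropicConductivity(0.04),
    SKIN: IsotropicConductivity(0.44),
    muscle_region(0): AnisotropicConductivity(sigma_l=0.4, sigma_t=0.08, direction=(0, 0, 1)),
}


# --- cylinder phantom --------------------------------------------------------


@dataclass(frozen=True)
class CylinderPhantomSpec:
    """Multi-layer cylinder phantom.

    ``radii`` are the strictly increasing outer radii of the layers (m);
    ``length`` the cylinder length (m); ``edge_length`` the target edge (m).
    ``labels`` gives one region code per layer; the default four-layer set
    is bone / muscle(0) / fat / skin.

    Optional grading controls (all in SI units; None = derive from
    ``edge_length``):

    - ``radial_positions``: explicit sorted ring radii (must contain every
      layer radius),
    - ``axial_positions``: explicit sorted z samples from 0 to ``length``,
    - ``n_theta``: number of angular nodes on the outermost ring (inner
      rings are proportionally coarser).
    """

    radii: tuple
    length: float = 0.3
    edge_length: float = 0.004
    labels: tuple | None = None
    radial_positions: tuple | None = None
    axial_positions: tuple | None = None
    n_theta: int | None = None

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        object.__setattr__(self, "radii", radii)
        if len(radii) == 0:
            raise ValueError("at least one layer radius required")
        if any(r <= 0 for r in radii) or any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("layer radii must be strictly increasing and positive")
        if self.length <= 0:
            raise ValueError("cylinder length must be positive")
        if self.edge_length <= 0:
            raise ValueError("edge length must be positive")
        labels = self.labels
        if labels is None:
            if len(radii) == 4:
                labels = (BONE, muscle_region(0), FAT, SKIN)
            else:
                labels = tuple(range(_MUSCLE_BASE, _MUSCLE_BASE + len(radii)))
                if len(radii) == 1:
                    labels = (muscle_region(0),)
        if len(labels) != len(radii):
            raise ValueError("one region label per layer required")
        object.__setattr__(self, "labels", tuple(int(c) for c in labels))


def _ring_radii(spec: CylinderPhantomSpec) -> np.ndarray:
    if spec.radial_positions is not None:
        r = np.asarray(sorted(set(float(x) for x in spec.radial_positions)))
        if r[0] <= 0 or r[-1] != spec.radii[-1]:
            raise ValueError("radial_positions must be positive and end at the outer radius")
        for rl in spec.radii:
            if not np.any(np.isclose(r, rl, rtol=0, atol=1e-12)):
                raise ValueError(f"radial_positions must include layer radius {rl}")
        return r
    rings = []
    r_in = 0.0
    for r_out in spec.radii:
        n = max(1, int(np.ceil((r_out - r_in) / spec.edge_length)))
        rings.extend(np.linspace(r_in, r_out, n + 1)[1:])
        r_in = r_out
    return np.asarray(rings)


def _stitch_rings(idx_in, th_in, idx_out, th_out):
    """Triangulate the annulus between two concentric rings.

    Classic two-pointer merge over unwrapped angles; every triangle spans
    the two rings, so layer circles are respected exactly.
    """
    na, nb = len(idx_in), len(idx_out)
    tris = []
    # start both pointers near angle 0; walk CCW once around
    i = j = 0
    ta = np.concatenate([th_in, th_in[:1] + 2 * np.pi])
    tb = np.concatenate([th_out, th_out[:1] + 2 * np.pi])
    while i < na or j < nb:
        adv_inner = j >= nb or (i < na and ta[i + 1] <= tb[j + 1])
        if adv_inner:
            tris.append((idx_in[i % na], idx_out[j % nb], idx_in[(i + 1) % na]))
            i += 1
        else:
            tris.append((idx_in[i % na], idx_out[j % nb], idx_out[(j + 1) % nb]))
            j += 1
    return tris


def _disc_triangulation(spec: CylinderPhantomSpec):
    """Graded structured triangulation of the cross-section disc.

    Concentric rings (including every layer radius) are stitched with a
    deterministic angular merge, so no triangle crosses a layer boundary.
    Returns (points2d, triangles, tri_labels).
    """
    rings = _ring_radii(spec)
    r_max = rings[-1]
    if spec.n_theta is not None:
        n_outer = int(spec.n_theta)
    else:
        n_outer = max(12, int(np.ceil(2 * np.pi * r_max / spec.edge_length)))
    pts = [np.zeros((1, 2))]
    ring_idx, ring_th = [np.array([0])], [np.array([0.0])]
    start = 1
    for k, r in enumerate(rings):
        n = max(6, int(round(n_outer * r / r_max)))
        offset = 0.0 if k % 2 else np.pi / n
        th = (offset + np.arange(n) * (2 * np.pi / n)) % (2 * np.pi)
        order = np.argsort(th)
        th = th[order]
        pts.append(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        ring_idx.append(start + np.arange(n))
        ring_th.append(th)
        start += n
    points = np.vstack(pts)
    radii = np.asarray(spec.radii)
    tris, labels = [], []
    for k in range(len(rings)):
        r_mid = 0.5 * ((rings[k - 1] if k else 0.0) + rings[k])
        layer = int(np.clip(np.searchsorted(radii, r_mid, side="left"), 0, len(radii) - 1))
        code = spec.labels[layer]
        if k == 0:
            # fan from the centre point
            idx, n = ring_idx[1], len(ring_idx[1])
            new = [(0, idx[j], idx[(j + 1) % n]) for j in range(n)]
        else:
            new = _stitch_rings(ring_idx[k], ring_th[k], ring_idx[k + 1], ring_th[k + 1])
        tris.extend(new)
        labels.extend([code] * len(new))
    simplices = np.asarray(tris, dtype=np.int64)
    # enforce CCW orientation in 2-D
    p = points[simplices]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = area2 < 0
    simplices[flip] = simplices[flip][:, [0, 2, 1]]
    return points, simplices, np.asarray(labels)


def _axial_positions(spec: CylinderPhantomSpec) -> np.ndarray:
    if spec.axial_positions is not None:
        z = np.asarray(sorted(set(float(x) for x in spec.axial_positions)))
        if not (np.isclose(z[0], 0.0) and np.isclose(z[-1], spec.length)):
            raise ValueError("axial_positions must span [0, length]")
        return z
    n = max(1, int(np.ceil(spec.length / spec.edge_length)))
    return np.linspace(0.0, spec.length, n + 1)


def _prisms_to_tets(tri: np.ndarray, n2d: int, n_levels: int) -> np.ndarray:
    """Split extruded prisms into tets with a consistent diagonal rule.

    Uses the smallest-global-index rule (rotate so the smallest bottom
    vertex leads, then compare cross-diagonal indices), which is invariant
    under extrusion offsets, so shared quadrilateral faces get matching
    diagonals and the mesh is conforming.
    """
    tri = np.asarray(tri)
    # rotate triangles so the smallest 2-D index is first
    order = np.argmin(tri, axis=1)
    rolled = np.empty_like(tri)
    for k in range(3):
        sel = order == k
        rolled[sel] = np.roll(tri[sel], -k, axis=1)
    i0, i1, i2 = rolled[:, 0], rolled[:, 1], rolled[:, 2]
    # case split from comparing the two candidate diagonals of the far quad
    case_a = np.minimum(i1, i2 + n2d) < np.minimum(i2, i1 + n2d)
    tets_per_level = []
    for lev in range(n_levels - 1):
        b = lev * n2d
        a0, a1, a2 = i0 + b, i1 + b, i2 + b
        b0, b1, b2 = a0 + n2d, a1 + n2d, a2 + n2d
        t = np.empty((len(tri), 3, 4), dtype=np.int64)
        # net effect: every quad face gets the diagonal from its smaller
        # bottom vertex to the larger top vertex, hence conformity
        t[case_a, 0] = np.column_stack([a0, a1, a2, b2])[case_a]
        t[case_a, 1] = np.column_stack([a0, a1, b2, b1])[case_a]
        t[case_a, 2] = np.column_stack([a0, b1, b2, b0])[case_a]
        nc = ~case_a
        t[nc, 0] = np.column_stack([a0, a1, a2, b1])[nc]
        t[nc, 1] = np.column_stack([a0, b1, a2, b2])[nc]
        t[nc, 2] = np.column_stack([a0, b1, b2, b0])[nc]
        tets_per_level.append(t.reshape(-1, 4))
    return np.vstack(tets_per_level)


def build_cylinder_phantom(spec: CylinderPhantomSpec) -> VolumeMesh:
    """Build the multi-layer cylinder phantom mesh.

    The cylinder axis is z, spanning ``[-length/2, +length/2]``; the
    cross-section is centred on the origin.  Every tetrahedron is labelled
    by the layer containing its cross-section centroid.
    """
    points2d, tri, tri_labels = _disc_triangulation(spec)
    z = _axial_positions(spec) - spec.length / 2.0
    n2d, n_lev = len(points2d), len(z)
    verts = np.empty((n2d * n_lev, 3))
    verts[:, :2] = np.tile(points2d, (n_lev, 1))
    verts[:, 2] = np.repeat(z, n2d)
    tets = _prisms_to_tets(tri, n2d, n_lev)
    region = np.tile(np.repeat(tri_labels, 3), n_lev - 1)
    mesh = VolumeMesh(verts, tets, region)
    if mesh.n_tets == 0:
        raise RuntimeError(f"cylinder meshing produced no tetrahedra for spec {spec}")
    return mesh


# --- mesh I/O (Gmsh MSH 2.2 ASCII and legacy VTK ASCII) ----------------------


def _check_orphans(mesh: VolumeMesh, path) -> None:
    used = np.zeros(mesh.n_vertices, dtype=bool)
    used[mesh.tets.ravel()] = True
    n_orphan = int((~used).sum())
    if n_orphan:
        warnings.warn(
            f"{path}: {n_orphan} orphan vertices not referenced by any tetrahedron "
            "(retained)",
            stacklevel=3,
        )


def save_mesh(mesh: VolumeMesh, path, format: str | None = None) -> None:
    """Write a mesh as Gmsh MSH 2.2 ASCII (``msh``) or legacy VTK (``vtk``)."""
    path = str(path)
    fmt = format or ("msh" if path.endswith(".msh") else "vtk")
    if fmt == "msh":
        with open(path, "w") as f:
            f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n$Nodes\n")
            f.write(f"{mesh.n_vertices}\n")
            for i, (x, y, z) in enumerate(mesh.vertices, start=1):
                f.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
            f.write("$EndNodes\n$Elements\n")
            f.write(f"{mesh.n_tets}\n")
            for i, (t, reg) in enumerate(zip(mesh.tets, mesh.region), start=1):
                f.write(f"{i} 4 2 {reg} {reg} {t[0]+1} {t[1]+1} {t[2]+1} {t[3]+1}\n")
            f.write("$EndElements\n")
    elif fmt == "vtk":
        with open(path, "w") as f:
            f.write("# vtk DataFile Version 3.0\nmyosim mesh\nASCII\n")
            f.write("DATASET UNSTRUCTURED_GRID\n")
            f.write(f"POINTS {mesh.n_vertices} double\n")
            for x, y, z in mesh.vertices:
                f.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
            f.write(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
            for t in mesh.tets:
                f.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
            f.write(f"CELL_TYPES {mesh.n_tets}\n")
            f.write("\n".join(["10"] * mesh.n_tets) + "\n")
            f.write(f"CELL_DATA {mesh.n_tets}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
            f.write("\n".join(str(int(r)) for r in mesh.region) + "\n")
    else:
        raise ValueError(f"unknown mesh format {fmt!r} (supported: msh, vtk)")


def _load_msh(path: str) -> VolumeMesh:
    with open(path) as f:
        lines = f.read().split("\n")
    try:
        i_nodes = lines.index("$Nodes")
        i_elems = lines.index("$Elements")
    except ValueError as exc:
        raise ValueError(f"{path}: malformed MSH file (missing section)") from exc
    n_nodes = int(lines[i_nodes + 1])
    verts = np.empty((n_nodes, 3))
    ids = np.empty(n_nodes, dtype=np.int64)
    for j in range(n_nodes):
        parts = lines[i_nodes + 2 + j].split()
        ids[j] = int(parts[0])
        verts[j] = [float(x) for x in parts[1:4]]
    id_map = {int(i): j for j, i in enumerate(ids)}
    n_elems = int(lines[i_elems + 1])
    tets, region = [], []
    for j in range(n_elems):
        parts = lines[i_elems + 2 + j].split()
        etype, ntags = int(parts[1]), int(parts[2])
        conn = parts[3 + ntags:]
        if etype == 4:
            tets.append([id_map[int(c)] for c in conn])
            region.append(int(parts[3]) if ntags >= 1 else 0)
    if not tets:
        raise ValueError(f"{path}: no tetrahedra in mesh file")
    mesh = VolumeMesh(verts, np.asarray(tets), np.asarray(region))
    _check_orphans(mesh, path)
    return mesh


def _load_vtk(path: str) -> VolumeMesh:
    with open(path) as f:
        tokens = f.read().split("\n")
    verts = tets = types = region = None
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(x) for x in tokens[i].split())
                i += 1
            verts = np.asarray(vals).reshape(n, 3)
            continue
        if line.startswith("CELLS"):
            n = int(line.split()[1])
            total = int(line.split()[2])
            vals = []
            i += 1
            while len(vals) < total:
                vals.extend(int(x) for x in tokens[i].split())
                i += 1
            cells = []
            k = 0
            for _ in range(n):
                sz = vals[k]
                cells.append(vals[k + 1 : k + 1 + sz])
                k += 1 + sz
            tets = cells
            continue
        if line.startswith("CELL_TYPES"):
            n = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < n:
                vals.extend(int(x) for x in tokens[i].split())
                i += 1
            types = np.asarray(vals)
            continue
        if line.startswith("SCALARS region"):
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while i < len(tokens) and len(vals) < len(types):
                vals.extend(int(x) for x in tokens[i].split())
                i += 1
            region = np.asarray(vals)
            continue
        i += 1
    if verts is None or tets is None or types is None:
        raise ValueError(f"{path}: malformed VTK file")
    keep = [j for j, t in enumerate(types) if t == 10]
    if not keep:
        raise ValueError(f"{path}: no tetrahedra in mesh file")
    tet_arr = np.asarray([tets[j] for j in keep])
    reg = region[keep] if region is not None else np.zeros(len(keep), dtype=np.int64)
    mesh = VolumeMesh(verts, tet_arr, reg)
    _check_orphans(mesh, path)
    return mesh


def load_mesh(path, format: str | None = None) -> VolumeMesh:
    """Load a tetrahedral mesh from Gmsh MSH 2.2 or legacy VTK ASCII."""
    path = str(path)
    fmt = format or ("msh" if path.endswith(".msh") else "vtk")
    if fmt == "msh":
        return _load_msh(path)
    if fmt == "vtk":
        return _load_vtk(path)
    raise ValueError(f"unknown mesh format {fmt!r} (supported: msh, vtk)")
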