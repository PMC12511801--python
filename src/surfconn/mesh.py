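"""Triangle-mesh handling for hemispheric surfaces.

A hemisphere is modelled as a closed (boundary-less) 2-manifold triangle
mesh. This module provides icosphere fixtures with nested subdivision
(level-k vertices are a prefix of level-(k+1) vertices, mirroring the
fsaverage-icoN template family), lumped vertex areas used as quadrature
weights everywhere downstream, nearest-vertex endpoint snapping, and the
coarse-to-fine vertex correspondence used to downsample spectral bases.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "TriangleMesh",
    "MeshCorrespondence",
    "generate_icosphere",
    "vertex_areas",
    "snap_to_vertices",
    "nested_correspondence",
    "load_mesh",
    "save_mesh",
    "load_mask",
    "validate_mesh",
]


@dataclasses.dataclass(frozen=True)
class TriangleMesh:
    """A closed 2-manifold triangle mesh.

    Parameters
    ----------
    vertices : (M, 3) float array
        Vertex coordinates in the embedding's length units (mm for
        cortical surfaces; unit-free on the unit sphere).
    faces : (T, 3) int array
        0-based vertex indices with consistent counter-clockwise
        orientation.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (M, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (T, 3)")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E, 2) sorted-index array."""
        f = self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)


@dataclasses.dataclass(frozen=True)
class MeshCorrespondence:
    """Injective map from coarse-mesh vertices into a fine mesh."""

    coarse_to_fine: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.coarse_to_fine, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("coarse_to_fine must be 1-D")
        if len(np.unique(idx)) != idx.size:
            raise ValueError("correspondence must be injective")
        object.__setattr__(self, "coarse_to_fine", idx)


def validate_mesh(mesh: TriangleMesh) -> None:
    """Check closed-manifold invariants; raise ValueError on violation.

    Every undirected edge must appear in exactly two faces, faces must be
    non-degenerate and unique.
    """
    f = mesh.faces
    if f.min() < 0 or f.max() >= mesh.n_vertices:
        raise ValueError("face index out of range")
    if (f[:, 0] == f[:, 1]).any() or (f[:, 1] == f[:, 2]).any() or (f[:, 0] == f[:, 2]).any():
        raise ValueError("degenerate face (repeated vertex)")
    key = np.sort(f, axis=1)
    if len(np.unique(key, axis=0)) != len(key):
        raise ValueError("duplicate face")
    e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e = np.sort(e, axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    if not (counts == 2).all():
        raise ValueError("mesh is not a closed 2-manifold (edge not shared by exactly 2 faces)")


# Icosahedron with outer-radius 1; golden-ratio construction.
def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts[0])
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def generate_icosphere(subdivisions: int, radius: float = 1.0) -> TriangleMesh:
    """Icosphere by uniform 1-to-4 subdivision with prefix-nested vertices.

    Each subdivision splits every triangle at its edge midpoints and
    projects the new vertices to the sphere. Parent vertices keep their
    indices, so the level-k vertex set is a prefix of the level-(k+1)
    vertex set — the nesting the fsaverage-icoN templates rely on.

    Parameters
    ----------
    subdivisions : int
        Number of refinement rounds, 0 (the icosahedron, 12 vertices)
        through 8.
    radius : float
        Sphere radius; all vertices are projected onto it.
    """
    if subdivisions < 0 or subdivisions > 8:
        raise ValueError("subdivisions must be in [0, 8]")
    if radius <= 0:
        raise ValueError("radius must be positive")
    verts, faces = _icosahedron()
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
    return TriangleMesh(vertices=verts * radius, faces=faces)


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # midpoint vertices are appended after the parents, keyed by sorted edge
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    edges, inv = np.unique(e, axis=0, return_inverse=True)
    mid = verts[edges[:, 0]] + verts[edges[:, 1]]
    mid /= np.linalg.norm(mid, axis=1, keepdims=True)
    new_verts = np.vstack([verts, mid])
    n0 = len(verts)
    t = len(faces)
    m01 = n0 + inv[:t]
    m12 = n0 + inv[t : 2 * t]
    m20 = n0 + inv[2 * t :]
    a, b, c = faces[:, 0], faces[:, 1], faces[:, 2]
    new_faces = np.empty((4 * t, 3), dtype=np.int64)
    new_faces[0::4] = np.column_stack([a, m01, m20])
    new_faces[1::4] = np.column_stack([b, m12, m01])
    new_faces[2::4] = np.column_stack([c, m20, m12])
    new_faces[3::4] = np.column_stack([m01, m12, m20])
    return new_verts, new_faces


def face_areas(mesh: TriangleMesh) -> np.ndarray:
    """Areas of all faces; raises on degenerate (zero-area) faces."""
    v = mesh.vertices
    f = mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    if (areas <= 0).any() or not np.isfinite(areas).all():
        raise ValueError("mesh has degenerate (zero-area) faces")
    return areas


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Lumped (barycentric) vertex areas m_i.

    Each vertex receives one third of the area of every incident face, so
    the m_i discretize the Riemannian surface measure: sum(m_i) equals the
    total mesh area exactly.
    """
    areas = face_areas(mesh)
    m = np.zeros(mesh.n_vertices)
    third = areas / 3.0
    for k in range(3):
        np.add.at(m, mesh.faces[:, k], third)
    return m


def snap_to_vertices(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Map each point to the index of the Euclidean-nearest mesh vertex.

    Exact ties are broken by the lowest vertex index. Chordal (not
    geodesic) distance is used: streamline endpoints lie on or very near
    the surface, where the two agree to leading order.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.size == 0:
        return np.empty(0, dtype=np.int64)
    if pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    v = mesh.vertices
    out = np.empty(len(pts), dtype=np.int64)
    # chunked brute force on explicit differences: exact ties (e.g. an edge
    # midpoint) give bitwise-equal distances, and argmin then returns the
    # first — i.e. lowest-index — minimizer, our deterministic tie rule
    chunk = max(1, int(8e6) // max(1, len(v)))
    for lo in range(0, len(pts), chunk):
        p = pts[lo : lo + chunk]
        d2 = ((p[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
        out[lo : lo + chunk] = np.argmin(d2, axis=1)
    return out


def nested_correspondence(
    coarse: TriangleMesh, fine: TriangleMesh, tol: float = 1e-8
) -> MeshCorrespondence:
    """Correspondence between two meshes from the same nested subdivision.

    The subdivision scheme appends new vertices, so coarse vertex i is fine
    vertex i; this is verified by coordinate agreement within ``tol``.

    Raises
    ------
    ValueError
        If the fine mesh is smaller than the coarse one or coordinates
        disagree (the meshes are not nested refinements of one base).
    """
    mc = coarse.n_vertices
    if fine.n_vertices < mc:
        raise ValueError("fine mesh has fewer vertices than coarse mesh")
    diff = np.abs(coarse.vertices - fine.vertices[:mc]).max()
    if diff > tol:
        raise ValueError(
            f"meshes are not nested: max coordinate mismatch {diff:.3g} > tol {tol:.3g}"
        )
    return MeshCorrespondence(coarse_to_fine=np.arange(mc, dtype=np.int64))


# ---------------------------------------------------------------------------
# I/O

def load_mesh(path: str) -> TriangleMesh:
    """Read a surface mesh from OFF/PLY (trimesh), FreeSurfer or GIFTI (nibabel)."""
    p = str(path)
    lower = p.lower()
    if lower.endswith((".off", ".ply", ".stl", ".obj")):
        import trimesh as _trimesh

        tm = _trimesh.load(p, process=False)
        return TriangleMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))
    if lower.endswith(".gii"):
        import nibabel as nib

        img = nib.load(p)
        coords = img.darrays[0].data
        faces = img.darrays[1].data
        return TriangleMesh(vertices=coords, faces=faces)
    # FreeSurfer binary surface (no extension convention: lh.white etc.)
    import nibabel.freesurfer.io as fsio

    coords, faces = fsio.read_geometry(p)
    return TriangleMesh(vertices=coords, faces=faces)


def save_mesh(mesh: TriangleMesh, path: str) -> None:
    """Write OFF or ASCII PLY via trimesh."""
    import trimesh as _trimesh

    tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    lower = str(path).lower()
    if lower.endswith(".ply"):
        data = _trimesh.exchange.ply.export_ply(tm, encoding="ascii")
        with open(path, "wb") as fh:
            fh.write(data)
    elif lower.endswith(".off"):
        data = _trimesh.exchange.off.export_off(tm)
        with open(path, "w") as fh:
            fh.write(data)
    else:
        raise ValueError("save_mesh supports .ply (ASCII) and .off")


def load_mask(path: str, n_vertices: int) -> np.ndarray:
    """Read a vertex mask: one 0/1 flag per line, or a FreeSurfer label file.

    Returns a boolean array where True marks excluded vertices (e.g. the
    medial wall). A FreeSurfer .label lists the *included-in-label*
    vertices; those are the ones flagged.
    """
    p = str(path)
    if p.lower().endswith(".label"):
        import nibabel.freesurfer.io as fsio

        idx = fsio.read_label(p)
        flags = np.zeros(n_vertices, dtype=bool)
        flags[np.asarray(idx, dtype=np.int64)] = True
        return flags
    vals = np.loadtxt(p, dtype=np.int64)
    flags = np.atleast_1d(vals).astype(bool)
    if flags.size != n_vertices:
        raise ValueError(f"mask length {flags.size} != vertex count {n_vertices}")
    return flags
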