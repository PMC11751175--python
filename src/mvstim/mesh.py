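"""Tetrahedral mesh containers and structured mesh generators.

All field solves in this package run on first-order tetrahedra.  Three
generators cover every geometry the model needs:

* :func:`voxel_mesh` — tetrahedralizes the True voxels of a boolean mask using
  the Kuhn (Freudenthal) 6-tet cube split, which is conforming across
  neighbouring cubes when applied with the same orientation everywhere.  Used
  for the labyrinth (implicit solid) and for box fixtures.
* :func:`extrude_triangulation` — extrudes a 2-D triangulation through a list
  of layer offsets, splitting each prism into three tets with the
  sorted-index (Dompierre) rule so shared quad faces agree between prisms.
  Used for the body-fitted cylinder (Poiseuille oracle).
* :func:`spherical_shell_mesh` — spherified-cube shell between two radii with
  vertices exactly on both spheres.  Used for the concentric-sphere Laplace
  oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TetMesh",
    "voxel_mesh",
    "box_mesh",
    "disk_triangulation",
    "extrude_triangulation",
    "cylinder_mesh",
    "spherical_shell_mesh",
]

# Kuhn split of the unit cube.  Corner index = 4*dx + 2*dy + dz.  Each row is
# one tet walking from corner 000 to 111 adding one axis at a time; the six
# permutations tile the cube and match across faces of adjacent cubes.
_KUHN_TETS = np.array(
    [
        [0, 4, 6, 7],  # x, y, z
        [0, 4, 5, 7],  # x, z, y
        [0, 2, 6, 7],  # y, x, z
        [0, 2, 3, 7],  # y, z, x
        [0, 1, 5, 7],  # z, x, y
        [0, 1, 3, 7],  # z, y, x
    ],
    dtype=np.int64,
)


def tet_volumes(vertices: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Signed tetrahedron volumes (positive for right-handed ordering)."""
    a = vertices[cells[:, 1]] - vertices[cells[:, 0]]
    b = vertices[cells[:, 2]] - vertices[cells[:, 0]]
    c = vertices[cells[:, 3]] - vertices[cells[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def _orient_positive(vertices: np.ndarray, cells: np.ndarray) -> np.ndarray:
    vol = tet_volumes(vertices, cells)
    flip = vol < 0
    cells = cells.copy()
    cells[flip, 2], cells[flip, 3] = cells[flip, 3], cells[flip, 2].copy()
    return cells


@dataclass
class TetMesh:
    """An unstructured tetrahedral mesh.

    ``vertices`` is (nv, 3) float64; ``cells`` is (nc, 4) int64 with positive
    orientation.  Boundary faces and the cell adjacency are computed lazily
    and cached.
    """

    vertices: np.ndarray
    cells: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.cells = _orient_positive(self.vertices, np.asarray(self.cells, dtype=np.int64))

    # -- basic measures ----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def volumes(self) -> np.ndarray:
        if "volumes" not in self._cache:
            self._cache["volumes"] = tet_volumes(self.vertices, self.cells)
        return self._cache["volumes"]

    def centroids(self) -> np.ndarray:
        if "centroids" not in self._cache:
            self._cache["centroids"] = self.vertices[self.cells].mean(axis=1)
        return self._cache["centroids"]

    # -- faces -------------------------------------------------------------
    def _face_table(self):
        """All cell faces, sorted vertex triples, with owning cell ids."""
        if "face_table" in self._cache:
            return self._cache["face_table"]
        # local faces opposite each vertex
        local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
        faces = self.cells[:, local]                      # (nc, 4, 3)
        faces = faces.reshape(-1, 3)                      # (4nc, 3)
        owners = np.repeat(np.arange(self.n_cells), 4)
        key = np.sort(faces, axis=1)
        self._cache["face_table"] = (faces, key, owners)
        return self._cache["face_table"]

    def boundary_faces(self):
        """(faces, owner_cells): faces with exactly one adjacent cell.

        Faces are returned with outward orientation (right-hand normal points
        out of the mesh).
        """
        if "boundary" in self._cache:
            return self._cache["boundary"]
        faces, key, owners = self._face_table()
        order = np.lexsort(key.T[::-1])
        skey = key[order]
        uniq_first = np.ones(len(skey), dtype=bool)
        uniq_first[1:] = np.any(skey[1:] != skey[:-1], axis=1)
        # boundary face: its sorted key occurs exactly once
        counts = np.diff(np.append(np.flatnonzero(uniq_first), len(skey)))
        starts = np.flatnonzero(uniq_first)
        single = starts[counts == 1]
        idx = order[single]
        bfaces = faces[idx]
        bowners = owners[idx]
        self._cache["boundary"] = (bfaces, bowners)
        return self._cache["boundary"]

    def interior_faces(self):
        """(faces, cell_pair): faces shared by exactly two cells."""
        if "interior" in self._cache:
            return self._cache["interior"]
        faces, key, owners = self._face_table()
        order = np.lexsort(key.T[::-1])
        skey = key[order]
        same = np.all(skey[1:] == skey[:-1], axis=1)
        first = np.flatnonzero(same)
        idx_a = order[first]
        idx_b = order[first + 1]
        self._cache["interior"] = (faces[idx_a], np.column_stack([owners[idx_a], owners[idx_b]]))
        return self._cache["interior"]

    def cell_adjacency(self):
        """Sparse symmetric (nc, nc) adjacency over shared faces."""
        from scipy.sparse import coo_matrix

        _, pairs = self.interior_faces()
        i = np.concatenate([pairs[:, 0], pairs[:, 1]])
        j = np.concatenate([pairs[:, 1], pairs[:, 0]])
        data = np.ones(len(i), dtype=np.int8)
        return coo_matrix((data, (i, j)), shape=(self.n_cells, self.n_cells)).tocsr()

    def boundary_vertices(self) -> np.ndarray:
        bfaces, _ = self.boundary_faces()
        return np.unique(bfaces)

    def total_volume(self) -> float:
        return float(self.volumes().sum())


def face_areas_normals(vertices: np.ndarray, faces: np.ndarray):
    """Areas and unit normals of triangle faces (right-hand rule)."""
    a = vertices[faces[:, 1]] - vertices[faces[:, 0]]
    b = vertices[faces[:, 2]] - vertices[faces[:, 0]]
    n = np.cross(a, b)
    norm = np.linalg.norm(n, axis=1)
    areas = norm / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = n / norm[:, None]
    return areas, unit


# ---------------------------------------------------------------------------
# voxel meshing
# ---------------------------------------------------------------------------

def voxel_mesh(mask: np.ndarray, origin, h: float):
    """Tet mesh of the True voxels of ``mask`` with spacing ``h``.

    Returns ``(mesh, cell_voxel)`` where ``cell_voxel`` maps each tet to the
    flat index of its parent voxel in ``mask``.  Vertex numbering is
    deterministic (lexicographic over the vertex grid), so the mesh is
    bit-identical for identical inputs.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty voxel mask: no cells inside the geometry")
    nx, ny, nz = mask.shape
    origin = np.asarray(origin, dtype=np.float64)

    vox = np.argwhere(mask)                               # (m, 3) voxel ijk
    m = len(vox)
    # vertex grid ids: (nx+1, ny+1, nz+1) flattened
    gny, gnz = ny + 1, nz + 1

    def gid(i, j, k):
        return (i * gny + j) * gnz + k

    corners = np.empty((m, 8), dtype=np.int64)
    for c in range(8):
        dx, dy, dz = c >> 2 & 1, c >> 1 & 1, c & 1
        corners[:, c] = gid(vox[:, 0] + dx, vox[:, 1] + dy, vox[:, 2] + dz)

    used = np.unique(corners)
    remap = np.full((nx + 1) * gny * gnz, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    corners = remap[corners]

    ii = used // (gny * gnz)
    jj = (used // gnz) % gny
    kk = used % gnz
    vertices = origin + h * np.column_stack([ii, jj, kk]).astype(np.float64)

    cells = corners[:, _KUHN_TETS].reshape(-1, 4)
    cell_voxel = np.repeat(np.ravel_multi_index(vox.T, mask.shape), 6)
    mesh = TetMesh(vertices, cells)
    return mesh, cell_voxel


def box_mesh(lengths, n) -> TetMesh:
    """Structured tet mesh of a box with ``n = (nx, ny, nz)`` voxels."""
    n = tuple(int(v) for v in np.atleast_1d(n) * np.ones(3, dtype=int))
    mask = np.ones(n, dtype=bool)
    h = 1.0
    mesh, _ = voxel_mesh(mask, (0.0, 0.0, 0.0), h)
    mesh.vertices *= np.asarray(lengths, dtype=float) / np.asarray(n, dtype=float)
    mesh._cache.clear()
    return mesh


# ---------------------------------------------------------------------------
# extruded meshes (body-fitted cylinder)
# ---------------------------------------------------------------------------

def disk_triangulation(radius: float, n_rings: int):
    """Structured polar triangulation of a disk, vertices exactly on r=radius."""
    pts = [(0.0, 0.0)]
    ring_start = [0]
    for r in range(1, n_rings + 1):
        k = 6 * r
        ring_start.append(len(pts))
        ang = 2 * np.pi * np.arange(k) / k
        rad = radius * r / n_rings
        pts.extend(zip(rad * np.cos(ang), rad * np.sin(ang)))
    pts = np.array(pts)

    tris = []
    for r in range(1, n_rings + 1):
        inner, outer = ring_start[r - 1], ring_start[r]
        n_in, n_out = 6 * (r - 1) if r > 1 else 1, 6 * r
        if r == 1:
            for a in range(6):
                tris.append((0, outer + a, outer + (a + 1) % 6))
            continue
        # walk both rings keeping angles aligned
        j = 0
        for a in range(n_out):
            v0 = outer + a
            v1 = outer + (a + 1) % n_out
            # inner vertex nearest in angle to a
            ja = int(np.floor(a * n_in / n_out))
            jb = int(np.floor((a + 1) * n_in / n_out)) % n_in
            tris.append((v0, v1, inner + ja))
            if jb != ja:
                tris.append((v1, inner + jb, inner + ja))
            j = jb
        del j
    tris = np.array(tris, dtype=np.int64)
    return pts, tris


def _prism_to_tets(p):
    """Split prism (p0..p2 bottom, p3..p5 top) into 3 tets, index rule.

    The Dompierre rotation + diagonal rule makes splits agree on shared quad
    faces between adjacent prisms.
    """
    rot = [(0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4)]
    k = int(np.argmin([p[0], p[1], p[2]]))
    q = [p[i] for i in rot[k]]
    if min(q[1], q[5]) < min(q[2], q[4]):
        return [(q[0], q[1], q[2], q[5]), (q[0], q[1], q[5], q[4]), (q[0], q[4], q[5], q[3])]
    return [(q[0], q[1], q[2], q[4]), (q[0], q[4], q[2], q[5]), (q[0], q[4], q[5], q[3])]


def extrude_triangulation(points2d: np.ndarray, tris: np.ndarray, z_layers) -> TetMesh:
    """Extrude a 2-D triangulation along z through the given layer offsets."""
    z_layers = np.asarray(z_layers, dtype=float)
    npt = len(points2d)
    nz = len(z_layers)
    vertices = np.column_stack(
        [
            np.tile(points2d[:, 0], nz),
            np.tile(points2d[:, 1], nz),
            np.repeat(z_layers, npt),
        ]
    )
    cells = []
    for lz in range(nz - 1):
        base, top = lz * npt, (lz + 1) * npt
        for t in tris:
            prism = (base + t[0], base + t[1], base + t[2], top + t[0], top + t[1], top + t[2])
            cells.extend(_prism_to_tets(prism))
    return TetMesh(vertices, np.array(cells, dtype=np.int64))


def cylinder_mesh(radius: float, length: float, n_rings: int, n_layers: int) -> TetMesh:
    """Body-fitted cylinder along z, lateral vertices exactly on the wall."""
    pts, tris = disk_triangulation(radius, n_rings)
    return extrude_triangulation(pts, tris, np.linspace(0.0, length, n_layers + 1))


# ---------------------------------------------------------------------------
# spherified-cube shell
# ---------------------------------------------------------------------------

def _cube_surface_grid(n: int):
    """Vertices and quads of an n x n per-face grid on the unit cube surface."""
    lin = np.linspace(-1.0, 1.0, n + 1)
    verts = {}
    order = []

    def vid(p):
        key = tuple(np.round(p, 12))
        if key not in verts:
            verts[key] = len(order)
            order.append(key)
        return verts[key]

    quads = []
    axes = [(0, 1, 2), (1, 2, 0), (2, 0, 1)]
    for ax, u, v in axes:
        for s in (-1.0, 1.0):
            grid = np.empty((n + 1, n + 1), dtype=np.int64)
            for i, a in enumerate(lin):
                for j, b in enumerate(lin):
                    p = np.zeros(3)
                    p[ax] = s
                    p[u] = a
                    p[v] = b
                    grid[i, j] = vid(p)
            for i in range(n):
                for j in range(n):
                    q = (grid[i, j], grid[i + 1, j], grid[i + 1, j + 1], grid[i, j + 1])
                    quads.append(q)
    return np.array(order, dtype=float), np.array(quads, dtype=np.int64)


def spherical_shell_mesh(r_inner: float, r_outer: float, n_face: int, n_layers: int) -> TetMesh:
    """Tet mesh of a spherical shell; vertices exactly on both radii."""
    cube_pts, quads = _cube_surface_grid(n_face)
    unit = cube_pts / np.linalg.norm(cube_pts, axis=1)[:, None]
    # split quads into triangles with the sorted-index diagonal rule so the
    # surface triangulation (and hence the prisms) is conforming
    tris = []
    for q in quads:
        if min(q[0], q[2]) < min(q[1], q[3]):
            tris.append((q[0], q[1], q[2]))
            tris.append((q[0], q[2], q[3]))
        else:
            tris.append((q[1], q[2], q[3]))
            tris.append((q[1], q[3], q[0]))
    tris = np.array(tris, dtype=np.int64)

    radii = np.linspace(r_inner, r_outer, n_layers + 1)
    npt = len(unit)
    vertices = np.concatenate([unit * r for r in radii])
    cells = []
    for lz in range(n_layers):
        base, top = lz * npt, (lz + 1) * npt
        for t in tris:
            prism = (base + t[0], base + t[1], base + t[2], top + t[0], top + t[1], top + t[2])
            cells.extend(_prism_to_tets(prism))
    return TetMesh(vertices, np.array(cells, dtype=np.int64))
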