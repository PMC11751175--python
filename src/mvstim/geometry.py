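"""Idealized membranous-labyrinth geometry.

The model labyrinth is an implicit solid, voxelized and tetrahedralized:

* an ellipsoidal utricle (semi-axes along the anterior/left/superior body
  axes),
* three mutually orthogonal torus canals (horizontal H, superior/anterior S,
  posterior P) whose rings pass through the utricle so each canal opens into
  it at two points,
* one spherical ampulla per canal on the ring just outside the utricle, and
* one thin cupula disk per ampulla (a slab of cells perpendicular to the
  local canal axis) sealing the ampulla+duct off from the utricle.

Body frame (right-handed): X = posterior->anterior, Y = right->left,
Z = feet->head (superior).  The left labyrinth is built; the right one is its
reflection through the sagittal plane y = 0.

Boundary faces are labeled with the nine dark-cell / hair-cell patches plus
``wall``: a secretory (dark-cell) band in each ampulla next to its crista,
dark bands on the posterior utricle wall and on the superior canal's
posterior limb (standing in for the common crus), the three cristae (the
exposed rim of each cupula disk) and the utricular macula on the anterior
floor of the utricle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import TetMesh, voxel_mesh, face_areas_normals

__all__ = [
    "LabyrinthConfig",
    "LabyrinthGeometry",
    "HeadOrientation",
    "CANALS",
    "PATCHES",
    "REGIONS",
    "ZONES",
    "build_labyrinth",
    "mirror_labyrinth",
    "orient",
    "rotation_ets",
    "rotation_fe",
]

CANALS = ("H", "S", "P")
REGIONS = ("endolymph", "cupula_H", "cupula_S", "cupula_P")
PATCHES = (
    "wall",
    "dark_ampulla_H",
    "dark_ampulla_S",
    "dark_ampulla_P",
    "dark_utricle",
    "dark_common_crus",
    "hair_crista_H",
    "hair_crista_S",
    "hair_crista_P",
    "hair_macula",
)
ZONES = ("utricle", "ampulla", "duct")

REGION_ID = {name: i for i, name in enumerate(REGIONS)}
PATCH_ID = {name: i for i, name in enumerate(PATCHES)}
ZONE_ID = {name: i for i, name in enumerate(ZONES)}

DARK_PATCHES = tuple(p for p in PATCHES if p.startswith("dark_"))
HAIR_PATCHES = tuple(p for p in PATCHES if p.startswith("hair_"))


@dataclass(frozen=True)
class LabyrinthConfig:
    """Geometry parameters, in millimetres.

    Dimensions are idealized defaults in the range of the adult human
    membranous labyrinth, not anatomical claims.
    """

    canal_major_radius_mm: float = 3.2
    duct_radius_mm: float = 0.16
    ampulla_radius_mm: float = 0.6
    cupula_thickness_mm: float = 0.3
    utricle_semiaxes_mm: tuple = (1.5, 0.75, 0.5)
    voxel_mm: float = 0.1
    #: arc angle (rad) along each ring, measured from the utricle, at which
    #: the ampulla sits
    ampulla_arc_rad: tuple = (0.45, 0.7, 0.7)       # H, S, P
    #: axial width of the secretory (dark-cell) strip beside each crista;
    #: kept narrow — the dominant current to each crista arrives through the
    #: canal from the utricular and common-crus dark regions
    ampulla_dark_band_mm: float = 0.15
    #: arc interval on the superior canal's posterior limb carrying the
    #: common-crus dark band
    common_crus_arc_rad: tuple = (-0.75, -0.45)
    #: anterior-posterior extent of the utricular macula on the utricle
    #: floor, as fractions of the anterior semi-axis (macula sits in the
    #: anterior part of the utricle floor)
    macula_x_frac: tuple = (0.25, 0.95)
    #: posterior-wall dark-cell region starts behind this fraction of the
    #: anterior semi-axis
    dark_utricle_x_frac: float = -0.6
    min_cells: int = 500

    def validate(self) -> None:
        if not (self.canal_major_radius_mm > self.duct_radius_mm > 0):
            raise ValueError(
                "infeasible geometry: need canal torus radius > duct radius > 0 "
                f"(got {self.canal_major_radius_mm} and {self.duct_radius_mm})"
            )
        if not all(s > 0 for s in self.utricle_semiaxes_mm):
            raise ValueError("utricle semi-axes must be positive")
        if self.ampulla_radius_mm <= self.duct_radius_mm:
            raise ValueError("ampulla radius must exceed duct radius")
        if not (0 < self.cupula_thickness_mm < 2 * self.ampulla_radius_mm):
            raise ValueError("cupula thickness must fit inside the ampulla")
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be positive")


class _Canal:
    """One torus canal: ring through the utricle, parametrized by arc angle t.

    t = 0 at the ring point inside the utricle; the ampulla sits at t_amp > 0.
    """

    def __init__(self, name, origin, e1, e2, a, t_amp):
        self.name = name
        self.o = np.asarray(origin, float)
        self.e1 = np.asarray(e1, float)
        self.e2 = np.asarray(e2, float)
        self.a = float(a)
        self.t_amp = float(t_amp)
        self.center = self.o + self.a * self.e2
        self.plane_normal = np.cross(self.e1, self.e2)

    def point(self, t):
        t = np.asarray(t, float)
        return (
            self.center
            + self.a * (np.sin(t)[..., None] * self.e1 - np.cos(t)[..., None] * self.e2)
        )

    def tangent(self, t):
        t = np.asarray(t, float)
        v = np.cos(t)[..., None] * self.e1 + np.sin(t)[..., None] * self.e2
        return v

    def t_of(self, pts):
        q = np.asarray(pts, float) - self.center
        return np.arctan2(q @ self.e1, -(q @ self.e2))

    def ring_distance(self, pts):
        q = np.asarray(pts, float) - self.center
        w = q @ self.plane_normal
        q_pl = q - np.outer(w, self.plane_normal)
        return np.hypot(np.linalg.norm(q_pl, axis=-1) - self.a, w)

    @property
    def ampulla_center(self):
        return self.point(self.t_amp)

    @property
    def ampulla_axis(self):
        """Unit vector along the canal at the ampulla, pointing away from the utricle."""
        return self.tangent(self.t_amp)


def _canals(cfg: LabyrinthConfig):
    a = cfg.canal_major_radius_mm
    tH, tS, tP = cfg.ampulla_arc_rad
    # lateral canal chord crosses the utricle obliquely: the ampullated end
    # opens antero-laterally, the non-ampullated end postero-medially (as in
    # the human labyrinth, where the non-ampullated end joins the utricle
    # near the common crus on the medial side)
    e1H = np.array([0.781, 0.625, 0.0])
    e2H = np.array([-0.625, 0.781, 0.0])
    return {
        # lateral canal: axial plane, bulges toward the left ear (+Y)
        "H": _Canal("H", (1.0, 0.35, 0.0), e1H, e2H, a, tH),
        # superior/anterior canal: parasagittal plane slightly medial,
        # arching superiorly, ampulla anterior
        "S": _Canal("S", (0.5, -0.45, 0.0), (1, 0, 0), (0, 0, 1), a, tS),
        # posterior canal: coronal plane posterior to the utricle centre,
        # arching inferiorly, ampulla on the lateral-inferior limb
        "P": _Canal("P", (-0.5, 0.0, 0.0), (0, 1, 0), (0, 0, -1), a, tP),
    }


@dataclass
class LabyrinthGeometry:
    """Labeled tet mesh of one membranous labyrinth (lengths in mm)."""

    mesh: TetMesh
    cell_region: np.ndarray          # (nc,) REGION_ID values
    cell_zone: np.ndarray            # (nc,) ZONE_ID values
    boundary_faces: np.ndarray       # (nf, 3) vertex ids (outward oriented)
    face_patch: np.ndarray           # (nf,) PATCH_ID values
    side: str                        # "left" | "right"
    crista_frames: dict              # canal -> dict(center, normal, utriculopetal, plane_normal)
    canal_cross_sections: dict       # canal -> [(point, normal, radius), ...]
    axes: np.ndarray                 # rows: anterior, left, superior (body axes in world coords)
    utricle_center: np.ndarray
    config: LabyrinthConfig
    # point-location support (body frame voxel grid)
    _vox_origin: np.ndarray = field(repr=False, default=None)
    _vox_shape: tuple = field(repr=False, default=None)
    _vox_flat: np.ndarray = field(repr=False, default=None)   # sorted flat voxel ids
    _world_from_body: np.ndarray = field(repr=False, default=None)

    # -- derived helpers -----------------------------------------------------
    def patch_faces(self, name: str) -> np.ndarray:
        return self.boundary_faces[self.face_patch == PATCH_ID[name]]

    def patch_area(self, name: str) -> float:
        faces = self.patch_faces(name)
        if len(faces) == 0:
            return 0.0
        areas, _ = face_areas_normals(self.mesh.vertices, faces)
        return float(areas.sum())

    def region_cells(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.cell_region == REGION_ID[name])

    def fluid_cells(self) -> np.ndarray:
        return np.flatnonzero(self.cell_region == REGION_ID["endolymph"])

    def present_patches(self) -> set:
        return {PATCHES[i] for i in np.unique(self.face_patch)}

    def locate_points(self, pts: np.ndarray) -> np.ndarray:
        """Cell index containing each point (-1 if outside the mesh)."""
        pts = np.atleast_2d(np.asarray(pts, float))
        body = pts @ self._world_from_body          # back to body frame
        h = self.config.voxel_mm
        ijk = np.floor((body - self._vox_origin) / h).astype(np.int64)
        out = np.full(len(pts), -1, dtype=np.int64)
        shape = self._vox_shape
        ok = np.all((ijk >= 0) & (ijk < np.asarray(shape)), axis=1)
        if not ok.any():
            return out
        flat = np.ravel_multi_index(ijk[ok].T, shape)
        pos = np.searchsorted(self._vox_flat, flat)
        pos = np.clip(pos, 0, len(self._vox_flat) - 1)
        hit = self._vox_flat[pos] == flat
        rows = np.flatnonzero(ok)[hit]
        ranks = pos[hit]
        # test the 6 Kuhn tets of each voxel with barycentric coordinates
        verts = self.mesh.vertices
        cells = self.mesh.cells
        remaining = np.ones(len(rows), dtype=bool)
        for k in range(6):
            if not remaining.any():
                break
            cid = ranks * 6 + k
            tet = cells[cid]
            p0 = verts[tet[:, 0]]
            T = np.stack(
                [verts[tet[:, 1]] - p0, verts[tet[:, 2]] - p0, verts[tet[:, 3]] - p0], axis=2
            )
            lam = np.linalg.solve(T, (pts[rows] - p0)[..., None])[..., 0]
            inside = (
                (lam >= -1e-9).all(axis=1) & (lam.sum(axis=1) <= 1 + 1e-9) & remaining
            )
            out[rows[inside]] = cid[inside]
            remaining &= ~inside
        return out

    def interpolate_vertex_field(self, field_v: np.ndarray, pts: np.ndarray):
        """P1 interpolation of a per-vertex field at arbitrary points.

        Returns (values, inside_mask); values are 0 outside.
        """
        pts = np.atleast_2d(np.asarray(pts, float))
        cid = self.locate_points(pts)
        inside = cid >= 0
        shape = (len(pts),) + np.shape(field_v)[1:]
        vals = np.zeros(shape)
        if inside.any():
            verts = self.mesh.vertices
            tet = self.mesh.cells[cid[inside]]
            p0 = verts[tet[:, 0]]
            T = np.stack(
                [verts[tet[:, 1]] - p0, verts[tet[:, 2]] - p0, verts[tet[:, 3]] - p0], axis=2
            )
            lam = np.linalg.solve(T, (pts[inside] - p0)[..., None])[..., 0]
            w = np.concatenate([(1 - lam.sum(axis=1))[:, None], lam], axis=1)  # (m,4)
            vals[inside] = np.einsum("mi,mi...->m...", w, field_v[tet])
        return vals, inside


# ---------------------------------------------------------------------------
# head orientation
# ---------------------------------------------------------------------------

def _rot(axis: int, deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    R = np.eye(3)
    i, j = [(1, 2), (2, 0), (0, 1)][axis]
    R[i, i] = R[j, j] = c
    R[i, j] = -s
    R[j, i] = s
    return R


def rotation_ets(ets_deg: float) -> np.ndarray:
    """Ear-to-shoulder roll about the anterior axis; positive = left ETS."""
    # positive ETS takes the left ear down toward the left shoulder
    return _rot(0, -ets_deg)


def rotation_fe(fe_deg: float) -> np.ndarray:
    """Flexion-extension pitch about the interaural axis; negative = flexion."""
    # flexion (negative fe) brings the nose down toward the chest
    return _rot(1, -fe_deg)


@dataclass(frozen=True)
class HeadOrientation:
    """Head attitude relative to the bore axis (degrees).

    ``pitch_offset_deg`` raises the utricle/lateral-canal plane above the
    axial plane, reproducing the natural inclination of those structures in
    a supine subject.
    """

    ets_deg: float = 0.0
    fe_deg: float = 0.0
    pitch_offset_deg: float = 20.0

    def __post_init__(self):
        for name in ("ets_deg", "fe_deg"):
            v = getattr(self, name)
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"{name} must lie in (-180, 180], got {v}")

    @property
    def rotation(self) -> np.ndarray:
        return rotation_ets(self.ets_deg) @ rotation_fe(self.fe_deg + self.pitch_offset_deg)


# ---------------------------------------------------------------------------
# builder
# ---------------------------------------------------------------------------

def build_labyrinth(config: LabyrinthConfig | None = None) -> LabyrinthGeometry:
    """Build the left labyrinth from the configuration."""
    cfg = config or LabyrinthConfig()
    cfg.validate()
    canals = _canals(cfg)
    ax, ay, az = cfg.utricle_semiaxes_mm
    r_duct = cfg.duct_radius_mm
    r_amp = cfg.ampulla_radius_mm
    h_cup = cfg.cupula_thickness_mm
    h = cfg.voxel_mm

    # bounding box over all primitives
    lo = np.array([-ax, -ay, -az], float)
    hi = np.array([ax, ay, az], float)
    for c in canals.values():
        t = np.linspace(-np.pi, np.pi, 721)
        ring = c.point(t)
        lo = np.minimum(lo, ring.min(axis=0) - r_amp)
        hi = np.maximum(hi, ring.max(axis=0) + r_amp)
    lo -= 2 * h
    hi += 2 * h
    shape = tuple(np.ceil((hi - lo) / h).astype(int))

    ii = lo[0] + h * (np.arange(shape[0]) + 0.5)
    jj = lo[1] + h * (np.arange(shape[1]) + 0.5)
    kk = lo[2] + h * (np.arange(shape[2]) + 0.5)
    X, Y, Z = np.meshgrid(ii, jj, kk, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    f_ell = (pts[:, 0] / ax) ** 2 + (pts[:, 1] / ay) ** 2 + (pts[:, 2] / az) ** 2
    inside = f_ell <= 1.0
    for c in canals.values():
        inside |= c.ring_distance(pts) <= r_duct
        inside |= np.linalg.norm(pts - c.ampulla_center, axis=1) <= r_amp
    mask = inside.reshape(shape)

    mesh, _ = voxel_mesh(mask, lo, h)
    if mesh.n_cells < cfg.min_cells:
        raise ValueError(
            f"mesh resolution too coarse: {mesh.n_cells} cells < minimum {cfg.min_cells}"
        )

    cent = mesh.centroids()
    f_ell_c = (cent[:, 0] / ax) ** 2 + (cent[:, 1] / ay) ** 2 + (cent[:, 2] / az) ** 2

    # regions: cupula slabs
    region = np.zeros(mesh.n_cells, dtype=np.int8)
    for c in canals.values():
        amp = c.ampulla_center
        axis = c.ampulla_axis
        d_sphere = np.linalg.norm(cent - amp, axis=1)
        axial = (cent - amp) @ axis
        slab = (np.abs(axial) <= h_cup / 2) & (d_sphere <= r_amp) & (f_ell_c > 1.0)
        region[slab] = REGION_ID[f"cupula_{c.name}"]

    # zones by deepest membership margin
    margins = [1.0 - np.sqrt(np.maximum(f_ell_c, 0.0))]
    m_amp = np.full(mesh.n_cells, -np.inf)
    m_duct = np.full(mesh.n_cells, -np.inf)
    duct_owner = np.zeros(mesh.n_cells, dtype=np.int8)
    amp_owner = np.zeros(mesh.n_cells, dtype=np.int8)
    for i, c in enumerate(canals.values()):
        ma = 1.0 - np.linalg.norm(cent - c.ampulla_center, axis=1) / r_amp
        md = 1.0 - c.ring_distance(cent) / r_duct
        upd = ma > m_amp
        amp_owner[upd] = i
        m_amp = np.maximum(m_amp, ma)
        upd = md > m_duct
        duct_owner[upd] = i
        m_duct = np.maximum(m_duct, md)
    margins.extend([m_amp, m_duct])
    zone = np.argmax(np.stack(margins), axis=0).astype(np.int8)

    # boundary patches
    bfaces, bowners = mesh.boundary_faces()
    fc = mesh.vertices[bfaces].mean(axis=1)
    _, fnormals = face_areas_normals(mesh.vertices, bfaces)
    patch = np.zeros(len(bfaces), dtype=np.int8)

    owner_region = region[bowners]
    owner_zone = zone[bowners]
    assigned = np.zeros(len(bfaces), dtype=bool)

    # 1) cristae: the exposed rim of each cupula disk
    for c in canals.values():
        sel = (owner_region == REGION_ID[f"cupula_{c.name}"]) & ~assigned
        patch[sel] = PATCH_ID[f"hair_crista_{c.name}"]
        assigned |= sel

    # 2) ampullary dark bands: on the ampulla wall, beside the crista on the
    #    canal side
    for i, c in enumerate(canals.values()):
        amp, axis = c.ampulla_center, c.ampulla_axis
        d_sphere = np.linalg.norm(fc - amp, axis=1)
        axial = (fc - amp) @ axis
        sel = (
            ~assigned
            & (owner_zone == ZONE_ID["ampulla"])
            & (amp_owner[bowners] == i)
            & (d_sphere <= r_amp + h)
            & (axial > h_cup / 2)
            & (axial <= h_cup / 2 + cfg.ampulla_dark_band_mm)
        )
        patch[sel] = PATCH_ID[f"dark_ampulla_{c.name}"]
        assigned |= sel

    # 3) common-crus dark band on the superior canal's posterior limb
    cS = canals["S"]
    tS = cS.t_of(fc)
    t0, t1 = cfg.common_crus_arc_rad
    f_ell_f = (fc[:, 0] / ax) ** 2 + (fc[:, 1] / ay) ** 2 + (fc[:, 2] / az) ** 2
    sel = (
        ~assigned
        & (owner_zone == ZONE_ID["duct"])
        & (duct_owner[bowners] == list(canals).index("S"))
        & (tS >= t0)
        & (tS <= t1)
        & (f_ell_f > 1.0)
    )
    patch[sel] = PATCH_ID["dark_common_crus"]
    assigned |= sel

    # 4) utricular dark cells on the posterior wall
    sel = ~assigned & (owner_zone == ZONE_ID["utricle"]) & (fc[:, 0] < cfg.dark_utricle_x_frac * ax)
    patch[sel] = PATCH_ID["dark_utricle"]
    assigned |= sel

    # 5) macula on the anterior floor of the utricle
    x0, x1 = cfg.macula_x_frac
    sel = (
        ~assigned
        & (owner_zone == ZONE_ID["utricle"])
        & (fnormals[:, 2] < -0.5)
        & (fc[:, 2] < -0.3 * az)
        & (fc[:, 0] > x0 * ax)
        & (fc[:, 0] < x1 * ax)
    )
    patch[sel] = PATCH_ID["hair_macula"]

    # frames and cross sections
    frames = {}
    sections = {}
    for c in canals.values():
        frames[c.name] = {
            "center": c.ampulla_center.copy(),
            "normal": c.ampulla_axis.copy(),
            "utriculopetal": -c.ampulla_axis,
            "plane_normal": c.plane_normal.copy(),
        }
        secs = []
        for dt in (2.0, 3.5):
            t = c.t_amp + dt
            secs.append((c.point(t), c.tangent(t), 2.5 * r_duct))
        sections[c.name] = secs

    # voxel lookup table
    vox = np.argwhere(mask)
    vox_flat = np.ravel_multi_index(vox.T, mask.shape)

    return LabyrinthGeometry(
        mesh=mesh,
        cell_region=region,
        cell_zone=zone,
        boundary_faces=bfaces,
        face_patch=patch,
        side="left",
        crista_frames=frames,
        canal_cross_sections=sections,
        axes=np.eye(3),
        utricle_center=np.zeros(3),
        config=cfg,
        _vox_origin=lo,
        _vox_shape=shape,
        _vox_flat=vox_flat,
        _world_from_body=np.eye(3),
    )


def _transform(geom: LabyrinthGeometry, Q: np.ndarray, side: str) -> LabyrinthGeometry:
    """Apply an orthogonal transform (rotation or reflection) to the geometry."""
    mesh = TetMesh(geom.mesh.vertices @ Q.T, geom.mesh.cells)
    frames = {
        name: {k: Q @ v for k, v in fr.items() if isinstance(v, np.ndarray)}
        for name, fr in geom.crista_frames.items()
    }
    sections = {
        name: [(Q @ p, Q @ n, r) for (p, n, r) in secs]
        for name, secs in geom.canal_cross_sections.items()
    }
    return LabyrinthGeometry(
        mesh=mesh,
        cell_region=geom.cell_region,
        cell_zone=geom.cell_zone,
        boundary_faces=geom.boundary_faces,
        face_patch=geom.face_patch,
        side=side,
        crista_frames=frames,
        canal_cross_sections=sections,
        axes=geom.axes @ Q.T,
        utricle_center=Q @ geom.utricle_center,
        config=geom.config,
        _vox_origin=geom._vox_origin,
        _vox_shape=geom._vox_shape,
        _vox_flat=geom._vox_flat,
        _world_from_body=Q @ geom._world_from_body,
    )


def mirror_labyrinth(geom: LabyrinthGeometry) -> LabyrinthGeometry:
    """Reflect a left labyrinth through the sagittal plane to get the right one."""
    if geom.side != "left":
        raise ValueError("mirror_labyrinth expects a left labyrinth")
    M = np.diag([1.0, -1.0, 1.0])
    return _transform(geom, M, "right")


def orient(
    geom: LabyrinthGeometry,
    head: HeadOrientation,
    B_magnitude: float,
    B_axis_sign: str = "head_to_feet",
):
    """Rotate the labyrinth into the scanner frame and return the B vector.

    The bore axis is the world Z axis.  ``head_to_feet`` (the common 7 T / 3 T
    installation) points B along -Z in the body convention used here;
    ``feet_to_head`` reverses it, which reverses every Lorentz force and hence
    the direction of the evoked nystagmus.
    """
    if B_magnitude < 0:
        raise ValueError("B magnitude must be non-negative")
    if B_axis_sign not in ("head_to_feet", "feet_to_head"):
        raise ValueError(f"unknown B axis sign {B_axis_sign!r}")
    rotated = _transform(geom, head.rotation, geom.side)
    B = np.array([0.0, 0.0, -B_magnitude if B_axis_sign == "head_to_feet" else B_magnitude])
    return rotated, B


# ---------------------------------------------------------------------------
# topology checks used by the generator's own invariants
# ---------------------------------------------------------------------------

def _component_labels(geom: LabyrinthGeometry, keep: np.ndarray) -> np.ndarray:
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse import csr_matrix

    idx = np.flatnonzero(keep)
    remap = -np.ones(geom.mesh.n_cells, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    adj = geom.mesh.cell_adjacency().tocoo()
    sel = keep[adj.row] & keep[adj.col]
    sub = csr_matrix(
        (adj.data[sel], (remap[adj.row[sel]], remap[adj.col[sel]])), shape=(len(idx),) * 2
    )
    _, labels = connected_components(sub, directed=False)
    full = -np.ones(geom.mesh.n_cells, dtype=np.int64)
    full[idx] = labels
    return full


def cupula_separates(geom: LabyrinthGeometry, canal: str) -> bool:
    """True if the cupula seals the direct ampulla-to-utricle passage.

    Each canal is a closed ring, so its ampulla always reaches the utricle
    the long way around the duct.  The sealing property is therefore checked
    by cutting the ring at a cross-section opposite the ampulla: with the
    cupula in place the ampulla must then be disconnected from the utricle;
    with the cupula cells reopened it must reconnect through the cupula gap.
    """
    cfg = geom.config
    canals = _canals(cfg)
    c = canals[canal]
    rid = REGION_ID[f"cupula_{canal}"]

    # body-frame centroids (the ring parametrization lives in the body frame)
    cent = geom.mesh.centroids() @ geom._world_from_body
    t = c.t_of(cent)
    d_ring = c.ring_distance(cent)
    t_cut = c.t_amp + np.pi
    dt = np.arctan2(np.sin(t - t_cut), np.cos(t - t_cut))
    cut = (np.abs(dt) * c.a <= 2.5 * cfg.voxel_mm) & (d_ring <= cfg.ampulla_radius_mm)

    fluid = geom.cell_region == REGION_ID["endolymph"]
    amp_axial = (cent - c.ampulla_center) @ c.ampulla_axis
    amp_seed = (
        fluid
        & (np.linalg.norm(cent - c.ampulla_center, axis=1) < cfg.ampulla_radius_mm)
        & (amp_axial > cfg.cupula_thickness_mm / 2)
    )
    utr_seed = fluid & (
        np.linalg.norm(cent, axis=1) < 0.5 * min(cfg.utricle_semiaxes_mm)
    )
    if not amp_seed.any() or not utr_seed.any():
        return False

    def connected(keep):
        labels = _component_labels(geom, keep)
        la = np.unique(labels[amp_seed & keep])
        lu = np.unique(labels[utr_seed & keep])
        return len(np.intersect1d(la, lu)) > 0

    sealed = not connected(fluid & ~cut)
    reopened = connected((fluid | (geom.cell_region == rid)) & ~cut)
    return sealed and reopened


def cupula_connected(geom: LabyrinthGeometry, canal: str) -> bool:
    """True if the cupula cells form one face-connected component."""
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse import csr_matrix

    rid = REGION_ID[f"cupula_{canal}"]
    idx = np.flatnonzero(geom.cell_region == rid)
    if len(idx) == 0:
        return False
    remap = -np.ones(geom.mesh.n_cells, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    adj = geom.mesh.cell_adjacency().tocoo()
    sel = (remap[adj.row] >= 0) & (remap[adj.col] >= 0)
    sub = csr_matrix(
        (adj.data[sel], (remap[adj.row[sel]], remap[adj.col[sel]])), shape=(len(idx),) * 2
    )
    n, _ = connected_components(sub, directed=False)
    return n == 1
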