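"""Steady Lorentz-forced endolymph flow.

The endolymph Reynolds number at the micrometre-per-second speeds induced by
MRI fields is far below one and the flow settles within a second, so the
momentum balance reduces to steady incompressible Stokes flow with the
Lorentz body force, rigid no-slip walls, and the cupulae treated as sealed
rigid walls for the flow stage (one-way coupling: the resulting transcupular
pressures drive the cupula model).  The solution is exactly linear in the
force, hence in the field strength B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import P1Basis, solve_stokes
from .geometry import CANALS, REGION_ID, ZONE_ID, LabyrinthGeometry
from .mesh import TetMesh, face_areas_normals

__all__ = [
    "FluidParams",
    "FlowSolution",
    "solve_flow",
    "transcupular_pressures",
    "regional_speed_summary",
    "vortex_diagnostics",
    "Vortex",
]

MM = 1e-3


@dataclass(frozen=True)
class FluidParams:
    """Endolymph material constants (SI)."""

    rho: float = 1000.0          # kg/m^3 (enters no steady-state result)
    mu_e: float = 8.15e-4        # Pa s
    c: float = 1500.0            # m/s, speed of sound; documentation only

    def validate(self):
        if self.rho <= 0 or self.mu_e <= 0:
            raise ValueError("fluid density and viscosity must be positive")


@dataclass
class FlowSolution:
    """Velocity/pressure on the endolymph subdomain of one labyrinth."""

    geom: LabyrinthGeometry
    v: np.ndarray                 # (nv, 3) m/s on the full vertex set (0 on walls/cupulae)
    p: np.ndarray                 # (nv,) Pa, zero-mean gauge over the fluid
    params: FluidParams
    fluid_cells: np.ndarray
    fluid_vertex_mask: np.ndarray
    divergence_residual: float
    canal_fluxes: dict = field(default_factory=dict)       # canal -> [m^3/s per section]
    transcupular_dp: dict = field(default_factory=dict)    # canal -> Pa (ampulla - utricle)

    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.v, axis=1)


def _fluid_submesh(geom: LabyrinthGeometry):
    fluid_cells = geom.fluid_cells()
    cells = geom.mesh.cells[fluid_cells]
    used = np.unique(cells)
    remap = -np.ones(geom.mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = TetMesh(geom.mesh.vertices[used], remap[cells])
    return sub, used, remap, fluid_cells


def solve_flow(
    geom: LabyrinthGeometry,
    f_cell,
    params: FluidParams = FluidParams(),
    stab_alpha: float = 0.05,
):
    """Solve steady Stokes flow for one force field or a list of them.

    ``f_cell`` is (nc, 3) N/m^3 on the full cell set (only endolymph cells are
    used) or a list of such arrays sharing one matrix factorization — useful
    for B-field series, where the force fields differ only by scale.
    """
    params.validate()
    single = not isinstance(f_cell, (list, tuple))
    f_list = [f_cell] if single else list(f_cell)

    sub, used, remap, fluid_cells = _fluid_submesh(geom)
    for f in f_list:
        f = np.asarray(f)
        if f.shape[0] != geom.mesh.n_cells or not np.all(np.isfinite(f[fluid_cells])):
            raise ValueError("body force must be finite on every endolymph cell")

    basis = P1Basis(sub)
    bverts = sub.boundary_vertices()

    # mm-coordinate scaling: with vertices in mm the discrete Stokes system
    # reproduces the SI one if the force is multiplied by MM (velocity) and
    # the returned pressure by 1/MM (see unit note in electrodynamics).
    # Derivation: A_mm = mu*L_SI/MM; load_mm = f*vol_SI/MM^3; so u solves
    # (A_SI/MM) u = F_SI/MM^3 * ..., handled by scaling f by MM and p by MM.
    results = []
    sols = solve_stokes(
        basis,
        params.mu_e,
        [np.asarray(f)[fluid_cells] * MM**2 for f in f_list],
        bverts,
        stab_alpha=stab_alpha,
    )
    for v_sub, p_sub in sols:
        v = np.zeros((geom.mesh.n_vertices, 3))
        v[used] = v_sub
        p = np.zeros(geom.mesh.n_vertices)
        p[used] = p_sub / MM
        div = basis.gradient_per_cell(v_sub[:, 0])[:, 0]
        div = div + basis.gradient_per_cell(v_sub[:, 1])[:, 1]
        div = div + basis.gradient_per_cell(v_sub[:, 2])[:, 2]
        vmax = np.abs(v_sub).max()
        div_res = float(
            np.sqrt(np.sum(div**2 * basis.volumes) / basis.volumes.sum())
            / max(vmax / (geom.config.voxel_mm), 1e-300)
        )
        sol = FlowSolution(
            geom=geom,
            v=v,
            p=p,
            params=params,
            fluid_cells=fluid_cells,
            fluid_vertex_mask=np.isin(np.arange(geom.mesh.n_vertices), used),
            divergence_residual=div_res,
        )
        sol.canal_fluxes = _canal_fluxes(sol)
        sol.transcupular_dp = transcupular_pressures(sol)
        results.append(sol)
    return results[0] if single else results


def _canal_fluxes(sol: FlowSolution) -> dict:
    """Volumetric flux (m^3/s) through each stored canal cross-section.

    Uses the interior faces of the fluid mesh cut by the section plane: each
    face crossing the plane contributes v_face . n_plane * projected area.
    """
    geom = sol.geom
    mesh = geom.mesh
    cent = mesh.centroids()
    faces, pairs = mesh.interior_faces()
    fluid = np.zeros(mesh.n_cells, dtype=bool)
    fluid[sol.fluid_cells] = True
    both_fluid = fluid[pairs[:, 0]] & fluid[pairs[:, 1]]
    out = {}
    for canal, secs in geom.canal_cross_sections.items():
        vals = []
        for point, normal, radius in secs:
            d0 = (cent[pairs[:, 0]] - point) @ normal
            d1 = (cent[pairs[:, 1]] - point) @ normal
            fcent = mesh.vertices[faces].mean(axis=1)
            near = np.linalg.norm(fcent - point, axis=1) <= radius
            crossing = both_fluid & near & ((d0 <= 0) & (d1 > 0) | (d0 > 0) & (d1 <= 0))
            if not crossing.any():
                vals.append(0.0)
                continue
            fsel = faces[crossing]
            areas, fnorm = face_areas_normals(mesh.vertices, fsel)
            # orient face normals along the section normal
            sign = np.sign(fnorm @ normal)
            proj = np.abs(fnorm @ normal) * areas * MM**2
            vface = sol.v[fsel].mean(axis=1)
            vals.append(float(np.sum((vface @ normal) * proj)))
            del sign
        out[canal] = vals
    return out


def transcupular_pressures(sol: FlowSolution) -> dict:
    """Pressure drop across each cupula: mean p on the ampullar side minus the
    utricular side of the cupula interface (Pa)."""
    geom = sol.geom
    mesh = geom.mesh
    faces, pairs = mesh.interior_faces()
    region = geom.cell_region
    out = {}
    for canal in CANALS:
        rid = REGION_ID[f"cupula_{canal}"]
        r0 = region[pairs[:, 0]]
        r1 = region[pairs[:, 1]]
        iface = ((r0 == rid) & (r1 == REGION_ID["endolymph"])) | (
            (r1 == rid) & (r0 == REGION_ID["endolymph"])
        )
        if not iface.any():
            out[canal] = 0.0
            continue
        fsel = faces[iface]
        fcent = mesh.vertices[fsel].mean(axis=1)
        fr = geom.crista_frames[canal]
        side = (fcent - fr["center"]) @ fr["utriculopetal"]
        areas, _ = face_areas_normals(mesh.vertices, fsel)
        pface = sol.p[fsel].mean(axis=1)
        amp = side < 0
        utr = side > 0
        if not amp.any() or not utr.any():
            out[canal] = 0.0
            continue
        p_amp = np.sum(pface[amp] * areas[amp]) / areas[amp].sum()
        p_utr = np.sum(pface[utr] * areas[utr]) / areas[utr].sum()
        out[canal] = float(p_amp - p_utr)
    return out


def regional_speed_summary(sol: FlowSolution) -> dict:
    """Maximum endolymph speed (m/s) in the utricle, the ampullae and the
    slender canal ducts.

    Cells in the transition necks where the classes meet are excluded so the
    duct figure reflects the slender ducts proper rather than the utricular
    flow spilling into the openings.
    """
    from .geometry import _canals

    geom = sol.geom
    cfg = geom.config
    canals = _canals(cfg)
    cent = geom.mesh.centroids() @ geom._world_from_body
    ax, ay, az = cfg.utricle_semiaxes_mm
    f_ell = (cent[:, 0] / ax) ** 2 + (cent[:, 1] / ay) ** 2 + (cent[:, 2] / az) ** 2
    d_amp = np.min(
        [np.linalg.norm(cent - c.ampulla_center, axis=1) for c in canals.values()], axis=0
    )
    # slender mid-duct: on a ring, at least 1.2 rad of arc from both the
    # utricular openings (around t = 0) and the ampulla (t = t_amp)
    deep_duct = np.zeros(geom.mesh.n_cells, dtype=bool)
    for c in canals.values():
        t = c.t_of(cent)
        far = (np.abs(t) > 1.2) & (
            np.abs(np.arctan2(np.sin(t - c.t_amp), np.cos(t - c.t_amp))) > 1.2
        )
        deep_duct |= far & (c.ring_distance(cent) <= cfg.duct_radius_mm)
    fluid = geom.cell_region == REGION_ID["endolymph"]
    masks = {
        "utricle": fluid & (f_ell <= 1.0),
        "ampullae": fluid & (f_ell > 1.0) & (d_amp <= cfg.ampulla_radius_mm),
        "ducts": fluid & deep_duct,
    }
    # per-cell speed (vertex mean) keeps shared junction vertices from
    # leaking one class's flow into another
    cell_speed = np.linalg.norm(sol.v[geom.mesh.cells].mean(axis=1), axis=1)
    return {
        name: float(cell_speed[m].max()) if m.any() else 0.0 for name, m in masks.items()
    }


@dataclass
class Vortex:
    center: np.ndarray            # world coordinates (mm)
    circulation_sign: int         # +1 counterclockwise about the plane normal
    peak_speed: float             # m/s, in-plane
    circulation: float            # m^2/s (in-plane, grid-integrated)


def vortex_diagnostics(
    sol: FlowSolution,
    plane_point: np.ndarray | None = None,
    plane_normal: np.ndarray | None = None,
    n_grid: int = 60,
    speed_frac: float = 0.05,
    circ_frac: float = 0.15,
) -> list[Vortex]:
    """Identify in-plane vortices on the utricle mid-plane.

    Velocity is sampled on a regular grid in the plane; contiguous regions of
    same-sign in-plane vorticity (where the flow is faster than
    ``speed_frac`` of the plane maximum) are candidate vortices, kept if
    their circulation exceeds ``circ_frac`` of the strongest one.  Returned
    sorted by peak in-plane speed, strongest first.
    """
    geom = sol.geom
    if plane_point is None:
        plane_point = geom.utricle_center
    if plane_normal is None:
        plane_normal = geom.axes[2]          # superior body axis
    n = np.asarray(plane_normal, float)
    n = n / np.linalg.norm(n)
    # in-plane axes: use the anterior body axis projected into the plane
    a = geom.axes[0] - (geom.axes[0] @ n) * n
    a = a / np.linalg.norm(a)
    b = np.cross(n, a)

    ax, ay, az = geom.config.utricle_semiaxes_mm
    ext = 1.1 * max(ax, ay, az)
    u = np.linspace(-ext, ext, n_grid)
    w = np.linspace(-ext, ext, n_grid)
    U, W = np.meshgrid(u, w, indexing="ij")
    pts = plane_point + U[..., None] * a + W[..., None] * b
    vals, inside = geom.interpolate_vertex_field(sol.v, pts.reshape(-1, 3))
    if not inside.any():
        raise ValueError("utricle mid-plane does not intersect the mesh")
    V = vals.reshape(n_grid, n_grid, 3)
    Ma = inside.reshape(n_grid, n_grid)
    vu = V @ a
    vw = V @ b
    speed = np.hypot(vu, vw)
    vmax = speed[Ma].max() if Ma.any() else 0.0
    if vmax <= 0:
        return []

    du = (u[1] - u[0]) * MM
    # in-plane vorticity d(vw)/du - d(vu)/dw
    omega = np.gradient(vw, du, axis=0) - np.gradient(vu, du, axis=1)
    omega[~Ma] = 0.0

    active = Ma & (speed > speed_frac * vmax)
    from scipy.ndimage import label

    vortices = []
    for sgn in (+1, -1):
        lab, nlab = label(active & (sgn * omega > 0))
        for k in range(1, nlab + 1):
            sel = lab == k
            circ = float(np.abs(omega[sel]).sum() * du * du)
            wgt = np.abs(omega[sel])
            cu = (U[sel] * wgt).sum() / wgt.sum()
            cw = (W[sel] * wgt).sum() / wgt.sum()
            vortices.append(
                Vortex(
                    center=plane_point + cu * a + cw * b,
                    circulation_sign=sgn,
                    peak_speed=float(speed[sel].max()),
                    circulation=circ,
                )
            )
    if not vortices:
        return []
    cmax = max(v.circulation for v in vortices)
    vortices = [v for v in vortices if v.circulation >= circ_frac * cmax]
    vortices.sort(key=lambda v: -v.peak_speed)
    return vortices
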