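"""Quasi-static electrodynamics of the labyrinth.

A static magnetic field does not disturb the standing ionic currents of the
inner ear (the magnetic Reynolds number of endolymph flow is ~1e-13), so the
electric problem decouples: solve the conduction equation
``div(sigma grad phi) = 0`` once, with the sensory hair-cell patches held at
a fixed potential and the secretory dark-cell patches injecting current, then
form the current density ``J = -sigma grad phi`` and the Lorentz body force
``f_l = J x B``.  J is independent of B; f_l is exactly linear in B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import P1Basis, solve_laplace
from .geometry import (
    CANALS,
    DARK_PATCHES,
    HAIR_PATCHES,
    PATCH_ID,
    PATCHES,
    REGION_ID,
    LabyrinthGeometry,
)
from .mesh import face_areas_normals

__all__ = [
    "ReynoldsInputs",
    "magnetic_reynolds",
    "ConductivityMap",
    "BoundaryConditionSet",
    "FieldSolution",
    "solve_potential",
    "current_and_force",
    "patch_current_budget",
    "trace_current_streamlines",
    "Streamline",
]

MM = 1e-3  # geometry lengths are mm; fields are computed in SI


@dataclass(frozen=True)
class ReynoldsInputs:
    """Scales entering the magnetic Reynolds number Re_m = sigma mu0 U L."""

    sigma_e: float = 1.67      # endolymph conductivity, S/m
    mu_0: float = 1.26e-6      # vacuum permeability, H/m
    U: float = 1.0e-4          # characteristic endolymph speed, m/s
    L: float = 1.0e-3          # characteristic utricle length, m

    def validate(self):
        for name in ("sigma_e", "mu_0", "U", "L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def magnetic_reynolds(inputs: ReynoldsInputs = ReynoldsInputs()):
    """Return (Re_m, order of magnitude).

    Re_m gauges how strongly the moving conductive endolymph perturbs the
    imposed field; at ~1e-13 the coupling is one-way and the electrodynamic
    solve is needed only once.
    """
    inputs.validate()
    value = inputs.sigma_e * inputs.mu_0 * inputs.U * inputs.L
    return value, int(np.floor(np.log10(value)))


@dataclass(frozen=True)
class ConductivityMap:
    """Electrical conductivities (S/m) of the two tissue classes."""

    sigma_endolymph: float = 1.67
    sigma_cupula: float = 1.67

    def validate(self):
        if self.sigma_endolymph <= 0 or self.sigma_cupula <= 0:
            raise ValueError("conductivities must be positive")

    def per_cell(self, geom: LabyrinthGeometry) -> np.ndarray:
        sigma = np.full(geom.mesh.n_cells, self.sigma_endolymph)
        sigma[geom.cell_region != REGION_ID["endolymph"]] = self.sigma_cupula
        return sigma


@dataclass(frozen=True)
class BoundaryConditionSet:
    """Electrical boundary data.

    Hair-cell patches (three cristae + macula) are Dirichlet at
    ``hair_potential_v``.  Dark-cell patches drive the circuit: in
    ``neumann_current`` mode a total current ``total_current_a`` enters the
    endolymph with uniform density over all dark patches (i.e. split across
    patches in proportion to area) and returns through the hair cells; in
    ``dirichlet_potential`` mode the dark patches are clamped at
    ``dark_potential_v`` instead.  Everything else is insulating.
    """

    hair_potential_v: float = 0.01
    drive_mode: str = "neumann_current"
    total_current_a: float = 1.0
    dark_potential_v: float = 0.02
    include_macula: bool = True

    def validate(self):
        if self.drive_mode not in ("neumann_current", "dirichlet_potential"):
            raise ValueError(f"unknown drive mode {self.drive_mode!r}")
        if not np.isfinite(self.total_current_a):
            raise ValueError("prescribed dark-cell current must be finite")


@dataclass
class FieldSolution:
    """Electric potential and derived per-cell fields on one labyrinth."""

    geom: LabyrinthGeometry
    phi: np.ndarray                      # (nv,) V
    residual: float
    bc: BoundaryConditionSet
    sigma: ConductivityMap
    E: np.ndarray | None = None          # (nc, 3) V/m
    J: np.ndarray | None = None          # (nc, 3) A/m^2
    f_l: np.ndarray | None = None        # (nc, 3) N/m^3
    B: np.ndarray | None = None          # (3,) T
    _basis: P1Basis = field(default=None, repr=False)

    def scale_drive(self, factor: float) -> None:
        """Rescale the dark-cell drive in place.

        With every hair patch at one common potential, the Dirichlet part of
        the solution is the constant ``hair_potential_v`` and carries no
        current, so phi is affine and J, E, f_l are exactly linear in the
        drive.
        """
        v0 = self.bc.hair_potential_v
        self.phi = v0 + factor * (self.phi - v0)
        for name in ("E", "J", "f_l"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, val * factor)


def _patch_vertex_ids(geom: LabyrinthGeometry, patch_names) -> np.ndarray:
    ids = [PATCH_ID[p] for p in patch_names]
    sel = np.isin(geom.face_patch, ids)
    return np.unique(geom.boundary_faces[sel])


def solve_potential(
    geom: LabyrinthGeometry,
    sigma: ConductivityMap = ConductivityMap(),
    bc: BoundaryConditionSet = BoundaryConditionSet(),
    basis: P1Basis | None = None,
) -> FieldSolution:
    """Solve the conduction problem for the electric potential."""
    sigma.validate()
    bc.validate()
    basis = basis or P1Basis(geom.mesh)

    hair = list(HAIR_PATCHES if bc.include_macula else [p for p in HAIR_PATCHES if p != "hair_macula"])
    dir_idx = _patch_vertex_ids(geom, hair)
    dir_vals = np.full(len(dir_idx), bc.hair_potential_v)

    dark_sel = np.isin(geom.face_patch, [PATCH_ID[p] for p in DARK_PATCHES])
    dark_faces = geom.boundary_faces[dark_sel]

    if bc.drive_mode == "dirichlet_potential":
        dk_idx = np.setdiff1d(np.unique(dark_faces), dir_idx)
        dir_idx = np.concatenate([dir_idx, dk_idx])
        dir_vals = np.concatenate([dir_vals, np.full(len(dk_idx), bc.dark_potential_v)])
        neu_faces, neu_flux = None, None
    else:
        areas, _ = face_areas_normals(geom.mesh.vertices, dark_faces)
        total_area = areas.sum() * MM**2
        density = bc.total_current_a / total_area          # A/m^2, uniform
        neu_faces = dark_faces
        # assembly runs on the mm-coordinate mesh: scale the flux so the
        # resulting equation matches SI (see note below)
        neu_flux = np.full(len(dark_faces), density)

    # Unit note: with vertices in mm, the P1 stiffness sigma*vol*grad.grad has
    # units S*mm, and a face load j*area has A/m^2*mm^2.  Multiplying the
    # Neumann load by 1/MM makes the discrete system identical to the SI one,
    # so phi comes out in volts.
    phi, res = solve_laplace(
        basis,
        sigma.per_cell(geom),
        dir_idx,
        dir_vals,
        neu_faces,
        None if neu_flux is None else neu_flux * MM,
    )
    return FieldSolution(geom=geom, phi=phi, residual=res, bc=bc, sigma=sigma, _basis=basis)


def current_and_force(sol: FieldSolution, B: np.ndarray) -> FieldSolution:
    """Fill E = -grad phi, J = sigma E and f_l = J x B (per cell, SI units)."""
    basis = sol._basis or P1Basis(sol.geom.mesh)
    sol._basis = basis
    grad = basis.gradient_per_cell(sol.phi) / MM          # V/m
    sol.E = -grad
    sol.J = sol.sigma.per_cell(sol.geom)[:, None] * sol.E
    sol.B = np.asarray(B, float)
    sol.f_l = np.cross(sol.J, sol.B)
    return sol


def patch_current_budget(sol: FieldSolution) -> dict:
    """Signed boundary current (A) through every patch; positive = into the domain.

    Computed from the discrete residual of the unconstrained stiffness system,
    which is the consistent boundary flux of the FE solution; the total over
    all patches vanishes up to solver tolerance (discrete current
    conservation).
    """
    geom = sol.geom
    basis = sol._basis or P1Basis(geom.mesh)
    A = basis.stiffness(sol.sigma.per_cell(geom))
    # the mm-coordinate stiffness is A_SI / MM, so scale back to amperes
    r = (A @ sol.phi) * MM

    # distribute vertex fluxes to patches by face membership (vertex areas)
    budget = {}
    areas, _ = face_areas_normals(geom.mesh.vertices, geom.boundary_faces)
    vert_patch_w = {}
    for pid, name in enumerate(PATCHES):
        sel = geom.face_patch == pid
        if not sel.any():
            continue
        w = np.zeros(geom.mesh.n_vertices)
        np.add.at(w, geom.boundary_faces[sel].reshape(-1), np.repeat(areas[sel] / 3, 3))
        vert_patch_w[name] = w
    totw = sum(vert_patch_w.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        for name, w in vert_patch_w.items():
            frac = np.where(totw > 0, w / np.maximum(totw, 1e-300), 0.0)
            budget[name] = float(np.sum(r * frac))
    return budget


@dataclass
class Streamline:
    points: np.ndarray
    origin_patch: str
    terminal_patch: str        # patch name or "truncated"


def trace_current_streamlines(
    sol: FieldSolution,
    n_seeds: int = 200,
    seed: int = 0,
    step_frac: float = 0.4,
    max_steps: int = 6000,
) -> list[Streamline]:
    """Integrate streamlines of J from dark-cell seed points.

    The direction field is the per-cell J.  At insulating walls the continuum
    current is tangential; discretely a cell's J may point slightly into the
    wall, so a step that would leave the mesh through a wall is projected
    back to the nearest interior before giving up.  Streamlines terminate
    when they exit near a boundary face, and are labeled with that face's
    patch; ones exceeding ``max_steps`` are labeled "truncated".
    """
    geom = sol.geom
    if sol.J is None:
        raise ValueError("current density not computed; call current_and_force first")
    rng = np.random.default_rng(seed)

    dark_sel = np.isin(geom.face_patch, [PATCH_ID[p] for p in DARK_PATCHES])
    dark_idx = np.flatnonzero(dark_sel)
    if len(dark_idx) == 0:
        return []
    areas, normals = face_areas_normals(geom.mesh.vertices, geom.boundary_faces)
    p_area = areas[dark_idx] / areas[dark_idx].sum()
    chosen = rng.choice(dark_idx, size=n_seeds, replace=True, p=p_area)

    jmax = np.linalg.norm(sol.J, axis=1).max()
    if jmax == 0:
        return []

    h = geom.config.voxel_mm
    step = step_frac * h

    # terminal patch lookup: nearest boundary face centroid (KD-tree)
    from scipy.spatial import cKDTree

    fc = geom.mesh.vertices[geom.boundary_faces].mean(axis=1)
    tree = cKDTree(fc)
    _, bowners = geom.mesh.boundary_faces()

    centroids = geom.mesh.centroids()

    def exit_patch(p):
        """Patch at an exit point: the nearest boundary face, preferring a
        sensory/secretory patch over `wall` within a small staircase margin
        (insulating walls cannot sink current in the continuum)."""
        dists, idxs = tree.query(p, k=min(24, len(fc)))
        idxs = np.atleast_1d(idxs)
        dists = np.atleast_1d(dists)
        best = PATCHES[geom.face_patch[idxs[0]]]
        if best != "wall":
            return best
        near = idxs[dists <= max(dists[0] + h, 1.5 * h)]
        for f in near:
            name = PATCHES[geom.face_patch[f]]
            if name != "wall":
                return name
        return "wall"

    out = []
    for fidx in chosen:
        # seed at the centroid of the owning cell of a dark face
        owner = bowners[fidx]
        p = centroids[owner].copy()
        origin = PATCHES[geom.face_patch[fidx]]
        pts = [p.copy()]
        terminal = "truncated"
        for _ in range(max_steps):
            cid = geom.locate_points(p[None, :])[0]
            if cid < 0:
                terminal = exit_patch(p)
                break
            j = sol.J[cid]
            nrm = np.linalg.norm(j)
            if nrm < 1e-9 * jmax:
                # zero-gradient pocket: next to a Dirichlet patch this is the
                # destination; in the interior the field is genuinely null
                d, _ = tree.query(p)
                terminal = exit_patch(p) if d <= 1.5 * h else "stagnant"
                break
            q = p + step * j / nrm
            if geom.locate_points(q[None, :])[0] < 0:
                name = exit_patch(q)
                if not name.startswith("hair_"):
                    # exits are only physical at the Dirichlet (hair) patches;
                    # slide tangentially along the staircase boundary, trying
                    # single-face and corner (two-face) projections at a few
                    # step scales
                    _, nfs = tree.query(q, k=2)
                    _, fn = face_areas_normals(
                        geom.mesh.vertices, geom.boundary_faces[np.atleast_1d(nfs)]
                    )
                    jdir = j / nrm
                    cands = []
                    d1 = jdir - (jdir @ fn[0]) * fn[0]
                    cands.append(d1)
                    if len(fn) > 1:
                        d2 = d1 - (d1 @ fn[1]) * fn[1]
                        cands.append(d2)
                    moved = False
                    for d in cands:
                        dn = np.linalg.norm(d)
                        if dn < 1e-9:
                            continue
                        for scale in (1.0, 0.5, 0.25):
                            q2 = p + scale * step * d / dn
                            if geom.locate_points(q2[None, :])[0] >= 0:
                                p = q2
                                pts.append(p.copy())
                                moved = True
                                break
                        if moved:
                            break
                    if moved:
                        continue
                terminal = name
                pts.append(q.copy())
                break
            p = q
            pts.append(p.copy())
        out.append(Streamline(np.array(pts), origin, terminal))
    return out
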