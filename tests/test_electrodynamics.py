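"""Electrodynamics: dimensionless diagnostic, Laplace oracles, J/force fields."""

import numpy as np
import pytest

from mvstim.electrodynamics import (
    BoundaryConditionSet,
    ConductivityMap,
    FieldSolution,
    ReynoldsInputs,
    current_and_force,
    magnetic_reynolds,
    patch_current_budget,
    solve_potential,
    trace_current_streamlines,
)
from mvstim.fem import P1Basis, solve_laplace
from mvstim.geometry import (
    HeadOrientation,
    LabyrinthConfig,
    LabyrinthGeometry,
    PATCH_ID,
    mirror_labyrinth,
    orient,
)
from mvstim.mesh import box_mesh, spherical_shell_mesh, voxel_mesh


@pytest.fixture(scope="module")
def supine_fields(left_geom):
    geom, B = orient(left_geom, HeadOrientation(), 7.0, "head_to_feet")
    sol = solve_potential(geom)
    return current_and_force(sol, B)


# -- magnetic Reynolds number ---------------------------------------------------

def test_magnetic_reynolds_default_scales():
    value, order = magnetic_reynolds()
    assert order == -13
    assert np.isclose(value, 1.67 * 1.26e-6 * 1e-4 * 1e-3, rtol=1e-12)


def test_magnetic_reynolds_rejects_nonpositive():
    with pytest.raises(ValueError):
        magnetic_reynolds(ReynoldsInputs(U=0.0))


def test_magnetic_reynolds_homogeneity():
    base, _ = magnetic_reynolds()
    scaled, _ = magnetic_reynolds(
        ReynoldsInputs(sigma_e=16.7, mu_0=1.26e-5, U=1e-3, L=1e-2)
    )
    assert np.isclose(scaled / base, 1e4, rtol=1e-12)


# -- Laplace solver oracles -------------------------------------------------------

def test_parallel_plate_linear_potential():
    m = box_mesh((1.0, 1.0, 1.0), (6, 6, 6))
    basis = P1Basis(m)
    z = m.vertices[:, 2]
    lo = np.flatnonzero(z < 1e-12)
    hi = np.flatnonzero(z > 1 - 1e-12)
    idx = np.concatenate([lo, hi])
    vals = np.concatenate([np.zeros(len(lo)), np.full(len(hi), 0.5)])
    phi, res = solve_laplace(basis, np.ones(m.n_cells), idx, vals)
    exact = 0.5 * z
    rel = np.linalg.norm(phi - exact) / np.linalg.norm(exact)
    assert rel < 1e-8
    assert res < 1e-8


def _shell_error(n):
    m = spherical_shell_mesh(1.0, 2.0, n, n)
    basis = P1Basis(m)
    r = np.linalg.norm(m.vertices, axis=1)
    inner = np.flatnonzero(r < 1 + 1e-9)
    outer = np.flatnonzero(r > 2 - 1e-9)
    idx = np.concatenate([inner, outer])
    vals = np.concatenate([np.ones(len(inner)), np.zeros(len(outer))])
    phi, _ = solve_laplace(basis, np.ones(m.n_cells), idx, vals)
    exact = 2.0 / r - 1.0
    return np.sqrt(np.mean((phi - exact) ** 2)) / np.sqrt(np.mean(exact**2))


def test_concentric_sphere_solution_and_convergence():
    e_coarse = _shell_error(6)
    e_fine = _shell_error(12)
    assert e_coarse < 0.02
    assert e_fine < e_coarse / 2.5     # ~second-order in L2


def test_missing_dirichlet_patch_raises():
    m = box_mesh((1.0, 1.0, 1.0), (3, 3, 3))
    with pytest.raises(ValueError, match="Dirichlet|hair"):
        solve_laplace(P1Basis(m), np.ones(m.n_cells), np.array([], dtype=int), np.array([]))


# -- labyrinth conduction ---------------------------------------------------------

def test_uniform_dirichlet_gives_constant_potential(left_geom):
    bc = BoundaryConditionSet(drive_mode="dirichlet_potential", dark_potential_v=0.01)
    sol = solve_potential(left_geom, bc=bc)
    assert np.allclose(sol.phi, 0.01, atol=1e-12)


def test_global_current_conservation(supine_fields):
    budget = patch_current_budget(supine_fields)
    total = sum(budget.values())
    influx = sum(v for v in budget.values() if v > 0)
    assert abs(total) < 1e-8 * influx
    # drive enters through dark patches and returns through hair patches
    assert all(budget[p] > 0 for p in budget if p.startswith("dark_"))


def test_current_density_independent_of_B(left_geom):
    geom, B7 = orient(left_geom, HeadOrientation(), 7.0, "head_to_feet")
    sol7 = current_and_force(solve_potential(geom), B7)
    sol15 = current_and_force(solve_potential(geom), B7 * (1.5 / 7.0))
    assert np.array_equal(sol7.J, sol15.J)
    assert np.allclose(sol15.f_l, sol7.f_l * (1.5 / 7.0), rtol=1e-12, atol=0)


def test_force_orthogonal_to_J_and_B(supine_fields):
    sol = supine_fields
    scale = np.linalg.norm(sol.f_l, axis=1) * np.linalg.norm(sol.J, axis=1) + 1e-300
    assert (np.abs(np.einsum("ij,ij->i", sol.f_l, sol.J)) / scale).max() < 1e-10
    scale_b = np.linalg.norm(sol.f_l, axis=1) * np.linalg.norm(sol.B) + 1e-300
    assert (np.abs(sol.f_l @ sol.B) / scale_b).max() < 1e-10


def test_field_reversal_negates_force(left_geom):
    geom, B = orient(left_geom, HeadOrientation(), 7.0, "head_to_feet")
    sol = solve_potential(geom)
    f_fwd = current_and_force(sol, B).f_l.copy()
    f_rev = current_and_force(sol, -B).f_l
    assert np.array_equal(f_rev, -f_fwd)


def test_supine_force_points_toward_left_ear(supine_fields, left_geom):
    """Anterior-directed utricular currents crossed with a head-to-feet field
    push the endolymph toward the left ear (+Y) in the utricle core."""
    from mvstim.geometry import ZONE_ID

    geom = supine_fields.geom
    core = geom.cell_zone == ZONE_ID["utricle"]
    mean_f = supine_fields.f_l[core].mean(axis=0)
    assert mean_f[1] > 0
    assert abs(mean_f[1]) > abs(mean_f[0])


def test_mirror_equivariance_of_potential(left_geom):
    """Solving on the mirrored labyrinth gives the reflected potential, and in
    the supine field both labyrinths are pushed toward the same ear."""
    head = HeadOrientation()
    gl, B = orient(left_geom, head, 7.0, "head_to_feet")
    gr, _ = orient(mirror_labyrinth(left_geom), head, 7.0, "head_to_feet")
    sl = current_and_force(solve_potential(gl), B)
    sr = current_and_force(solve_potential(gr), B)
    # vertex sets correspond 1:1 under the reflection (same ordering)
    assert np.allclose(sr.phi, sl.phi, rtol=1e-8, atol=1e-12)
    from mvstim.geometry import ZONE_ID

    core = gl.cell_zone == ZONE_ID["utricle"]
    assert sl.f_l[core].mean(axis=0)[1] > 0
    assert sr.f_l[core].mean(axis=0)[1] > 0


def test_uniform_current_cross_product_example():
    """J along +X with B head-to-feet (-Z) yields a +Y (leftward) force."""
    J = np.array([[2.0, 0.0, 0.0]])
    B = np.array([0.0, 0.0, -3.0])
    f = np.cross(J, B)
    assert np.allclose(f, [[0.0, 6.0, 0.0]])


# -- streamlines ------------------------------------------------------------------

def _slab_geometry(n=6):
    """A box 'labyrinth' with a dark floor and a hair ceiling for the tracer."""
    mask = np.ones((n, n, n), dtype=bool)
    mesh, _ = voxel_mesh(mask, (0.0, 0.0, 0.0), 1.0)
    bfaces, _ = mesh.boundary_faces()
    from mvstim.mesh import face_areas_normals

    fc = mesh.vertices[bfaces].mean(axis=1)
    _, normals = face_areas_normals(mesh.vertices, bfaces)
    patch = np.zeros(len(bfaces), dtype=np.int8)
    patch[normals[:, 2] < -0.5] = PATCH_ID["dark_utricle"]
    patch[normals[:, 2] > 0.5] = PATCH_ID["hair_macula"]
    vox = np.argwhere(mask)
    return LabyrinthGeometry(
        mesh=mesh,
        cell_region=np.zeros(mesh.n_cells, dtype=np.int8),
        cell_zone=np.zeros(mesh.n_cells, dtype=np.int8),
        boundary_faces=bfaces,
        face_patch=patch,
        side="left",
        crista_frames={},
        canal_cross_sections={},
        axes=np.eye(3),
        utricle_center=np.full(3, n / 2),
        config=LabyrinthConfig(voxel_mm=1.0),
        _vox_origin=np.zeros(3),
        _vox_shape=mask.shape,
        _vox_flat=np.ravel_multi_index(vox.T, mask.shape),
        _world_from_body=np.eye(3),
    )


def _uniform_solution(geom, j_vec):
    sol = FieldSolution(
        geom=geom,
        phi=np.zeros(geom.mesh.n_vertices),
        residual=0.0,
        bc=BoundaryConditionSet(),
        sigma=ConductivityMap(),
    )
    sol.J = np.tile(np.asarray(j_vec, float), (geom.mesh.n_cells, 1))
    sol.E = sol.J / 1.67
    sol.B = np.zeros(3)
    sol.f_l = np.zeros_like(sol.J)
    return sol


def test_streamlines_uniform_field_all_reach_sink():
    geom = _slab_geometry()
    sol = _uniform_solution(geom, (0.0, 0.0, 1.0))
    lines = trace_current_streamlines(sol, n_seeds=40, seed=0)
    assert len(lines) == 40
    assert all(l.origin_patch == "dark_utricle" for l in lines)
    assert all(l.terminal_patch == "hair_macula" for l in lines)


def test_streamlines_zero_drive_reports_none():
    geom = _slab_geometry()
    sol = _uniform_solution(geom, (0.0, 0.0, 0.0))
    assert trace_current_streamlines(sol, n_seeds=10, seed=0) == []


def test_streamlines_labyrinth_terminate_on_hair_patches(supine_fields):
    lines = trace_current_streamlines(supine_fields, n_seeds=120, seed=3)
    done = [l for l in lines if l.terminal_patch not in ("truncated", "stagnant")]
    assert len(done) >= 0.8 * len(lines)
    frac_hair = np.mean([l.terminal_patch.startswith("hair_") for l in done])
    assert frac_hair >= 0.9


def test_streamlines_reproducible(supine_fields):
    a = trace_current_streamlines(supine_fields, n_seeds=15, seed=7)
    b = trace_current_streamlines(supine_fields, n_seeds=15, seed=7)
    assert [l.terminal_patch for l in a] == [l.terminal_patch for l in b]
    assert all(np.array_equal(x.points, y.points) for x, y in zip(a, b))
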