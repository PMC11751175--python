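"""Shared closed-form solver oracles used by the unit and acceptance suites."""

import numpy as np

from mvstim.fem import P1Basis, solve_laplace, solve_stokes
from mvstim.mesh import box_mesh, cylinder_mesh, spherical_shell_mesh


def parallel_plate_error() -> float:
    """Relative L2 error of the conduction solve against a linear potential."""
    m = box_mesh((1.0, 1.0, 1.0), (6, 6, 6))
    basis = P1Basis(m)
    z = m.vertices[:, 2]
    lo = np.flatnonzero(z < 1e-12)
    hi = np.flatnonzero(z > 1 - 1e-12)
    idx = np.concatenate([lo, hi])
    vals = np.concatenate([np.zeros(len(lo)), np.ones(len(hi))])
    phi, _ = solve_laplace(basis, np.ones(m.n_cells), idx, vals)
    return float(np.linalg.norm(phi - z) / np.linalg.norm(z))


def shell_error(n: int) -> float:
    """Relative L2 error against the concentric-sphere solution a + b/r."""
    m = spherical_shell_mesh(1.0, 2.0, n, n)
    basis = P1Basis(m)
    r = np.linalg.norm(m.vertices, axis=1)
    inner = np.flatnonzero(r < 1 + 1e-9)
    outer = np.flatnonzero(r > 2 - 1e-9)
    idx = np.concatenate([inner, outer])
    vals = np.concatenate([np.ones(len(inner)), np.zeros(len(outer))])
    phi, _ = solve_laplace(basis, np.ones(m.n_cells), idx, vals)
    exact = 2.0 / r - 1.0
    return float(np.sqrt(np.mean((phi - exact) ** 2)) / np.sqrt(np.mean(exact**2)))


def poiseuille_error(n_rings: int, n_layers: int) -> float:
    """Relative centerline-speed error against Poiseuille flow in a tube."""
    R, L, mu, g = 1.0, 4.0, 1.0, 1.0
    mesh = cylinder_mesh(R, L, n_rings, n_layers)
    basis = P1Basis(mesh)
    rr = np.linalg.norm(mesh.vertices[:, :2], axis=1)
    zz = mesh.vertices[:, 2]
    bv = mesh.boundary_vertices()
    wall = bv[rr[bv] > R - 1e-9]
    caps = np.setdiff1d(bv, wall)
    d_idx = np.concatenate([wall, caps])
    free = np.zeros((len(d_idx), 3), dtype=bool)
    free[len(wall):, 2] = True
    f = np.zeros((mesh.n_cells, 3))
    f[:, 2] = g
    v, _ = solve_stokes(basis, mu, f, d_idx, free_components=free)
    center = np.flatnonzero((rr < 1e-9) & (np.abs(zz - L / 2) < L / (2 * n_layers)))
    exact = g * R**2 / (4 * mu)
    return float(abs(v[center, 2].mean() - exact) / exact)
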