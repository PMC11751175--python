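"""First-order finite elements on tetrahedra.

Two solvers back the physics modules:

* :func:`solve_laplace` — conduction / Laplace problems div(sigma grad phi)=0
  with Dirichlet vertex values and Neumann surface flux, used for the
  quasi-static electric potential.
* :func:`solve_stokes` — steady incompressible Stokes flow with a per-cell
  body force, equal-order P1-P1 velocity/pressure with Brezzi-Pitkaranta
  pressure stabilization, no-slip (or prescribed) velocity Dirichlet data.

Both use deterministic sparse direct solves so repeated runs are bit-stable.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix, bmat, eye as speye
from scipy.sparse.linalg import spsolve

from .mesh import TetMesh, face_areas_normals

__all__ = ["P1Basis", "solve_laplace", "solve_stokes"]


class P1Basis:
    """Per-cell P1 shape-function gradients and volumes."""

    def __init__(self, mesh: TetMesh):
        self.mesh = mesh
        verts = mesh.vertices
        cells = mesh.cells
        a = verts[cells[:, 1]] - verts[cells[:, 0]]
        b = verts[cells[:, 2]] - verts[cells[:, 0]]
        c = verts[cells[:, 3]] - verts[cells[:, 0]]
        T = np.stack([a, b, c], axis=1)                 # (nc,3,3) rows are edges
        self.volumes = np.abs(np.linalg.det(T)) / 6.0
        Tinv = np.linalg.inv(T)                          # columns: grads of lam1..3
        g123 = np.transpose(Tinv, (0, 2, 1))             # (nc,3,3): grad lam_i rows
        g0 = -g123.sum(axis=1, keepdims=True)
        self.grads = np.concatenate([g0, g123], axis=1)  # (nc,4,3)

    def stiffness(self, coeff: np.ndarray) -> csr_matrix:
        """Assemble sum_K coeff_K vol_K grad_i . grad_j."""
        mesh = self.mesh
        ke = np.einsum("k,kid,kjd->kij", coeff * self.volumes, self.grads, self.grads)
        rows = np.repeat(mesh.cells, 4, axis=1).reshape(-1)
        cols = np.tile(mesh.cells, (1, 4)).reshape(-1)
        A = coo_matrix((ke.reshape(-1), (rows, cols)), shape=(mesh.n_vertices,) * 2)
        return A.tocsr()

    def gradient_per_cell(self, u: np.ndarray) -> np.ndarray:
        """Piecewise-constant gradient of a vertex field."""
        return np.einsum("kid,ki->kd", self.grads, u[self.mesh.cells])

    def load_per_vertex(self, f_cell: np.ndarray) -> np.ndarray:
        """RHS of int f v for per-cell scalar f (lumped over the 4 vertices)."""
        mesh = self.mesh
        out = np.zeros(mesh.n_vertices)
        w = f_cell * self.volumes / 4.0
        np.add.at(out, mesh.cells.reshape(-1), np.repeat(w, 4))
        return out


def _apply_dirichlet(A: csr_matrix, b: np.ndarray, idx: np.ndarray, vals: np.ndarray):
    """Eliminate Dirichlet DOFs symmetrically; returns reduced system + maps."""
    n = A.shape[0]
    keep = np.setdiff1d(np.arange(n), idx)
    x0 = np.zeros(n)
    x0[idx] = vals
    b_red = (b - A @ x0)[keep]
    A_red = A[keep][:, keep]
    return A_red, b_red, keep, x0


def solve_laplace(
    basis: P1Basis,
    sigma_cell: np.ndarray,
    dirichlet_idx: np.ndarray,
    dirichlet_vals: np.ndarray,
    neumann_faces: np.ndarray | None = None,
    neumann_flux: np.ndarray | None = None,
):
    """Solve div(sigma grad phi) = 0 with mixed boundary data.

    ``neumann_faces`` are boundary triangles (vertex triples) carrying an
    inward normal current density ``neumann_flux`` (A/m^2 per face, positive
    = injected into the domain).  Returns (phi, residual_norm).
    """
    mesh = basis.mesh
    if len(dirichlet_idx) == 0:
        raise ValueError(
            "ill-posed conduction problem: no Dirichlet patch fixes the potential "
            "(at least one hair-cell patch must prescribe a potential)"
        )
    A = basis.stiffness(sigma_cell)
    b = np.zeros(mesh.n_vertices)
    if neumann_faces is not None and len(neumann_faces):
        areas, _ = face_areas_normals(mesh.vertices, neumann_faces)
        w = neumann_flux * areas / 3.0
        np.add.at(b, neumann_faces.reshape(-1), np.repeat(w, 3))

    A_red, b_red, keep, x0 = _apply_dirichlet(A, b, dirichlet_idx, dirichlet_vals)
    phi = x0
    phi[keep] = spsolve(A_red.tocsc(), b_red)
    res = np.linalg.norm(A_red @ phi[keep] - b_red)
    scale = max(np.linalg.norm(b_red), np.linalg.norm(A_red @ phi[keep]), 1e-300)
    return phi, float(res / scale)


def solve_stokes(
    basis: P1Basis,
    mu: float,
    f_cells,
    velocity_dirichlet_idx: np.ndarray,
    velocity_dirichlet_vals: np.ndarray | None = None,
    free_components: np.ndarray | None = None,
    stab_alpha: float = 0.05,
):
    """Steady Stokes flow: -grad p + mu lap v + f = 0, div v = 0.

    Equal-order P1-P1 with Brezzi-Pitkaranta stabilization
    ``alpha * h_K^2 / mu * (grad p, grad q)``.  ``f_cells`` is one (nc, 3)
    body-force array or a list of them (sharing one factorization).
    ``velocity_dirichlet_idx`` are vertex ids whose velocity is prescribed
    (default zero).  ``free_components`` is an optional (n_dirichlet, 3)
    boolean mask: True marks components left free at those vertices (used to
    impose symmetry conditions such as u_x = u_y = 0, u_z free).

    Returns list of (v, p) matching the list of forces (or a single pair).
    """
    mesh = basis.mesh
    nv = mesh.n_vertices

    single = not isinstance(f_cells, (list, tuple))
    f_list = [f_cells] if single else list(f_cells)

    A1 = basis.stiffness(np.full(mesh.n_cells, mu))

    # divergence: B[p_i, (comp k, vertex a)] = int lam_i d(lam_a)/dx_k
    vol4 = basis.volumes / 4.0
    rows = np.repeat(mesh.cells, 4, axis=1).reshape(-1)      # pressure vertex i
    cols = np.tile(mesh.cells, (1, 4)).reshape(-1)           # velocity vertex a
    B_blocks = []
    for k in range(3):
        w = np.repeat(vol4, 16) * np.tile(basis.grads[:, :, k], (1, 4)).reshape(-1)
        B_blocks.append(coo_matrix((w, (rows, cols)), shape=(nv, nv)).tocsr())

    # stabilization: alpha * h^2 / mu * stiffness-like matrix
    h2 = basis.volumes ** (2.0 / 3.0) * 6 ** (2.0 / 3.0)
    C = basis.stiffness(stab_alpha * h2 / mu)

    # Dirichlet DOF bookkeeping in the 3nv velocity space (component-major)
    d_idx = np.asarray(velocity_dirichlet_idx, dtype=np.int64)
    if velocity_dirichlet_vals is None:
        d_vals = np.zeros((len(d_idx), 3))
    else:
        d_vals = np.asarray(velocity_dirichlet_vals, dtype=float)
    if free_components is None:
        free = np.zeros((len(d_idx), 3), dtype=bool)
    else:
        free = np.asarray(free_components, dtype=bool)

    fixed_dofs = []
    fixed_vals = []
    for k in range(3):
        sel = ~free[:, k]
        fixed_dofs.append(k * nv + d_idx[sel])
        fixed_vals.append(d_vals[sel, k])
    fixed_dofs = np.concatenate(fixed_dofs)
    fixed_vals = np.concatenate(fixed_vals)

    from scipy.sparse import block_diag

    A = block_diag([A1, A1, A1], format="csr")
    B = bmat([[B_blocks[0], B_blocks[1], B_blocks[2]]], format="csr")  # (nv, 3nv)

    keep_u = np.setdiff1d(np.arange(3 * nv), fixed_dofs)
    u0 = np.zeros(3 * nv)
    u0[fixed_dofs] = fixed_vals

    A_red = A[keep_u][:, keep_u]
    B_red = B[:, keep_u]

    # pin one pressure DOF to remove the constant-pressure null space
    pin = 0
    Cp = C.tolil()
    Bp = B_red.tolil()
    Cp[pin, :] = 0.0
    Cp[pin, pin] = 1.0
    Bp[pin, :] = 0.0
    C_fix = Cp.tocsr()
    B_fix = Bp.tocsr()

    K = bmat([[A_red, B_fix.T], [B_fix, -C_fix]], format="csc")
    from scipy.sparse.linalg import splu

    lu = splu(K, permc_spec="COLAMD")

    results = []
    vols = basis.volumes
    lumped = np.zeros(nv)
    np.add.at(lumped, mesh.cells.reshape(-1), np.repeat(vols / 4.0, 4))
    for f in f_list:
        f = np.asarray(f, dtype=float)
        F = np.concatenate([basis.load_per_vertex(f[:, k]) for k in range(3)])
        rhs_u = F[keep_u] - (A[keep_u][:, fixed_dofs] @ fixed_vals if len(fixed_dofs) else 0.0)
        rhs_p = -(B[:, fixed_dofs] @ fixed_vals) if len(fixed_dofs) else np.zeros(nv)
        rhs_p[pin] = 0.0
        sol = lu.solve(np.concatenate([rhs_u, rhs_p]))
        u = u0.copy()
        u[keep_u] = sol[: len(keep_u)]
        # the symmetric form solves for the negated pressure
        p = -sol[len(keep_u):]
        p = p - np.sum(p * lumped) / lumped.sum()        # zero-mean gauge
        v = u.reshape(3, nv).T
        results.append((v, p))
    return results[0] if single else results
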