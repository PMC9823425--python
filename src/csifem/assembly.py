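"""Element integrals and global assembly of the vector wave equation.

The discrete problem posed on Whitney (lowest-order Nedelec) elements is

    ([U] - [V] - [A]) [E_t] = [rhs_t]

with the stiffness matrix ``U_ij = \\int (curl N_i).(curl N_j)``, the mass
matrix ``V_ij = \\int kb^2 N_i.N_j`` (``kb^2`` constant per cell, sampled at
the barycenter) and a first-order absorbing boundary term
``A_ij = j kb \\oint (n x N_i).(n x N_j) dS`` on the outer surface.

All element integrals are evaluated in closed form: the curl of a Whitney
function is constant per cell and products of barycentric coordinates
integrate to ``V/10`` (equal indices) or ``V/20`` (distinct) over a
tetrahedron, and to ``A/6`` / ``A/12`` over a triangle.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .mesh import TetMesh

__all__ = [
    "stiffness_elements",
    "mass_elements",
    "edge_average_elements",
    "assemble_stiffness",
    "assemble_mass",
    "assemble_abc",
    "dipole_rhs",
    "SystemMatrices",
]


def _gather_pair(arr, x, y):
    """arr[(cell, x[cell,i], y[cell,j])] -> (I, 6, 6)."""
    return np.take_along_axis(
        np.take_along_axis(arr, x[:, :, None], axis=1), y[:, None, :], axis=2
    )


def stiffness_elements(mesh: TetMesh):
    """Per-cell 6x6 curl-curl blocks, closed form.

    ``curl N_(a,b) = 2 grad(lambda_a) x grad(lambda_b)`` is constant, so the
    block is ``4 V (g_a x g_b).(g_c x g_d)`` and has rank 3 (six edge curls
    span the 3-dimensional space of constant vectors).
    """
    a, b = mesh.edge_lo_local, mesh.edge_hi_local
    g = mesh.grads
    ga = np.take_along_axis(g, a[..., None], axis=1)
    gb = np.take_along_axis(g, b[..., None], axis=1)
    cr = np.cross(ga, gb)  # (I, 6, 3)
    return 4.0 * mesh.volumes[:, None, None] * np.einsum("iak,ibk->iab", cr, cr)


def mass_elements(mesh: TetMesh):
    """Per-cell 6x6 blocks of ``\\int N_i . N_j`` (unit coefficient)."""
    a, b = mesh.edge_lo_local, mesh.edge_hi_local
    I = mesh.n_tets
    S = np.full((I, 4, 4), 1.0 / 20.0)
    S[:, range(4), range(4)] = 1.0 / 10.0
    S *= mesh.volumes[:, None, None]
    gdot = np.einsum("iak,ibk->iab", mesh.grads, mesh.grads)
    return (
        _gather_pair(gdot, b, b) * _gather_pair(S, a, a)
        - _gather_pair(gdot, b, a) * _gather_pair(S, a, b)
        - _gather_pair(gdot, a, b) * _gather_pair(S, b, a)
        + _gather_pair(gdot, a, a) * _gather_pair(S, b, b)
    )


def edge_average_elements(mesh: TetMesh):
    """Per-cell integrals ``\\int_Ci N_e dV = (V/4)(g_b - g_a)`` as (I, 6, 3)."""
    a, b = mesh.edge_lo_local, mesh.edge_hi_local
    g = mesh.grads
    ga = np.take_along_axis(g, a[..., None], axis=1)
    gb = np.take_along_axis(g, b[..., None], axis=1)
    return 0.25 * mesh.volumes[:, None, None] * (gb - ga)


def _scatter(mesh, blocks):
    rows = np.repeat(mesh.tet_edges, 6, axis=1).ravel()
    cols = np.tile(mesh.tet_edges, (1, 6)).ravel()
    E = mesh.n_edges
    return sp.coo_matrix((blocks.ravel(), (rows, cols)), shape=(E, E)).tocsc()


def assemble_stiffness(mesh: TetMesh):
    """Global sparse stiffness matrix ``U`` (real, symmetric)."""
    return _scatter(mesh, stiffness_elements(mesh))


def assemble_mass(mesh: TetMesh, kb2):
    """Global sparse mass matrix ``V`` with per-cell coefficient ``kb2``.

    Parameters
    ----------
    kb2 : scalar or (I,) complex array
        Squared background wavenumber per cell.
    """
    kb2 = np.asarray(kb2, dtype=complex)
    if kb2.ndim == 0:
        kb2 = np.full(mesh.n_tets, kb2)
    if len(kb2) != mesh.n_tets:
        raise ValueError("kb2 must have one value per tetrahedron")
    blocks = kb2[:, None, None] * mass_elements(mesh)
    return _scatter(mesh, blocks)


def _face_edge_ids(mesh, faces):
    """Global edge indices of each boundary face's 3 edges (lo-hi pairs)."""
    E = mesh.edges
    key = E[:, 0] * mesh.n_nodes + E[:, 1]
    order = np.argsort(key)
    pairs = np.stack(
        [faces[:, [0, 1]], faces[:, [0, 2]], faces[:, [1, 2]]], axis=1
    )  # (F, 3, 2) already lo < hi because faces are sorted triples
    fk = pairs[..., 0] * mesh.n_nodes + pairs[..., 1]
    pos = order[np.searchsorted(key[order], fk)]
    return pos


def assemble_abc(mesh: TetMesh, kb_boundary):
    """First-order absorbing boundary term on the outer surface.

    ``A_ij = j kb \\oint (n x N_i).(n x N_j) dS``.  Only the three edges of
    each boundary triangle carry a tangential trace, which coincides with
    the two-dimensional Whitney function built from the in-plane gradients
    of the face barycentric coordinates.
    """
    if not mesh.boundary_is_closed():
        raise ValueError("boundary surface is not closed")
    b = mesh.boundary
    faces, areas = b["faces"], b["areas"]
    p = mesh.nodes[faces]  # (F, 3, 3)
    t1 = p[:, 1] - p[:, 0]
    t2 = p[:, 2] - p[:, 0]
    g11 = (t1 * t1).sum(1)
    g12 = (t1 * t2).sum(1)
    g22 = (t2 * t2).sum(1)
    det = g11 * g22 - g12 * g12
    gs1 = (g22[:, None] * t1 - g12[:, None] * t2) / det[:, None]
    gs2 = (g11[:, None] * t2 - g12[:, None] * t1) / det[:, None]
    gs0 = -gs1 - gs2
    gs = np.stack([gs0, gs1, gs2], axis=1)  # (F, 3, 3) surface gradients
    # face-local edges: (0,1), (0,2), (1,2) in face-vertex numbering
    fe = np.array([[0, 1], [0, 2], [1, 2]])
    a, bb = fe[:, 0], fe[:, 1]
    gdot = np.einsum("fak,fbk->fab", gs, gs)
    S = np.full((len(faces), 3, 3), 1.0 / 12.0)
    S[:, range(3), range(3)] = 1.0 / 6.0
    S *= areas[:, None, None]
    ax = np.broadcast_to(a, (len(faces), 3))
    bx = np.broadcast_to(bb, (len(faces), 3))
    blocks = (
        _gather_pair(gdot, bx, bx) * _gather_pair(S, ax, ax)
        - _gather_pair(gdot, bx, ax) * _gather_pair(S, ax, bx)
        - _gather_pair(gdot, ax, bx) * _gather_pair(S, bx, ax)
        + _gather_pair(gdot, ax, ax) * _gather_pair(S, bx, bx)
    )
    eid = _face_edge_ids(mesh, faces)  # (F, 3)
    rows = np.repeat(eid, 3, axis=1).ravel()
    cols = np.tile(eid, (1, 3)).ravel()
    E = mesh.n_edges
    A = sp.coo_matrix((blocks.ravel(), (rows, cols)), shape=(E, E)).tocsc()
    return 1j * complex(kb_boundary) * A


def dipole_rhs(mesh: TetMesh, position, moment, omega=None, mu0=None):
    """Right-hand side of an elementary electric dipole.

    Galerkin testing of a point current source ``J = Il p_hat delta(r-r0)``
    gives ``rhs_e = -j omega mu0 Il N_e(r0).p_hat``; when ``omega`` is not
    given the prefactor is taken as 1 (the scale is irrelevant to every
    relative quantity in the pipeline).
    """
    moment = np.asarray(moment, dtype=float)
    tets, lam = mesh.locate(np.atleast_2d(position))
    t = int(tets[0])
    rhs = np.zeros(mesh.n_edges, dtype=complex)
    scale = 1.0 if omega is None else -1j * omega * mu0
    for le in range(6):
        a = mesh.edge_lo_local[t, le]
        b = mesh.edge_hi_local[t, le]
        g = mesh.grads[t]
        N = lam[0][a] * g[b] - lam[0][b] * g[a]
        rhs[mesh.tet_edges[t, le]] += scale * (N @ moment)
    return rhs


class SystemMatrices:
    """Assembled FEM operators and a reusable solver for ``U - V - A``.

    The system matrix is independent of the contrast, so one factorization
    (or preconditioner) serves every transmitter and every inversion
    iteration.

    Parameters
    ----------
    mesh : TetMesh
    kb2 : (I,) complex
        Per-cell squared wavenumber entering the mass matrix.
    kb_boundary : complex
        Wavenumber of the (background) medium at the outer boundary.
    solver : {"auto", "direct", "fft"}
        ``direct`` uses a sparse LU; ``fft`` the structured-grid
        preconditioned GMRES (structured meshes only); ``auto`` picks
        ``fft`` for structured meshes above ~40k edges.
    tol : float
        Relative-residual target of :meth:`solve`.
    """

    def __init__(self, mesh, kb2, kb_boundary, solver="auto", tol=1e-12,
                 solver_opts=None):
        self.mesh = mesh
        self.solver_opts = dict(solver_opts or {})
        self.kb2 = np.asarray(kb2, dtype=complex)
        self.U = assemble_stiffness(mesh).astype(complex)
        self.V = assemble_mass(mesh, self.kb2)
        self.A_abc = assemble_abc(mesh, kb_boundary)
        self.K = (self.U - self.V - self.A_abc).tocsc()
        self.tol = float(tol)
        if solver == "auto":
            solver = (
                "fft"
                if mesh.structured is not None and mesh.n_edges > 40_000
                else "direct"
            )
        self.solver_kind = solver
        self._solver = None

    @property
    def solver(self):
        if self._solver is None:
            from .solvers import DirectSolver, StructuredFFTSolver

            if self.solver_kind == "direct":
                self._solver = DirectSolver(self.K)
            elif self.solver_kind == "fft":
                self._solver = StructuredFFTSolver(
                    self.K, self.mesh, self.kb2, rtol=self.tol,
                    **self.solver_opts
                )
            else:
                raise ValueError(f"unknown solver kind {self.solver_kind!r}")
        return self._solver

    def solve(self, rhs, adjoint=False, x0=None):
        """Solve ``K x = rhs`` (or ``K^H x = rhs``) to the configured
        relative residual; raises ``RuntimeError`` on a singular system.
        ``x0`` seeds the iterative solver (ignored by the direct one)."""
        rhs = np.asarray(rhs, dtype=complex)
        if not np.linalg.norm(rhs):
            return np.zeros_like(rhs)
        return self.solver.solve(rhs, adjoint=adjoint, x0=x0)
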