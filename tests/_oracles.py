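"""Independent numerical oracles used to validate closed-form integrals.

Everything here evaluates integrals by quadrature and basis functions
point-wise from their definition, deliberately avoiding the closed-form
element routines under test.
"""

import numpy as np

# Keast degree-3, 5-point tetrahedron rule (exact for cubic polynomials;
# the integrands under test are at most quadratic)
_TET_BARY = np.array(
    [
        [0.25, 0.25, 0.25, 0.25],
        [0.5, 1 / 6, 1 / 6, 1 / 6],
        [1 / 6, 0.5, 1 / 6, 1 / 6],
        [1 / 6, 1 / 6, 0.5, 1 / 6],
        [1 / 6, 1 / 6, 1 / 6, 0.5],
    ]
)
_TET_W = np.array([-0.8, 0.45, 0.45, 0.45, 0.45])

# degree-2 midside triangle rule (exact for quadratics)
_TRI_BARY = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]])
_TRI_W = np.array([1 / 3, 1 / 3, 1 / 3])


def whitney_point(mesh, tet, point):
    """All six Whitney functions of one tet at a point, from the definition
    ``N = lambda_a grad(lambda_b) - lambda_b grad(lambda_a)`` with the
    barycentric coordinates computed by solving the 4x4 vertex system."""
    verts = mesh.nodes[mesh.tets[tet]]
    M = np.hstack([np.ones((4, 1)), verts])
    coef = np.linalg.inv(M)  # lambda_i(r) = coef[0,i] + coef[1:,i].r
    lam = coef.T @ np.concatenate([[1.0], point])
    grads = coef[1:, :].T
    out = np.empty((6, 3))
    for le in range(6):
        a = mesh.edge_lo_local[tet, le]
        b = mesh.edge_hi_local[tet, le]
        out[le] = lam[a] * grads[b] - lam[b] * grads[a]
    return out


def tet_quadrature_matrix(mesh, tet, pair_fn):
    """``sum_q w_q V f(N(x_q))`` for a 6x6 integrand ``pair_fn(N) -> 6x6``."""
    verts = mesh.nodes[mesh.tets[tet]]
    V = mesh.volumes[tet]
    out = np.zeros((6, 6))
    for lam, w in zip(_TET_BARY, _TET_W):
        p = lam @ verts
        out += w * V * pair_fn(whitney_point(mesh, tet, p))
    return out


def mass_block_quadrature(mesh, tet):
    """Oracle for the cell block of ``\\int N_i . N_j dV``."""
    return tet_quadrature_matrix(mesh, tet, lambda N: N @ N.T)


def stiffness_block_quadrature(mesh, tet):
    """Oracle for the curl-curl block via central finite-difference curls
    evaluated at the quadrature points (the curl is constant per cell)."""
    verts = mesh.nodes[mesh.tets[tet]]
    V = mesh.volumes[tet]
    center = verts.mean(axis=0)
    eps = 1e-6 * np.cbrt(V)

    def curl(le):
        c = np.zeros(3)
        for k in range(3):
            for l in range(3):
                for m in range(3):
                    sign = {(0, 1, 2): 1, (1, 2, 0): 1, (2, 0, 1): 1,
                            (0, 2, 1): -1, (2, 1, 0): -1, (1, 0, 2): -1}.get(
                                (k, l, m), 0)
                    if sign == 0:
                        continue
                    dp = np.zeros(3)
                    dp[l] = eps
                    fp = whitney_point(mesh, tet, center + dp)[le, m]
                    fm = whitney_point(mesh, tet, center - dp)[le, m]
                    c[k] += sign * (fp - fm) / (2 * eps)
        return c

    curls = np.array([curl(le) for le in range(6)])
    return V * curls @ curls.T


def edge_average_quadrature(mesh, tet):
    """Oracle for ``\\int_C N_e dV`` as a (6, 3) array."""
    verts = mesh.nodes[mesh.tets[tet]]
    V = mesh.volumes[tet]
    out = np.zeros((6, 3))
    for lam, w in zip(_TET_BARY, _TET_W):
        p = lam @ verts
        out += w * V * whitney_point(mesh, tet, p)
    return out


def boundary_face_block_quadrature(mesh, face_idx):
    """Oracle for ``\\oint (n x N_i).(n x N_j) dS`` on one boundary face.

    Evaluates the 3-D Whitney functions of the owner tet at face
    quadrature points and removes the normal component explicitly.
    Returns the 3x3 block and the global edge ids of the face edges.
    """
    b = mesh.boundary
    fc = b["faces"][face_idx]
    t = int(b["owner_tets"][face_idx])
    n = b["normals"][face_idx]
    verts = mesh.nodes[fc]
    area = 0.5 * np.linalg.norm(np.cross(verts[1] - verts[0], verts[2] - verts[0]))
    les = [
        le for le in range(6)
        if set(mesh.edges[mesh.tet_edges[t, le]]) <= set(fc)
    ]
    assert len(les) == 3
    block = np.zeros((3, 3))
    for lam, w in zip(_TRI_BARY, _TRI_W):
        p = lam @ verts
        N = whitney_point(mesh, t, p)[les]
        Nt = N - np.outer(N @ n, n)
        block += w * area * (Nt @ Nt.T)
    edge_ids = [mesh.tet_edges[t, le] for le in les]
    return block, edge_ids


def random_tet_mesh(rng, scale=1.0):
    """A single well-shaped random tetrahedron as a TetMesh."""
    from csifem.mesh import TetMesh

    while True:
        nodes = scale * rng.standard_normal((4, 3))
        vol = abs(np.linalg.det(nodes[1:] - nodes[0]) / 6.0)
        edge = max(np.linalg.norm(nodes[i] - nodes[j])
                   for i in range(4) for j in range(i + 1, 4))
        if vol > 1e-3 * edge**3:  # avoid slivers
            return TetMesh(nodes, [[0, 1, 2, 3]])
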