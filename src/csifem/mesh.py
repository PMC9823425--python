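"""Tetrahedral meshes with global edge enumeration for curl-conforming FEM.

The mesh is the geometric backbone of the solver: every field is expanded
on lowest-order Whitney (edge) elements, so besides nodes and cells the
mesh carries a global edge table, the per-tetrahedron local-to-global edge
map, and the edge-to-cell incidence used by the edge-basis contrast-source
representation.

Orientation convention: every edge is stored (and every Whitney function
defined) with the lower global node index first.  Because neighbouring
tetrahedra then agree on the edge direction by construction, no per-cell
orientation signs other than +1 ever arise; the ``tet_edge_signs`` array is
kept for interface completeness.
"""

from __future__ import annotations

import hashlib

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["TetMesh", "build_box_mesh"]

# local vertex pairs defining the 6 edges of a tetrahedron
_LOCAL_EDGES = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


class TetMesh:
    """Conforming tetrahedral mesh with edge tables.

    Parameters
    ----------
    nodes : (N, 3) float array
        Vertex positions in metres.
    tets : (I, 4) int array
        Vertex indices of each tetrahedron.  Cells with negative signed
        volume are reordered on construction so that all volumes are
        positive.
    structured : tuple, optional
        ``(origin, h, ncells)`` metadata when the mesh is a structured
        box grid; enables O(1) point location and the structured fast
        solver.

    Attributes
    ----------
    edges : (E, 2) int array
        Unique global edges, lower node index first.
    tet_edges : (I, 6) int array
        Global edge index of each local edge.
    tet_edge_signs : (I, 6) int array
        Orientation signs (all +1 under the global convention).
    volumes, barycenters, grads
        Signed volumes (all positive), cell barycenters ``r_i`` and the
        constant gradients of the four barycentric coordinates per cell.
    """

    def __init__(self, nodes, tets, structured=None):
        self.nodes = np.ascontiguousarray(nodes, dtype=float)
        tets = np.ascontiguousarray(tets, dtype=np.int64)
        vol = _signed_volumes(self.nodes, tets)
        neg = vol < 0
        if neg.any():
            tets = tets.copy()
            tets[neg] = tets[neg][:, [1, 0, 2, 3]]
            vol = _signed_volumes(self.nodes, tets)
        if (vol <= 0).any():
            bad = int(np.argmin(vol))
            raise ValueError(f"degenerate tetrahedron {bad}: volume {vol[bad]:.3e}")
        self.tets = tets
        self.volumes = vol
        self.barycenters = self.nodes[tets].mean(axis=1)
        self.structured = structured

        # barycentric gradients: lambda_i(r) = 1/4 + grads[i] . (r - barycenter)
        p = self.nodes[tets]
        M = np.concatenate([np.ones((len(tets), 4, 1)), p], axis=2)
        self.grads = np.linalg.inv(M)[:, 1:4, :].transpose(0, 2, 1)

        self._enumerate_edges()
        self._boundary = None
        self._kdtree = None

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    def _enumerate_edges(self):
        tets = self.tets
        pairs = np.stack(
            [np.sort(tets[:, lp], axis=1) for lp in _LOCAL_EDGES], axis=1
        )  # (I, 6, 2) sorted by global node id
        edges, inv = np.unique(pairs.reshape(-1, 2), axis=0, return_inverse=True)
        self.edges = edges
        self.tet_edges = inv.reshape(-1, 6)
        self.tet_edge_signs = np.ones_like(self.tet_edges, dtype=np.int8)

        # local vertex index of the lower/upper node of each local edge
        I = len(tets)
        a_loc = np.empty((I, 6), dtype=np.int64)
        b_loc = np.empty((I, 6), dtype=np.int64)
        for le, (i, j) in enumerate(_LOCAL_EDGES):
            swap = tets[:, i] > tets[:, j]
            a_loc[:, le] = np.where(swap, j, i)
            b_loc[:, le] = np.where(swap, i, j)
        self.edge_lo_local = a_loc
        self.edge_hi_local = b_loc

        # incidence alpha(e, q): CSR over edges -> (tet, local edge)
        order = np.argsort(self.tet_edges.ravel(), kind="stable")
        self._inc_tet = order // 6
        self._inc_local = order % 6
        counts = np.bincount(self.tet_edges.ravel(), minlength=len(edges))
        self._inc_ptr = np.concatenate([[0], np.cumsum(counts)])

    # ------------------------------------------------------------------
    # basic properties
    # ------------------------------------------------------------------
    @property
    def n_nodes(self):
        return len(self.nodes)

    @property
    def n_tets(self):
        return len(self.tets)

    @property
    def n_edges(self):
        return len(self.edges)

    def edge_multiplicity(self):
        """Number of tetrahedra sharing each edge (``Q_e``)."""
        return np.diff(self._inc_ptr)

    def incidence(self, edge):
        """Tetrahedra sharing ``edge`` as ``(tet_indices, local_edge_indices)``.

        This is the map ``alpha(e, q)`` for ``q = 1..Q_e``.
        """
        s, e = self._inc_ptr[edge], self._inc_ptr[edge + 1]
        return self._inc_tet[s:e], self._inc_local[s:e]

    def edge_midpoints(self):
        return 0.5 * (self.nodes[self.edges[:, 0]] + self.nodes[self.edges[:, 1]])

    def edge_vectors(self):
        """Vector from the lower- to the higher-index node of each edge."""
        return self.nodes[self.edges[:, 1]] - self.nodes[self.edges[:, 0]]

    # ------------------------------------------------------------------
    # boundary
    # ------------------------------------------------------------------
    @property
    def boundary(self):
        """Boundary triangulation as a dict with faces, normals, owner tets.

        Faces are node triples sorted by global index; normals point out of
        the domain.  Computed lazily and cached.
        """
        if self._boundary is None:
            self._boundary = self._extract_boundary()
        return self._boundary

    def _extract_boundary(self):
        # face f of tet = the 3 vertices excluding local vertex f
        opp = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
        faces = np.concatenate([self.tets[:, o] for o in opp], axis=0)
        owner = np.tile(np.arange(self.n_tets), 4)
        opp_vertex = np.repeat(np.arange(4), self.n_tets)
        key = np.sort(faces, axis=1)
        uniq, inv, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        on_bdry = counts[inv] == 1
        faces = key[on_bdry]
        owner = owner[on_bdry]
        opp_vertex = opp_vertex[on_bdry]
        # outward normal: opposite to the gradient of the excluded vertex's
        # barycentric function (which points into the cell)
        g = self.grads[owner, opp_vertex]
        normals = -g / np.linalg.norm(g, axis=1, keepdims=True)
        p = self.nodes[faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )
        return {
            "faces": faces,
            "owner_tets": owner,
            "normals": normals,
            "areas": areas,
        }

    def boundary_is_closed(self, tol=1e-9):
        """Check the divergence-theorem identity: sum of area-weighted
        outward normals of a closed surface vanishes."""
        b = self.boundary
        s = (b["normals"] * b["areas"][:, None]).sum(axis=0)
        return np.linalg.norm(s) <= tol * b["areas"].sum()

    # ------------------------------------------------------------------
    # point location and field evaluation
    # ------------------------------------------------------------------
    def barycentric(self, tet, points):
        """Barycentric coordinates of ``points`` (n, 3) within ``tet``."""
        points = np.atleast_2d(points)
        d = points - self.barycenters[tet]
        return 0.25 + d @ self.grads[tet].T

    def locate(self, points, tol=1e-10):
        """Find the tetrahedron containing each point.

        Returns ``(tet_indices, barycentric)``; raises ``ValueError`` for
        points outside the mesh.
        """
        points = np.atleast_2d(np.asarray(points, float))
        out = np.full(len(points), -1, dtype=np.int64)
        lam = np.zeros((len(points), 4))
        if self.structured is not None:
            origin, h, nc = self.structured
            cell = np.floor((points - origin) / h).astype(np.int64)
            cell = np.clip(cell, 0, np.asarray(nc) - 1)
            flat = (cell[:, 0] * nc[1] + cell[:, 1]) * nc[2] + cell[:, 2]
            nhex = int(np.prod(nc))
            for k in range(len(points)):
                # the 6 tets of hex `flat[k]` are at flat[k] + j*nhex
                for t in flat[k] + nhex * np.arange(6):
                    l = self.barycentric(int(t), points[k])[0]
                    if l.min() >= -tol:
                        out[k], lam[k] = t, l
                        break
        else:
            if self._kdtree is None:
                self._kdtree = cKDTree(self.barycenters)
            k_near = min(64, self.n_tets)
            _, cand = self._kdtree.query(points, k=k_near)
            cand = np.atleast_2d(cand)
            for k in range(len(points)):
                for t in cand[k]:
                    l = self.barycentric(int(t), points[k])[0]
                    if l.min() >= -tol:
                        out[k], lam[k] = t, l
                        break
        if (out < 0).any():
            bad = points[out < 0][0]
            raise ValueError(f"point {bad} is outside the mesh")
        return out, lam

    def eval_whitney(self, tet, local_edge, point):
        """Evaluate the Whitney edge function ``N_e`` of one local edge.

        The function is ``lambda_a grad(lambda_b) - lambda_b grad(lambda_a)``
        with ``a``/``b`` the lower/higher global node of the edge; its
        tangential line integral along its own edge is 1 and vanishes along
        the other five edges.
        """
        lam = self.barycentric(tet, point)[0]
        if lam.min() < -1e-9:
            raise ValueError("point outside tetrahedron")
        a = self.edge_lo_local[tet, local_edge]
        b = self.edge_hi_local[tet, local_edge]
        g = self.grads[tet]
        return lam[a] * g[b] - lam[b] * g[a]

    def eval_field(self, coeffs, points, tets=None, lam=None):
        """Evaluate an edge-element field ``sum_e c_e N_e`` at points.

        Parameters
        ----------
        coeffs : (E,) array
            Edge coefficients.
        points : (n, 3) array
        tets, lam : optional
            Precomputed point location (from :meth:`locate`).
        """
        points = np.atleast_2d(points)
        if tets is None:
            tets, lam = self.locate(points)
        vals = np.zeros((len(points), 3), dtype=np.result_type(coeffs, float))
        a = self.edge_lo_local[tets]       # (n, 6)
        b = self.edge_hi_local[tets]
        g = self.grads[tets]               # (n, 4, 3)
        ga = np.take_along_axis(g, a[..., None], axis=1)
        gb = np.take_along_axis(g, b[..., None], axis=1)
        la = np.take_along_axis(lam, a, axis=1)[..., None]
        lb = np.take_along_axis(lam, b, axis=1)[..., None]
        N = la * gb - lb * ga              # (n, 6, 3)
        c = coeffs[self.tet_edges[tets]]   # (n, 6)
        vals = (c[..., None] * N).sum(axis=1)
        return vals

    # ------------------------------------------------------------------
    def content_hash(self):
        """SHA-256 over node and cell arrays, for provenance records."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.nodes).tobytes())
        h.update(np.ascontiguousarray(self.tets).tobytes())
        return h.hexdigest()

    def __repr__(self):
        return (
            f"TetMesh(nodes={self.n_nodes}, tets={self.n_tets}, "
            f"edges={self.n_edges}, structured={self.structured is not None})"
        )


def _signed_volumes(nodes, tets):
    p = nodes[tets]
    return (
        np.linalg.det(
            np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=1)
        )
        / 6.0
    )


def build_box_mesh(extent, h, origin=(0.0, 0.0, 0.0)):
    """Structured tetrahedral mesh of a box.

    Each hexahedral cell of a uniform grid is split into six tetrahedra
    around the main diagonal (Kuhn/Freudenthal subdivision) with the same
    diagonal direction in every cell, which makes the mesh conforming.
    The construction is fully deterministic.

    Parameters
    ----------
    extent : length-3 sequence
        Box dimensions in metres.
    h : float
        Target edge length; the grid uses ``round(extent/h)`` cells per
        axis (at least 1).
    origin : length-3 sequence, optional
        Position of the box corner.

    Returns
    -------
    TetMesh
    """
    extent = np.asarray(extent, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if (extent <= 0).any():
        raise ValueError("extent components must be positive")
    if h <= 0 or h > extent.min():
        raise ValueError("h must satisfy 0 < h <= min(extent)")
    nc = np.maximum(np.round(extent / h).astype(int), 1)
    nx, ny, nz = (int(v) for v in nc)
    xs = [origin[i] + np.linspace(0.0, extent[i], nc[i] + 1) for i in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    corner = {}
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                corner[(di, dj, dk)] = nid(I + di, J + dj, K + dk).ravel()
    # six tetrahedra along the 000 -> 111 diagonal; the vertex pair in each
    # entry walks the six lateral paths of the cube
    paths = [
        ((1, 0, 0), (1, 1, 0)),
        ((1, 1, 0), (0, 1, 0)),
        ((0, 1, 0), (0, 1, 1)),
        ((0, 1, 1), (0, 0, 1)),
        ((0, 0, 1), (1, 0, 1)),
        ((1, 0, 1), (1, 0, 0)),
    ]
    tets = np.concatenate(
        [
            np.stack(
                [corner[(0, 0, 0)], corner[p1], corner[p2], corner[(1, 1, 1)]],
                axis=1,
            )
            for p1, p2 in paths
        ],
        axis=0,
    )
    spacing = extent / nc
    if not np.allclose(spacing, spacing[0], rtol=1e-9):
        structured = None
    else:
        structured = (origin, float(spacing[0]), tuple(int(v) for v in nc))
    return TetMesh(nodes, tets, structured=structured)
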