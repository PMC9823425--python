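"""Contrast, contrast-source representations and the G_S / G_D operators.

Two discretizations of the contrast source are supported.

* ``standard``: one *vector* coefficient per cell,
  ``w_t,i = chi(r_i) E_t(r_i)``, paired with the E x I vector coupling
  matrix ``R_vec[m, i] = \\int_Ci kb^2 N_m dV`` (a 3-vector per entry).

* ``edge`` (the novel scheme): 6I *scalar* coefficients on the cell-
  restricted Whitney basis ``N_e p_i``; the coupling matrix
  ``R[m, (i,le)] = \\int_Ci kb^2 N_m . N_le dV`` is an ordinary scalar
  sparse matrix, and when the coefficients are built from exact
  ``(chi, E_tot)`` the identity ``R w = (V_target - V_background) E_tot``
  holds to machine precision (because ``kb^2 chi = k^2 - kb^2`` cell-wise).
  Its ``barycenter`` evaluation mode freezes the basis at the cell
  barycenter, which reproduces the standard scheme inside the scalar
  machinery and is the comparison mode used by the inversion.

Slot layout: edge-basis coefficient arrays are flat ``(6I,)`` vectors
ordered ``cell-major`` (slot ``6 i + le``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .assembly import edge_average_elements, mass_elements
from .materials import MaterialMap
from .mesh import TetMesh

__all__ = [
    "Contrast",
    "contrast_from_materials",
    "doi_sphere",
    "doi_halfspace",
    "assemble_coupling",
    "omega_from_exact",
    "CSIOperators",
]


@dataclass
class Contrast:
    """Cell-wise dielectric contrast restricted to a domain of interest."""

    chi: np.ndarray       # (I,) complex, zero outside the DoI
    doi_mask: np.ndarray  # (I,) bool

    def __post_init__(self):
        self.chi = np.where(self.doi_mask, self.chi, 0.0).astype(complex)

    @property
    def n_cells(self):
        return len(self.chi)


def contrast_from_materials(materials: MaterialMap, doi_mask):
    """``chi_i = (eps_target_i - eps_b_i) / eps_b_i`` inside the DoI."""
    doi_mask = np.asarray(doi_mask, bool)
    if (materials.eps_b[doi_mask] == 0).any():
        raise ValueError("background permittivity vanishes inside the DoI")
    chi = np.zeros(materials.n_cells, complex)
    chi[doi_mask] = (
        materials.eps_target[doi_mask] - materials.eps_b[doi_mask]
    ) / materials.eps_b[doi_mask]
    return Contrast(chi, doi_mask)


def doi_sphere(mesh: TetMesh, center, radius):
    """Cells whose barycenter lies in a sphere."""
    return np.linalg.norm(mesh.barycenters - np.asarray(center), axis=1) <= radius


def doi_halfspace(mesh: TetMesh, point, normal, base_mask=None):
    """Restrict a mask to the half-space ``(r - point) . normal >= 0``."""
    m = (mesh.barycenters - np.asarray(point)) @ np.asarray(normal, float) >= 0
    return m if base_mask is None else (m & base_mask)


def _whitney_at_barycenter(mesh):
    """``N_le(r_i) = (g_b - g_a)/4`` for the six local edges, (I, 6, 3)."""
    g = mesh.grads
    ga = np.take_along_axis(g, mesh.edge_lo_local[..., None], axis=1)
    gb = np.take_along_axis(g, mesh.edge_hi_local[..., None], axis=1)
    return 0.25 * (gb - ga)


def assemble_coupling(mesh: TetMesh, kb2, variant="edge", eval_mode="linear",
                      doi_mask=None):
    """Coupling matrix between contrast-source coefficients and the RHS.

    Parameters
    ----------
    kb2 : (I,) complex
        Background squared wavenumber per cell.
    variant : {"edge", "standard"}
        Scalar edge-basis (E x 6I) or vector per-cell (E x 3I) matrix.
    eval_mode : {"linear", "barycenter"}
        Edge variant only: integrate the cell-restricted basis exactly,
        or freeze it at the cell barycenter (the standard-equivalent
        comparison mode).
    doi_mask : (I,) bool, optional
        Zero all columns of cells outside the DoI.
    """
    kb2 = np.asarray(kb2, complex)
    I = mesh.n_tets
    w = kb2.copy()
    if doi_mask is not None:
        w = np.where(np.asarray(doi_mask, bool), w, 0.0)
    if variant == "edge":
        if eval_mode == "linear":
            blocks = w[:, None, None] * mass_elements(mesh)  # (I, 6m, 6n)
        elif eval_mode == "barycenter":
            avg = w[:, None, None] * edge_average_elements(mesh)  # (I, 6, 3)
            nbar = _whitney_at_barycenter(mesh)
            blocks = np.einsum("imk,ink->imn", avg, nbar)
        else:
            raise ValueError(f"unknown eval_mode {eval_mode!r}")
        rows = np.repeat(mesh.tet_edges, 6, axis=1).ravel()
        cols = np.broadcast_to(
            6 * np.arange(I)[:, None, None] + np.arange(6)[None, None, :],
            (I, 6, 6),
        ).ravel()
        return sp.coo_matrix(
            (blocks.ravel(), (rows, cols)), shape=(mesh.n_edges, 6 * I)
        ).tocsr()
    if variant == "standard":
        avg = w[:, None, None] * edge_average_elements(mesh)  # (I, 6, 3)
        rows = np.repeat(mesh.tet_edges, 3, axis=1).ravel()
        cols = np.broadcast_to(
            3 * np.arange(I)[:, None, None] + np.arange(3)[None, None, :],
            (I, 6, 3),
        ).ravel()
        return sp.coo_matrix(
            (avg.ravel(), (rows, cols)), shape=(mesh.n_edges, 3 * I)
        ).tocsr()
    raise ValueError(f"unknown variant {variant!r}")


def omega_from_exact(contrast: Contrast, etot, mesh: TetMesh, variant="edge"):
    """Exact contrast-source coefficients from ``(chi, E_tot)``.

    ``edge``: slot ``(i, le)`` takes ``E_tot_edge * chi_i``.
    ``standard``: cell vector ``chi_i E_tot(r_i)`` with the field summed
    from the six Whitney functions at the barycenter.
    """
    etot = np.asarray(etot, complex)
    if contrast.n_cells != mesh.n_tets:
        raise ValueError("contrast and mesh cell counts differ")
    if variant == "edge":
        return (contrast.chi[:, None] * etot[mesh.tet_edges]).ravel()
    if variant == "standard":
        nbar = _whitney_at_barycenter(mesh)  # (I, 6, 3)
        Ebar = np.einsum("ik,ikj->ij", etot[mesh.tet_edges], nbar)
        return (contrast.chi[:, None] * Ebar).ravel()
    raise ValueError(f"unknown variant {variant!r}")


class CSIOperators:
    """The discrete ``G_D`` and ``G_S`` operators of one inversion setup.

    ``G_D`` maps contrast-source coefficients to scattered-field edge
    coefficients by solving the (background) wave equation with the
    coupling matrix on the right-hand side; ``G_S`` composes it with the
    acquisition's measurement functional.  Both are linear; the adjoint
    of ``G_S`` is available for gradients and backpropagation.

    Parameters
    ----------
    system : SystemMatrices
        Background-system factorization (contrast independent; reused
        across transmitters and iterations).
    msense : (T, E) sparse
        Measurement operator of the acquisition.
    mesh, kb2, doi_mask
        Geometry, background coefficient and DoI restriction used to
        assemble the coupling matrix.
    """

    def __init__(self, system, msense, mesh, kb2, doi_mask,
                 variant="edge", eval_mode="linear"):
        self.system = system
        self.msense = msense.tocsr()
        self.mesh = mesh
        self.doi_mask = np.asarray(doi_mask, bool)
        self.variant = variant
        self.eval_mode = eval_mode
        self.R = assemble_coupling(
            mesh, kb2, variant=variant, eval_mode=eval_mode, doi_mask=doi_mask
        )
        self._Rh = self.R.conj().T.tocsr()
        self._Mh = self.msense.conj().T.tocsr()
        self.slot_mask = np.repeat(self.doi_mask, 6)

    # -- broadcast between edge space and cell-slot space ----------------
    def slots_from_edges(self, edge_array):
        """Restrict an edge field to the DoI slots (the operator ``B``)."""
        s = np.asarray(edge_array)[self.mesh.tet_edges].ravel()
        return np.where(self.slot_mask, s, 0.0)

    def edges_from_slots(self, slots):
        """Adjoint of :meth:`slots_from_edges` (sum slots per edge)."""
        out = np.zeros(self.mesh.n_edges, complex)
        np.add.at(out, self.mesh.tet_edges.ravel(),
                  np.where(self.slot_mask, slots, 0.0))
        return out

    # -- forward operators ------------------------------------------------
    def gd(self, omega):
        """Scattered-field edge coefficients radiated by ``omega``."""
        return self.system.solve(self.R @ omega)

    def gs(self, omega, esct=None):
        """Scattered data at the antennas; pass ``esct`` to reuse a solve."""
        if esct is None:
            esct = self.gd(omega)
        return self.msense @ esct

    def gs_adjoint(self, d):
        """Adjoint data-to-source map ``G_S^H d``."""
        return self._Rh @ self.system.solve(self._Mh @ d, adjoint=True)

    def rhs_adjoint(self, edge_array):
        """``R^H K^{-H}`` applied to an edge-space vector."""
        return self._Rh @ self.system.solve(edge_array, adjoint=True)
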