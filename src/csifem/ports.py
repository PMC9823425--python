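"""Coaxial TEM ports: modal field, projections and S-parameter algebra.

An antenna port is the annulus between the inner and outer conductor of
its coaxial feed.  With the reference impedance common to all ports, the
scattering parameter from transmitter ``t`` to receiver ``m`` is the
projection of the received port field onto the normalized TEM mode

    e_TEM = 1 / sqrt(2 pi ln(rb/ra)) * rho_hat / rho ,

whose squared magnitude integrates to one over the annulus.  Scattered
data follow as differences of target- and background-scenario
S-parameters; they are the entries of the data domain used by the
inversion cost functional.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CoaxPort",
    "sparam_from_port_fields",
    "scattered_data_from_sparams",
]


class CoaxPort:
    """Annular coaxial port surface.

    Parameters
    ----------
    center : (3,) float
        Centre of the annulus, metres.
    normal : (3,) float
        Port plane normal (normalized on construction).
    ra, rb : float
        Inner and outer conductor radii, ``0 < ra < rb``.
    """

    def __init__(self, center, normal, ra, rb):
        if not 0 < ra < rb:
            raise ValueError("radii must satisfy 0 < ra < rb")
        self.center = np.asarray(center, dtype=float)
        normal = np.asarray(normal, dtype=float)
        nn = np.linalg.norm(normal)
        if nn == 0:
            raise ValueError("normal must be nonzero")
        self.normal = normal / nn
        self.ra = float(ra)
        self.rb = float(rb)
        # in-plane orthonormal frame
        ref = np.array([1.0, 0.0, 0.0])
        if abs(self.normal @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = ref - (ref @ self.normal) * self.normal
        self.u = u / np.linalg.norm(u)
        self.v = np.cross(self.normal, self.u)

    @property
    def mode_norm(self):
        """Normalization factor ``1/sqrt(2 pi ln(rb/ra))``."""
        return 1.0 / np.sqrt(2.0 * np.pi * np.log(self.rb / self.ra))

    def etem(self, points, tol=1e-9):
        """TEM modal field at points on the annulus.

        Raises ``ValueError`` for points off the port plane or outside
        ``ra <= rho <= rb``.
        """
        points = np.atleast_2d(np.asarray(points, float))
        d = points - self.center
        off = d @ self.normal
        if (np.abs(off) > tol + 1e-12 * self.rb).any():
            raise ValueError("point off the port plane")
        rho_vec = d - off[:, None] * self.normal
        rho = np.linalg.norm(rho_vec, axis=1)
        if ((rho < self.ra * (1 - 1e-9)) | (rho > self.rb * (1 + 1e-9))).any():
            raise ValueError("point outside the annulus ra <= rho <= rb")
        return self.mode_norm * rho_vec / rho[:, None] ** 2

    def quadrature(self, n_rho=16, n_phi=32):
        """Tensor-product rule on the annulus: Gauss-Legendre radially,
        uniform (trapezoidal, exact for trigonometric polynomials)
        azimuthally.  Returns ``(points, weights)`` with weights carrying
        the area element ``rho drho dphi``."""
        x, w = np.polynomial.legendre.leggauss(n_rho)
        rho = 0.5 * (self.rb - self.ra) * x + 0.5 * (self.rb + self.ra)
        wr = 0.5 * (self.rb - self.ra) * w * rho
        phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
        wphi = 2.0 * np.pi / n_phi
        R, P = np.meshgrid(rho, phi, indexing="ij")
        W = np.outer(wr, np.full(n_phi, wphi)).ravel()
        pts = (
            self.center
            + R.ravel()[:, None] * (np.cos(P.ravel())[:, None] * self.u
                                    + np.sin(P.ravel())[:, None] * self.v)
        )
        return pts, W

    def project_tem(self, field_values, points, weights):
        """Inner product ``<E, e_TEM>`` by annulus quadrature.

        ``field_values`` are (n, 3) complex field samples at the
        quadrature ``points``.
        """
        e = self.etem(points)
        return np.sum(weights * np.einsum("ij,ij->i", field_values, e))


def sparam_from_port_fields(
    em_values, points, weights, port, et_plus_amplitude=1.0, m_equals_t=False
):
    """Scattering parameter from sampled port fields.

    With a unit-amplitude impressed TEM field at the transmitter,
    ``S_mt = <E_m, e_TEM>`` at a receiving port and
    ``S_tt = <E_t - E_t^+, e_TEM>`` at the transmitting one.

    Parameters
    ----------
    em_values : (n, 3) complex
        Total field samples at the quadrature points of port ``m``.
    points, weights : arrays
        Annulus quadrature of port ``m``.
    et_plus_amplitude : complex
        Amplitude of the impressed TEM wave at the transmitter (must be
        nonzero; S-parameters are ratios).
    m_equals_t : bool
        Whether this is the reflection coefficient of the transmitter.
    """
    if et_plus_amplitude == 0:
        raise ValueError("impressed amplitude must be nonzero")
    em_values = np.asarray(em_values, dtype=complex)
    if m_equals_t:
        em_values = em_values - et_plus_amplitude * port.etem(points)
    return port.project_tem(em_values, points, weights) / et_plus_amplitude


def scattered_data_from_sparams(s_tot, s_inc):
    """Scattered data matrix ``S^tot - S^inc`` (transmitter = column)."""
    s_tot = np.asarray(s_tot, dtype=complex)
    s_inc = np.asarray(s_inc, dtype=complex)
    if s_tot.shape != s_inc.shape or s_tot.ndim != 2:
        raise ValueError("S-parameter sets must be equal-shape 2-D matrices")
    return s_tot - s_inc
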