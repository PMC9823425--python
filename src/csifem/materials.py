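"""Per-cell dielectric description of background and target scenarios.

The time convention is ``exp(+j omega t)``, so a passive medium with
conductivity ``sigma`` has complex relative permittivity
``eps_r - j sigma / (omega eps0)`` with non-positive imaginary part.
"""

from __future__ import annotations

import numpy as np

from .constants import EPS0, MU0

__all__ = ["complex_permittivity", "MaterialMap"]


def complex_permittivity(eps_r, sigma, frequency):
    """Complex relative permittivity of a conductive dielectric."""
    omega = 2.0 * np.pi * frequency
    return eps_r - 1j * sigma / (omega * EPS0)


class MaterialMap:
    """Cell-wise complex permittivity of the background and target scenarios.

    Parameters
    ----------
    frequency : float
        Working frequency in Hz.
    eps_b : (I,) complex array
        Background (reference-scenario) relative permittivity per cell.
    eps_target : (I,) complex array, optional
        Scenario-under-test permittivity; defaults to the background
        (zero contrast).

    Notes
    -----
    The permittivity is sampled at each cell barycenter and held constant
    over the cell, and so is the squared background wavenumber
    ``kb^2 = omega^2 mu0 eps0 eps_b``.
    """

    def __init__(self, frequency, eps_b, eps_target=None):
        self.frequency = float(frequency)
        self.eps_b = np.asarray(eps_b, dtype=complex)
        self.eps_target = (
            self.eps_b.copy()
            if eps_target is None
            else np.asarray(eps_target, dtype=complex)
        )
        if self.eps_target.shape != self.eps_b.shape:
            raise ValueError("eps_target and eps_b must have equal length")
        for name, arr in (("eps_b", self.eps_b), ("eps_target", self.eps_target)):
            if (arr.imag > 1e-12).any():
                raise ValueError(
                    f"{name} has positive imaginary part; passive media "
                    "require Im(eps) <= 0 under the exp(+j omega t) convention"
                )

    @property
    def omega(self):
        return 2.0 * np.pi * self.frequency

    @property
    def k0sq(self):
        """Free-space squared wavenumber ``omega^2 mu0 eps0``."""
        return self.omega**2 * MU0 * EPS0

    @property
    def kb2(self):
        """Per-cell squared background wavenumber."""
        return self.k0sq * self.eps_b

    @property
    def kb2_target(self):
        return self.k0sq * self.eps_target

    @property
    def n_cells(self):
        return len(self.eps_b)

    def with_target(self, eps_target):
        return MaterialMap(self.frequency, self.eps_b, eps_target)

    def sigma_from_eps(self, eps):
        """Conductivity in S/m implied by a complex relative permittivity."""
        return -np.imag(eps) * self.omega * EPS0
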