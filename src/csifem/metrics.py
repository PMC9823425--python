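"""Accuracy diagnostics for the contrast-source discretizations.

Three consistency experiments quantify how faithfully each contrast-
source representation reproduces the discretized wave equation when fed
*exact* fields and contrast:

1. the residual between the two sides of the discretized wave equation
   (`wave_equation_residual`),
2. the error in scattered-field coefficients recovered by solving that
   equation (`esct_recovery_error`),
3. the value of the cost functional at the exact solution
   (`exact_cost_eval`).

For the edge-basis scheme in its exact (cell-linear) mode all three sit
at the forward-solver floor, because ``R w_exact`` coincides with
``(V_target - V_background) E_tot`` identically; the standard/barycenter
scheme carries a genuine discretization error.

Region statistics summarize a reconstruction inside a target region
(mean, spread, maximum of the recovered permittivity and conductivity,
and the percentage of cells above detection thresholds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .csi import cost_fd, cost_fs
from .operators import Contrast, CSIOperators, omega_from_exact

__all__ = [
    "ResidualReport",
    "RegionStats",
    "residual_norms",
    "wave_equation_residual",
    "esct_recovery_error",
    "exact_cost_eval",
    "stroke_stats",
    "convergence_report",
]


@dataclass
class ResidualReport:
    """Euclidean and relative norms of an LHS/RHS mismatch.

    ``eta = sqrt(sum_e |LHS_e - RHS_e|^2)`` and ``eta_r = eta / ||LHS||``
    (complex moduli inside the sums); ``per_transmitter`` holds
    ``(eta, eta_r)`` pairs when the report aggregates several sources.
    """

    eta: float
    eta_r: float
    per_transmitter: list | None = None


def residual_norms(lhs, rhs):
    """Norms of the difference between two coefficient arrays."""
    lhs = np.asarray(lhs)
    rhs = np.asarray(rhs)
    if lhs.shape != rhs.shape:
        raise ValueError("LHS and RHS must have equal length")
    eta = float(np.linalg.norm(lhs - rhs))
    nl = float(np.linalg.norm(lhs))
    if nl == 0.0:
        if eta > 0.0:
            warnings.warn("||LHS|| = 0 with eta > 0; eta_r is infinite",
                          RuntimeWarning, stacklevel=2)
            return ResidualReport(eta, float("inf"))
        return ResidualReport(0.0, 0.0)
    return ResidualReport(eta, eta / nl)


def _aggregate(pairs, lhs_norms):
    eta = float(np.sqrt(sum(e**2 for e, _ in pairs)))
    nl = float(np.sqrt(sum(n**2 for n in lhs_norms)))
    return ResidualReport(eta, eta / nl if nl else float("inf"),
                          per_transmitter=pairs)


def wave_equation_residual(system, mesh, contrast: Contrast, fields,
                           variant="edge", eval_mode="linear"):
    """LHS/RHS mismatch of the discretized wave equation.

    ``LHS = (U - V - A) E^sct`` and ``RHS = R w`` with the contrast
    sources built from the exact ``(chi, E_tot)`` of the same mesh.
    Reported per transmitter and aggregated over all of them.
    """
    from .operators import assemble_coupling

    kb2 = system.kb2
    if variant == "edge":
        R = assemble_coupling(mesh, kb2, variant="edge", eval_mode=eval_mode)
    else:
        R = assemble_coupling(mesh, kb2, variant="standard")
    pairs, lhs_norms = [], []
    for t in range(len(fields.etot)):
        lhs = system.K @ fields.esct[t]
        w = omega_from_exact(contrast, fields.etot[t], mesh, variant=variant)
        rhs = R @ w
        rep = residual_norms(lhs, rhs)
        pairs.append((rep.eta, rep.eta_r))
        lhs_norms.append(float(np.linalg.norm(lhs)))
    return _aggregate(pairs, lhs_norms)


def esct_recovery_error(system, mesh, contrast: Contrast, fields,
                        variant="edge", eval_mode="linear"):
    """Error of scattered-field coefficients recovered from ``R w``.

    Solves the discretized wave equation for ``E^sct`` with the exact
    contrast sources on the right-hand side and compares with the
    forward-solver difference ``E_tot - E_inc``.
    """
    from .operators import assemble_coupling

    kb2 = system.kb2
    variant_kw = dict(variant="edge", eval_mode=eval_mode) \
        if variant == "edge" else dict(variant="standard")
    R = assemble_coupling(mesh, kb2, **variant_kw)
    pairs, lhs_norms = [], []
    for t in range(len(fields.etot)):
        w = omega_from_exact(contrast, fields.etot[t], mesh, variant=variant)
        esct = system.solve(R @ w)
        ref = fields.esct[t]
        rep = residual_norms(ref, esct)
        pairs.append((rep.eta, rep.eta_r))
        lhs_norms.append(float(np.linalg.norm(ref)))
    return _aggregate(pairs, lhs_norms)


def exact_cost_eval(contrast: Contrast, fields, data, ops: CSIOperators):
    """``F_S`` and ``F_D`` evaluated at the exact contrast and sources."""
    T = len(fields.etot)
    omegas = [
        omega_from_exact(contrast, fields.etot[t], ops.mesh, variant="edge")
        for t in range(T)
    ]
    fs = cost_fs(omegas, data, ops)
    einc_slots = [ops.slots_from_edges(fields.einc[t]) for t in range(T)]
    chi_slots = np.repeat(contrast.chi, 6)
    fd = cost_fd(chi_slots, omegas, einc_slots, ops)
    return {"FS": fs, "FD": fd}


@dataclass
class RegionStats:
    """Reconstruction statistics inside a cell region."""

    n_cells: int
    eps_mean: float
    eps_std: float
    eps_max: float
    sigma_mean: float
    sigma_std: float
    sigma_max: float
    pct_eps_above: float
    pct_sigma_above: float
    eps_threshold: float
    sigma_threshold: float

    def as_frame(self):
        return pd.DataFrame(
            {
                "mean": [self.eps_mean, self.sigma_mean],
                "std": [self.eps_std, self.sigma_std],
                "max": [self.eps_max, self.sigma_max],
                "% above threshold": [self.pct_eps_above, self.pct_sigma_above],
                "threshold": [self.eps_threshold, self.sigma_threshold],
            },
            index=["eps_r", "sigma (S/m)"],
        )


def stroke_stats(contrast: Contrast, materials, region_mask,
                 eps_threshold=53.0, sigma_threshold=1.0):
    """Summary of the reconstructed dielectric properties in a region.

    The contrast is mapped back to ``(eps_r, sigma)`` through
    ``eps_tilde = eps_b (1 + chi)``; percentages count region cells whose
    recovered value exceeds the detection thresholds.
    """
    region_mask = np.asarray(region_mask, bool)
    if not region_mask.any():
        raise ValueError("empty region")
    eps = materials.eps_b * (1.0 + contrast.chi)
    eps_r = np.real(eps)[region_mask]
    sig = materials.sigma_from_eps(eps)[region_mask]
    return RegionStats(
        n_cells=int(region_mask.sum()),
        eps_mean=float(eps_r.mean()),
        eps_std=float(eps_r.std()),
        eps_max=float(eps_r.max()),
        sigma_mean=float(sig.mean()),
        sigma_std=float(sig.std()),
        sigma_max=float(sig.max()),
        pct_eps_above=float(100.0 * np.mean(eps_r > eps_threshold)),
        pct_sigma_above=float(100.0 * np.mean(sig > sigma_threshold)),
        eps_threshold=float(eps_threshold),
        sigma_threshold=float(sigma_threshold),
    )


def convergence_report(history, path=None):
    """Per-iteration cost table ``(n, FS, FD, FCSI)``.

    ``history`` is a sequence of ``(n, FS, FD)`` tuples (as logged by the
    inversion) or a DataFrame with those columns.  When ``path`` is given
    the table is also written as whitespace-separated columns.
    """
    if isinstance(history, pd.DataFrame):
        df = history[["n", "FS", "FD"]].copy()
    else:
        df = pd.DataFrame(list(history), columns=["n", "FS", "FD"])
    if not len(df):
        raise ValueError("empty history")
    df["FCSI"] = df["FS"] + df["FD"]
    if path is not None:
        df.to_csv(path, sep=" ", index=False, float_format="%.8e")
    return df
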