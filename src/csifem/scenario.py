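"""Synthetic phantoms, acquisition geometry and simulated scattered data.

The generator emulates a desk-scale microwave brain-imaging session: a
lossy head phantom (concentric spheres/ellipsoids) immersed in a coupling
medium inside a box domain, a blood-like stroke inclusion, and a ring of
antennas acting alternately as transmitter and receivers.  Scattered data
are produced by forward-solving the background and target scenarios on a
mesh *different* from the inversion mesh, so that the inversion never
sees data generated on its own discretization.

Default study conditions: head sphere of radius 50 mm centred in a
140 mm box, coupling medium with relative permittivity 20, blood
inclusion with eps_r = 64.41 and sigma = 1.58 S/m, 1 GHz, 8 antennas on
an equatorial ring, data mesh h = 4 mm vs inversion mesh h = 5 mm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from .assembly import SystemMatrices, dipole_rhs
from .materials import MaterialMap, complex_permittivity
from .mesh import TetMesh, build_box_mesh
from .ports import CoaxPort

__all__ = [
    "Layer",
    "PhantomSpec",
    "StrokeSpec",
    "AcquisitionSpec",
    "FieldSolution",
    "ScatteringDataset",
    "build_phantom_materials",
    "add_inclusion",
    "antenna_ring",
    "measurement_matrix",
    "source_rhs",
    "generate_dataset",
    "ConsistencyFixture",
    "homogeneous_head_fixture",
    "default_phantom",
    "default_stroke",
    "default_acquisition",
]


@dataclass
class Layer:
    """One phantom layer: an ellipsoid (or sphere) of a single tissue."""

    center: tuple
    semi_axes: tuple  # (ax, ay, az) in metres; equal values give a sphere
    eps_r: float
    sigma: float  # S/m

    def contains(self, pts):
        d = (np.atleast_2d(pts) - np.asarray(self.center)) / np.asarray(
            self.semi_axes
        )
        return (d**2).sum(axis=1) <= 1.0


@dataclass
class PhantomSpec:
    """Layered phantom in a coupling-medium-filled box.

    Layers are ordered outermost to innermost; later layers override
    earlier ones cell-wise.
    """

    layers: list
    coupling_eps_r: float = 20.0
    coupling_sigma: float = 0.0
    frequency: float = 1.0e9
    domain: tuple = (0.14, 0.14, 0.14)

    def __post_init__(self):
        for lay in self.layers:
            if lay.eps_r < 1 or lay.sigma < 0:
                raise ValueError("layers require eps_r >= 1 and sigma >= 0")


@dataclass
class StrokeSpec:
    """Blood-like ellipsoidal inclusion (haemorrhagic-stroke surrogate)."""

    center: tuple
    semi_axes: tuple
    eps_r: float = 64.41
    sigma: float = 1.58

    def as_layer(self):
        return Layer(self.center, self.semi_axes, self.eps_r, self.sigma)


@dataclass
class AcquisitionSpec:
    """Antenna ring and meshing of the acquisition.

    ``source_model`` selects elementary dipoles (field sampling at the
    receiver positions) or annular coaxial ports with TEM projection.
    """

    n_antennas: int = 8
    ring_radius: float = 0.060
    ring_center: tuple = (0.07, 0.07, 0.07)
    source_model: str = "dipole"  # or "coax_port"
    data_h: float = 0.004
    inversion_h: float = 0.005
    dipole_moment: tuple = (0.0, 0.0, 1.0)
    port_ra: float = 0.001
    port_rb: float = 0.004

    def __post_init__(self):
        if self.source_model not in ("dipole", "coax_port"):
            raise ValueError("source_model must be 'dipole' or 'coax_port'")


@dataclass
class FieldSolution:
    """Per-transmitter edge-coefficient arrays (rows = transmitters)."""

    etot: np.ndarray  # (T, E)
    einc: np.ndarray  # (T, E)

    @property
    def esct(self):
        return self.etot - self.einc


def default_phantom(**kw):
    head = Layer((0.07, 0.07, 0.07), (0.05, 0.05, 0.05), 45.37, 0.77)
    return PhantomSpec(layers=[head], **kw)


def default_stroke():
    # posterior off-centre ellipsoid inside the head, ~15 mm scale
    return StrokeSpec(center=(0.085, 0.07, 0.07), semi_axes=(0.015, 0.012, 0.012))


def default_acquisition(**kw):
    return AcquisitionSpec(**kw)


# ----------------------------------------------------------------------
# materials
# ----------------------------------------------------------------------
def build_phantom_materials(mesh: TetMesh, spec: PhantomSpec, background="coupling"):
    """Cell-wise permittivity maps from a layered phantom.

    Each cell takes the permittivity of the innermost layer containing
    its barycenter, the coupling medium elsewhere.

    Parameters
    ----------
    background : {"coupling", "phantom"}
        What the reference (background) scenario contains: the coupling
        medium only, or the full layered phantom (the usual imaging
        reference, leaving any later inclusion as the only contrast).
    """
    lo, hi = mesh.nodes.min(axis=0), mesh.nodes.max(axis=0)
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    for lay in spec.layers:
        c, a = np.asarray(lay.center), np.asarray(lay.semi_axes)
        sticks_out = ((c - a) < lo - 1e-12).any() or ((c + a) > hi + 1e-12).any()
        covers_all = lay.contains(corners).all()
        if sticks_out and not covers_all:
            raise ValueError(f"layer {lay} extends outside the mesh bounds")
    eps_c = complex_permittivity(spec.coupling_eps_r, spec.coupling_sigma, spec.frequency)
    eps = np.full(mesh.n_tets, eps_c, dtype=complex)
    for lay in spec.layers:  # later layers override earlier ones
        inside = lay.contains(mesh.barycenters)
        eps[inside] = complex_permittivity(lay.eps_r, lay.sigma, spec.frequency)
    if background == "coupling":
        eps_b = np.full(mesh.n_tets, eps_c, dtype=complex)
    elif background == "phantom":
        eps_b = eps.copy()
    else:
        raise ValueError("background must be 'coupling' or 'phantom'")
    return MaterialMap(spec.frequency, eps_b, eps)


def add_inclusion(materials: MaterialMap, mesh: TetMesh, stroke: StrokeSpec,
                  phantom: PhantomSpec | None = None):
    """Override target-scenario cells inside the inclusion with its tissue.

    The background map is untouched; a zero-volume inclusion leaves the
    materials unchanged.
    """
    if min(stroke.semi_axes) <= 0:
        return materials
    if phantom is not None and phantom.layers:
        inner = phantom.layers[-1]
        # the inclusion must fit inside the innermost layer: test the
        # bounding-box corners of the stroke ellipsoid
        c, a = np.asarray(stroke.center), np.asarray(stroke.semi_axes)
        corners = c + a * np.array(
            [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        )
        if not inner.contains(corners).all():
            raise ValueError("stroke inclusion extends outside the innermost layer")
    lay = stroke.as_layer()
    inside = lay.contains(mesh.barycenters)
    eps_t = materials.eps_target.copy()
    eps_t[inside] = complex_permittivity(stroke.eps_r, stroke.sigma, materials.frequency)
    return materials.with_target(eps_t)


# ----------------------------------------------------------------------
# acquisition
# ----------------------------------------------------------------------
def antenna_ring(acq: AcquisitionSpec):
    """Positions and unit moments of the antennas on the equatorial ring."""
    T = acq.n_antennas
    ang = 2.0 * np.pi * np.arange(T) / T
    c = np.asarray(acq.ring_center)
    pos = c + acq.ring_radius * np.stack(
        [np.cos(ang), np.sin(ang), np.zeros(T)], axis=1
    )
    mom = np.tile(np.asarray(acq.dipole_moment, float), (T, 1))
    mom /= np.linalg.norm(mom, axis=1, keepdims=True)
    return pos, mom


def _ports(acq: AcquisitionSpec):
    pos, _ = antenna_ring(acq)
    c = np.asarray(acq.ring_center)
    ports = []
    for p in pos:
        normal = c - p
        ports.append(CoaxPort(p, normal, acq.port_ra, acq.port_rb))
    return ports


def _sampling_row(mesh, point, direction):
    """Sparse row sampling ``E(point) . direction`` of an edge field."""
    tets, lam = mesh.locate(np.atleast_2d(point))
    t = int(tets[0])
    g = mesh.grads[t]
    cols, vals = [], []
    for le in range(6):
        a, b = mesh.edge_lo_local[t, le], mesh.edge_hi_local[t, le]
        N = lam[0][a] * g[b] - lam[0][b] * g[a]
        cols.append(mesh.tet_edges[t, le])
        vals.append(N @ direction)
    return cols, vals


def _port_row(mesh, port, n_rho=12, n_phi=24):
    """Sparse row of the TEM projection ``<E, e_TEM>`` on an edge field."""
    pts, w = port.quadrature(n_rho, n_phi)
    e = port.etem(pts)
    tets, lam = mesh.locate(pts)
    g = mesh.grads[tets]
    a = mesh.edge_lo_local[tets]
    b = mesh.edge_hi_local[tets]
    ga = np.take_along_axis(g, a[..., None], axis=1)
    gb = np.take_along_axis(g, b[..., None], axis=1)
    la = np.take_along_axis(lam, a, axis=1)[..., None]
    lb = np.take_along_axis(lam, b, axis=1)[..., None]
    N = la * gb - lb * ga  # (n, 6, 3)
    contrib = w[:, None] * np.einsum("nkj,nj->nk", N, e)  # (n, 6)
    cols = mesh.tet_edges[tets].ravel()
    vals = contrib.ravel()
    return cols, vals


def measurement_matrix(mesh: TetMesh, acq: AcquisitionSpec):
    """T x E sparse operator mapping edge coefficients to received data."""
    rows, cols, vals = [], [], []
    if acq.source_model == "dipole":
        pos, mom = antenna_ring(acq)
        for m in range(acq.n_antennas):
            c, v = _sampling_row(mesh, pos[m], mom[m])
            rows += [m] * len(c)
            cols += list(c)
            vals += list(v)
    else:
        for m, port in enumerate(_ports(acq)):
            c, v = _port_row(mesh, port)
            rows += [m] * len(c)
            cols += list(c)
            vals += list(v)
    M = sp.coo_matrix(
        (np.asarray(vals, complex), (rows, cols)),
        shape=(acq.n_antennas, mesh.n_edges),
    ).tocsr()
    return M


def source_rhs(mesh: TetMesh, acq: AcquisitionSpec, t: int):
    """Excitation vector of transmitter ``t``.

    For the dipole model this is the Galerkin load of an elementary
    dipole; for the port model, an impressed TEM-distributed surface
    current on the annulus.  Source and measurement use the same spatial
    weighting, which makes the simulated data exactly reciprocal for
    reciprocal media.
    """
    if acq.source_model == "dipole":
        pos, mom = antenna_ring(acq)
        return dipole_rhs(mesh, pos[t], mom[t])
    port = _ports(acq)[t]
    cols, vals = _port_row(mesh, port)
    rhs = np.zeros(mesh.n_edges, dtype=complex)
    np.add.at(rhs, cols, vals)
    return rhs


# ----------------------------------------------------------------------
# dataset generation
# ----------------------------------------------------------------------
@dataclass
class ScatteringDataset:
    """Everything the inversion needs, plus provenance.

    ``data[m, t]`` is the scattered datum received at antenna ``m`` when
    antenna ``t`` transmits.  ``fields`` holds the incident edge
    coefficients on the inversion mesh (and the data-mesh fields when the
    generator was run in same-mesh mode for consistency experiments).
    """

    mesh: TetMesh
    materials: MaterialMap
    acq: AcquisitionSpec
    data: np.ndarray            # (T, T) complex
    einc: np.ndarray            # (T, E) on the inversion mesh
    system: SystemMatrices      # background system on the inversion mesh
    provenance: dict = field(default_factory=dict)
    data_fields: FieldSolution | None = None  # populated in same-mesh mode

    @property
    def n_antennas(self):
        return self.data.shape[0]

    def save(self, path):
        np.savez_compressed(
            path,
            nodes=self.mesh.nodes,
            tets=self.mesh.tets,
            structured=json.dumps(
                None
                if self.mesh.structured is None
                else [list(self.mesh.structured[0]), self.mesh.structured[1],
                      list(self.mesh.structured[2])]
            ),
            eps_b=self.materials.eps_b,
            eps_target=self.materials.eps_target,
            data=self.data,
            einc=self.einc,
            provenance=json.dumps(self.provenance),
        )

    @classmethod
    def load(cls, path, solver="auto", tol=1e-12):
        """Rebuild a dataset bundle (and its operators) from disk."""
        z = np.load(path, allow_pickle=False)
        prov = json.loads(str(z["provenance"]))
        structured = json.loads(str(z["structured"]))
        if structured is not None:
            structured = (
                np.asarray(structured[0]),
                float(structured[1]),
                tuple(structured[2]),
            )
        mesh = TetMesh(z["nodes"], z["tets"], structured=structured)
        acq = AcquisitionSpec(**prov["acquisition"])
        freq = prov["phantom"]["frequency"]
        materials = MaterialMap(freq, z["eps_b"], z["eps_target"])
        kb_bdry = np.sqrt(materials.k0sq * materials.eps_b[_boundary_cell(mesh)])
        system = SystemMatrices(mesh, materials.kb2, kb_bdry,
                                solver=solver, tol=tol)
        return cls(
            mesh=mesh, materials=materials, acq=acq, data=z["data"],
            einc=z["einc"], system=system, provenance=prov,
        )


def _forward_fields(mesh, materials, acq, solver, tol, scenarios=("background",)):
    """Solve all transmitters for the requested scenarios on one mesh."""
    eps_c = materials.eps_b[_boundary_cell(mesh)]
    kb_bdry = np.sqrt(materials.k0sq * eps_c)
    out = {}
    for scen in scenarios:
        kb2 = materials.kb2 if scen == "background" else materials.kb2_target
        sysm = SystemMatrices(mesh, kb2, kb_bdry, solver=solver, tol=tol)
        sols = np.empty((acq.n_antennas, mesh.n_edges), dtype=complex)
        for t in range(acq.n_antennas):
            # seed the target solve with the background field of the same
            # transmitter (same rhs, related solution); exact solvers
            # ignore the seed
            seed = out["background"][1][t] if "background" in out else None
            sols[t] = sysm.solve(source_rhs(mesh, acq, t), x0=seed)
        out[scen] = (sysm, sols)
    return out


def _boundary_cell(mesh):
    return int(mesh.boundary["owner_tets"][0])


def generate_dataset(
    phantom: PhantomSpec,
    stroke: StrokeSpec | None,
    acq: AcquisitionSpec,
    seed: int | None = None,
    snr_db: float | None = None,
    solver="auto",
    tol=1e-12,
    background="phantom",
    allow_inverse_crime=False,
):
    """Simulate scattered data and build the inversion-side operators.

    Scattered data come from forward solves of the background and target
    scenarios on the *data* mesh; the incident field and the system
    operators handed to the inversion are built on the coarser
    *inversion* mesh.  Requesting identical meshes without
    ``allow_inverse_crime`` raises a warning ("inverse crime": inverting
    data generated on the inversion's own discretization).

    Optional additive complex circular Gaussian noise is applied per
    datum, with the standard deviation set by ``snr_db`` relative to the
    per-transmitter scattered-data norm; the generator is seeded by
    ``seed`` and the pipeline is fully deterministic.
    """
    same_mesh = np.isclose(acq.data_h, acq.inversion_h)
    if same_mesh and not allow_inverse_crime:
        warnings.warn(
            "data and inversion meshes are identical (inverse crime); "
            "pass allow_inverse_crime=True if this is intentional",
            UserWarning,
            stacklevel=2,
        )

    # --- data mesh: simulate both scenarios -------------------------------
    mesh_d = build_box_mesh(phantom.domain, acq.data_h)
    mat_d = build_phantom_materials(mesh_d, phantom, background=background)
    if stroke is not None:
        mat_d = add_inclusion(mat_d, mesh_d, stroke, phantom)
    _validate_antennas(phantom, acq)
    fwd = _forward_fields(
        mesh_d, mat_d, acq, solver, tol, scenarios=("background", "target")
    )
    _, einc_d = fwd["background"]
    _, etot_d = fwd["target"]
    Msense_d = measurement_matrix(mesh_d, acq)
    data = np.empty((acq.n_antennas, acq.n_antennas), dtype=complex)
    for t in range(acq.n_antennas):
        data[:, t] = Msense_d @ (etot_d[t] - einc_d[t])

    rng = np.random.default_rng(seed)
    if snr_db is not None:
        for t in range(acq.n_antennas):
            level = np.linalg.norm(data[:, t]) / np.sqrt(acq.n_antennas)
            s = level * 10.0 ** (-snr_db / 20.0)
            data[:, t] += s / np.sqrt(2) * (
                rng.standard_normal(acq.n_antennas)
                + 1j * rng.standard_normal(acq.n_antennas)
            )

    # --- inversion mesh: incident field and operators ---------------------
    if same_mesh:
        mesh_i, mat_i = mesh_d, mat_d
        sys_i, einc_i = fwd["background"]
    else:
        mesh_i = build_box_mesh(phantom.domain, acq.inversion_h)
        mat_i = build_phantom_materials(mesh_i, phantom, background=background)
        if stroke is not None:
            mat_i = add_inclusion(mat_i, mesh_i, stroke, phantom)
        res = _forward_fields(mesh_i, mat_i, acq, solver, tol)
        sys_i, einc_i = res["background"]

    prov = {
        "phantom": asdict(phantom),
        "stroke": asdict(stroke) if stroke is not None else None,
        "acquisition": asdict(acq),
        "seed": seed,
        "snr_db": snr_db,
        "mesh_data_hash": mesh_d.content_hash(),
        "mesh_inversion_hash": mesh_i.content_hash(),
    }
    ds = ScatteringDataset(
        mesh=mesh_i,
        materials=mat_i,
        acq=acq,
        data=data,
        einc=einc_i,
        system=sys_i,
        provenance=prov,
        data_fields=FieldSolution(etot=etot_d, einc=einc_d) if same_mesh else None,
    )
    return ds


@dataclass
class ConsistencyFixture:
    """Same-mesh forward bundle for the discretization-accuracy experiments.

    Background = coupling medium only; target = the homogeneous head in
    the coupling medium, so the whole head is the contrast.  Fields,
    system and data share one mesh: the experiments measure pure
    discretization consistency, not model error.
    """

    mesh: TetMesh
    materials: MaterialMap
    acq: AcquisitionSpec
    phantom: PhantomSpec
    system: SystemMatrices      # background system
    fields: FieldSolution
    data: np.ndarray            # (T, T) scattered data
    msense: sp.spmatrix
    head_mask: np.ndarray       # (I,) bool


def homogeneous_head_fixture(h=0.005, n_antennas=4, solver="auto", tol=1e-12,
                             domain=0.14, head_radius=0.05, frequency=1.0e9,
                             head_eps=45.37, head_sigma=0.77,
                             coupling_eps=20.0):
    """Build the homogeneous-head same-mesh accuracy fixture.

    Default geometry: a lossy sphere with the head-average dielectric
    properties (eps_r = 45.37, sigma = 0.77 S/m) of radius 50 mm centred
    in a 140 mm coupling-medium box, meshed at h = 5 mm, with 4 dipole
    antennas on the equatorial ring, at 1 GHz.
    """
    center = (domain / 2.0,) * 3
    phantom = PhantomSpec(
        layers=[Layer(center, (head_radius,) * 3, head_eps, head_sigma)],
        coupling_eps_r=coupling_eps,
        frequency=frequency,
        domain=(domain,) * 3,
    )
    acq = AcquisitionSpec(
        n_antennas=n_antennas,
        ring_radius=head_radius + 0.5 * (domain / 2.0 - head_radius),
        ring_center=center,
        data_h=h,
        inversion_h=h,
    )
    _validate_antennas(phantom, acq)
    mesh = build_box_mesh(phantom.domain, h)
    materials = build_phantom_materials(mesh, phantom, background="coupling")
    fwd = _forward_fields(mesh, materials, acq, solver, tol,
                          scenarios=("background", "target"))
    system, einc = fwd["background"]
    _, etot = fwd["target"]
    fields = FieldSolution(etot=etot, einc=einc)
    msense = measurement_matrix(mesh, acq)
    data = np.empty((n_antennas, n_antennas), complex)
    for t in range(n_antennas):
        data[:, t] = msense @ fields.esct[t]
    head_mask = phantom.layers[0].contains(mesh.barycenters)
    return ConsistencyFixture(
        mesh=mesh, materials=materials, acq=acq, phantom=phantom,
        system=system, fields=fields, data=data, msense=msense,
        head_mask=head_mask,
    )


def _validate_antennas(phantom, acq):
    pos, _ = antenna_ring(acq)
    lo = np.zeros(3)
    hi = np.asarray(phantom.domain)
    if ((pos < lo).any()) or ((pos > hi).any()):
        raise ValueError("antennas fall outside the computational domain")
    for lay in phantom.layers:
        if lay.contains(pos).any():
            raise ValueError("antennas must lie outside the phantom")
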