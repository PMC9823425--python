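"""Interchange formats: Gmsh meshes, legacy-VTK volumes, S-parameter tables.

Meshes round-trip through the ASCII Gmsh v2.2 format (node and element
blocks); reconstructed permittivity/conductivity volumes are exported as
legacy-VTK unstructured grids with cell data, readable by ParaView and
friends.  S-parameter matrices are stored as columnar text with
real/imaginary pairs, transmitter in the column index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mesh import TetMesh

__all__ = ["write_msh", "read_msh", "write_vtk", "write_sparams", "read_sparams"]


def write_msh(path, mesh: TetMesh):
    """Write the mesh in ASCII Gmsh v2.2 (nodes + 4-node tetrahedra)."""
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, p in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {p[0]:.16g} {p[1]:.16g} {p[2]:.16g}\n")
        f.write("$EndNodes\n")
        f.write(f"$Elements\n{mesh.n_tets}\n")
        for i, t in enumerate(mesh.tets + 1, start=1):
            f.write(f"{i} 4 2 0 1 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        f.write("$EndElements\n")


def read_msh(path):
    """Read an ASCII Gmsh v2.2 mesh (tetrahedral elements only)."""
    nodes, tets = [], []
    with open(path) as f:
        lines = iter(f.read().splitlines())
    for line in lines:
        if line.strip() == "$Nodes":
            n = int(next(lines))
            for _ in range(n):
                parts = next(lines).split()
                nodes.append([float(x) for x in parts[1:4]])
        elif line.strip() == "$Elements":
            n = int(next(lines))
            for _ in range(n):
                parts = next(lines).split()
                if int(parts[1]) == 4:  # 4-node tetrahedron
                    ntags = int(parts[2])
                    tets.append([int(x) - 1 for x in parts[3 + ntags:7 + ntags]])
    if not tets:
        raise ValueError(f"no tetrahedra found in {path}")
    return TetMesh(np.asarray(nodes), np.asarray(tets))


def write_vtk(path, mesh: TetMesh, cell_data=None):
    """Write a legacy-VTK (ASCII) unstructured grid with cell data."""
    cell_data = cell_data or {}
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncsifem volume\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.12g")
        f.write(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
        cells = np.column_stack([np.full(mesh.n_tets, 4), mesh.tets])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {mesh.n_tets}\n")
        np.savetxt(f, np.full(mesh.n_tets, 10), fmt="%d")  # VTK_TETRA
        if cell_data:
            f.write(f"CELL_DATA {mesh.n_tets}\n")
            for name, arr in cell_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, np.asarray(arr, float), fmt="%.12g")


def write_sparams(path, s, label="S"):
    """Columnar text table of a complex T x T matrix (transmitter = column).

    Columns: ``m t re im`` with 0-based antenna indices.
    """
    s = np.asarray(s, complex)
    T = s.shape[0]
    m, t = np.meshgrid(np.arange(T), np.arange(T), indexing="ij")
    df = pd.DataFrame(
        {
            "m": m.ravel(),
            "t": t.ravel(),
            f"{label}_re": s.real.ravel(),
            f"{label}_im": s.imag.ravel(),
        }
    )
    df.to_csv(path, sep=" ", index=False, float_format="%.16e")
    return df


def read_sparams(path):
    """Read a table written by :func:`write_sparams` back into a matrix."""
    df = pd.read_csv(path, sep=r"\s+")
    T = int(df["m"].max()) + 1
    s = np.zeros((T, T), complex)
    re_col = [c for c in df.columns if c.endswith("_re")][0]
    im_col = [c for c in df.columns if c.endswith("_im")][0]
    s[df["m"].to_numpy(), df["t"].to_numpy()] = (
        df[re_col].to_numpy() + 1j * df[im_col].to_numpy()
    )
    return s
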