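"""Legacy ASCII VTK export and false-colour stress maps.

The mesh is written as a VTK unstructured grid (cell type 9 for Q4, 23
for quadratic quads) with per-element material and stress fields as cell
data, viewable in ParaView.  For pixel-lattice meshes, per-element scalars
can also be rendered directly to a false-colour PNG heat map.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .mesh import FEMesh

__all__ = ["write_vtk", "write_heatmap_png"]

_CELL_TYPE = {"q4": 9, "q8": 23}


def write_vtk(path, mesh: FEMesh, cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh and optional per-element scalars as legacy ASCII VTK."""
    path = Path(path)
    cell_data = cell_data or {}
    nn = mesh.elements.shape[1]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("xray2fem unstructured grid\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.node_coords:
            fh.write(f"{x:.9g} {y:.9g} 0\n")
        fh.write(f"CELLS {mesh.n_elements} {mesh.n_elements * (nn + 1)}\n")
        for conn in mesh.elements:
            fh.write(f"{nn} " + " ".join(str(int(i)) for i in conn) + "\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        ct = _CELL_TYPE[mesh.order]
        fh.write("\n".join([str(ct)] * mesh.n_elements) + "\n")
        if cell_data:
            fh.write(f"CELL_DATA {mesh.n_elements}\n")
            for name, values in cell_data.items():
                values = np.asarray(values)
                if values.shape[0] != mesh.n_elements:
                    raise ValueError(f"cell data {name!r} does not match element count")
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9g}" for v in values.astype(float)) + "\n")


def write_heatmap_png(
    path,
    mesh: FEMesh,
    values: np.ndarray,
    title: str = "",
    cmap: str = "inferno",
    vmax: float | None = None,
) -> None:
    """False-colour map of a per-element scalar on a pixel-lattice mesh."""
    if mesh.grid_shape is None:
        raise ValueError("heat maps require a structured pixel mesh")
    img = np.asarray(values, dtype=float).reshape(mesh.grid_shape)
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(img, cmap=cmap, vmax=vmax, interpolation="nearest")
    ax.set_xlabel("x (elements)")
    ax.set_ylabel("y (elements)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="MPa")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
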