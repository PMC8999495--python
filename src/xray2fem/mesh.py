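"""Structured quadrilateral meshes on the pixel lattice.

Every pixel of the material map becomes one square element with edge
length equal to the pixel spacing; no coarsening or boundary fitting is
performed (the rapid-modelling premise is that the raster *is* the mesh).
Coordinates are in mm with x along image columns and y along image rows,
so y increases toward the fixed base at the bottom edge.

Both bilinear Q4 and serendipity quadratic Q8 elements are supported.
Connectivity ordering is counterclockwise corners then midside nodes
(Q8: [c1 c2 c3 c4 m12 m23 m34 m41]); with y treated as an ordinary
Cartesian coordinate all Jacobians are positive by construction.

``mesh_from_mapping`` builds boundary-fitted structured meshes from an
analytic (u, v) -> (x, y) mapping; the verification benchmarks (plate
with hole, beams) use it, exercising the same element machinery on
curved, graded geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.sparse import csgraph, csr_matrix

from .materials import MaterialMap, Tissue

__all__ = ["FEMesh", "build_mesh", "mesh_from_mapping", "deactivate_elements"]


@dataclass
class FEMesh:
    node_coords: np.ndarray  # (n_nodes, 2) mm
    elements: np.ndarray  # (n_elem, 4|8) node indices
    E: np.ndarray  # (n_elem,) MPa
    nu: np.ndarray  # (n_elem,)
    order: str  # "q4" | "q8"
    thickness_mm: float = 1.0
    material: np.ndarray | None = None  # (n_elem,) tissue class, if known
    grid_shape: tuple[int, int] | None = None  # (ny, nx) for pixel meshes

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def n_dofs(self) -> int:
        return 2 * self.n_nodes

    def nodes_where(self, predicate) -> np.ndarray:
        """Node indices whose coordinates satisfy ``predicate(x, y)``."""
        x, y = self.node_coords[:, 0], self.node_coords[:, 1]
        return np.flatnonzero(predicate(x, y))

    def bottom_nodes(self, tol: float = 1e-9) -> np.ndarray:
        y_max = self.node_coords[:, 1].max()
        return self.nodes_where(lambda x, y: y >= y_max - tol)

    def element_edges(self) -> np.ndarray:
        """(n_elem, 4, 2) corner-node pairs of each element's four edges."""
        c = self.elements[:, :4]
        return np.stack(
            [c[:, [0, 1]], c[:, [1, 2]], c[:, [2, 3]], c[:, [3, 0]]], axis=1
        )


def _q8_node_grid(ny: int, nx: int) -> np.ndarray:
    """Fine-grid index map for serendipity nodes; element centres are -1."""
    fine = np.full((2 * ny + 1, 2 * nx + 1), -1, dtype=np.int64)
    keep = ~((np.arange(2 * ny + 1)[:, None] % 2 == 1) & (np.arange(2 * nx + 1)[None, :] % 2 == 1))
    fine[keep] = np.arange(np.count_nonzero(keep))
    return fine


def build_mesh(material_map: MaterialMap, order: str = "q4") -> FEMesh:
    """One element per pixel at the pixel spacing; material copied per pixel.

    For an ``ny x nx`` map, Q4 yields ``nx*ny`` elements and
    ``(nx+1)(ny+1)`` nodes; Q8 yields ``(2nx+1)(2ny+1) - nx*ny`` nodes.
    """
    order = order.lower()
    if order not in ("q4", "q8"):
        raise ValueError(f"unknown element order {order!r}")
    ny, nx = material_map.shape
    if nx == 0 or ny == 0:
        raise ValueError("empty material map")
    h = material_map.pixel_spacing_mm
    if not h > 0:
        raise ValueError("pixel spacing must be positive")

    r, c = np.divmod(np.arange(ny * nx), nx)
    if order == "q4":
        node_id = lambda rr, cc: rr * (nx + 1) + cc  # noqa: E731
        xs, ys = np.meshgrid(np.arange(nx + 1) * h, np.arange(ny + 1) * h)
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        elements = np.column_stack(
            [node_id(r, c), node_id(r, c + 1), node_id(r + 1, c + 1), node_id(r + 1, c)]
        )
    else:
        fine = _q8_node_grid(ny, nx)
        fr, fc = np.nonzero(fine >= 0)
        coords = np.empty((fr.size, 2))
        coords[fine[fr, fc]] = np.column_stack([fc * h / 2, fr * h / 2])
        elements = np.column_stack(
            [
                fine[2 * r, 2 * c],
                fine[2 * r, 2 * c + 2],
                fine[2 * r + 2, 2 * c + 2],
                fine[2 * r + 2, 2 * c],
                fine[2 * r, 2 * c + 1],
                fine[2 * r + 1, 2 * c + 2],
                fine[2 * r + 2, 2 * c + 1],
                fine[2 * r + 1, 2 * c],
            ]
        )

    return FEMesh(
        node_coords=coords,
        elements=elements,
        E=material_map.E.ravel().astype(float),
        nu=material_map.nu.ravel().astype(float),
        order=order,
        thickness_mm=1.0,
        material=material_map.tissue.ravel().astype(np.int64),
        grid_shape=(ny, nx),
    )


def mesh_from_mapping(
    mapping: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]],
    n_u: int,
    n_v: int,
    E: float,
    nu: float,
    order: str = "q4",
    thickness_mm: float = 1.0,
) -> FEMesh:
    """Structured mesh of ``n_u x n_v`` elements over the unit square
    transported by ``mapping(u, v) -> (x, y)``.

    For Q8, midside nodes are evaluated from the mapping at parameter
    midpoints, so curved boundaries (e.g. a hole arc) are represented
    quadratically.
    """
    order = order.lower()
    r, c = np.divmod(np.arange(n_u * n_v), n_u)
    if order == "q4":
        uu, vv = np.meshgrid(np.linspace(0, 1, n_u + 1), np.linspace(0, 1, n_v + 1))
        x, y = mapping(uu.ravel(), vv.ravel())
        coords = np.column_stack([x, y])
        nid = lambda rr, cc: rr * (n_u + 1) + cc  # noqa: E731
        elements = np.column_stack(
            [nid(r, c), nid(r, c + 1), nid(r + 1, c + 1), nid(r + 1, c)]
        )
    elif order == "q8":
        fine = _q8_node_grid(n_v, n_u)
        fr, fc = np.nonzero(fine >= 0)
        x, y = mapping(fc / (2 * n_u), fr / (2 * n_v))
        coords = np.empty((fr.size, 2))
        coords[fine[fr, fc]] = np.column_stack([x, y])
        elements = np.column_stack(
            [
                fine[2 * r, 2 * c],
                fine[2 * r, 2 * c + 2],
                fine[2 * r + 2, 2 * c + 2],
                fine[2 * r + 2, 2 * c],
                fine[2 * r, 2 * c + 1],
                fine[2 * r + 1, 2 * c + 2],
                fine[2 * r + 2, 2 * c + 1],
                fine[2 * r + 1, 2 * c],
            ]
        )
    else:
        raise ValueError(f"unknown element order {order!r}")

    ne = n_u * n_v
    return FEMesh(
        node_coords=coords,
        elements=elements,
        E=np.full(ne, float(E)),
        nu=np.full(ne, float(nu)),
        order=order,
        thickness_mm=thickness_mm,
        grid_shape=(n_v, n_u),
    )


def deactivate_elements(mesh: FEMesh, keep: np.ndarray) -> FEMesh:
    """Drop elements where ``keep`` is False and renumber nodes.

    The remaining mesh must be a single piece connected to the base
    (bottom-most remaining row); otherwise floating fragments would make
    the stiffness matrix singular and a ``ValueError`` is raised.
    """
    keep = np.asarray(keep, dtype=bool)
    if keep.shape != (mesh.n_elements,):
        raise ValueError("keep mask must have one entry per element")
    if not keep.any():
        raise ValueError("cannot deactivate every element")
    elems = mesh.elements[keep]

    used = np.unique(elems)
    remap = np.full(mesh.n_nodes, -1, dtype=np.int64)
    remap[used] = np.arange(used.size)
    sub = FEMesh(
        node_coords=mesh.node_coords[used],
        elements=remap[elems],
        E=mesh.E[keep],
        nu=mesh.nu[keep],
        order=mesh.order,
        thickness_mm=mesh.thickness_mm,
        material=None if mesh.material is None else mesh.material[keep],
        grid_shape=None,
    )

    # connectivity check: every element must reach the base through shared nodes
    ne = sub.n_elements
    rows = np.repeat(np.arange(ne), sub.elements.shape[1])
    cols = sub.elements.ravel()
    inc = csr_matrix((np.ones(rows.size), (rows, cols)), shape=(ne, sub.n_nodes))
    n_comp, elem_comp = csgraph.connected_components((inc @ inc.T) > 0)
    if n_comp > 1:
        base = sub.bottom_nodes()
        base_elems = np.unique(rows[np.isin(cols, base)])
        anchored = np.unique(elem_comp[base_elems])
        if not np.isin(elem_comp, anchored).all():
            raise ValueError("deactivation left fragments disconnected from the base")
    return sub
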