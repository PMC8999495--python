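"""2D static linear elasticity on quadrilateral meshes.

Isoparametric displacement FEM, plane stress by default (the radiograph is
treated as a unit-thickness slab; plane strain is available behind a
flag).  The physical setup mirrors a standing-load radiograph model: all
degrees of freedom are removed at the bottom edge (clamped base) and a
uniform traction of 1 N/mm^2 acts along the gravity/limb axis on the top
edge -- by default only on the segments overlying non-soft-tissue
material, i.e. the articular surface.  A roller base (vertical support
plus one lateral pin) is provided for verification problems whose closed
forms assume free lateral contraction.

Element stiffness uses Gauss quadrature (2x2 for bilinear Q4, 3x3 for
serendipity Q8); assembly is vectorised over elements.  Constraints are
applied by row/column elimination so the reduced system stays symmetric
positive definite; it is solved by sparse direct factorisation, and
reactions are recovered as ``K u - f`` on the fixed rows.  Every solve
checks the relative residual (<= 1e-8) and global equilibrium: the sum of
reactions balances the applied load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .materials import Tissue
from .mesh import FEMesh

__all__ = [
    "BoundaryConditions",
    "StaticResult",
    "element_stiffness",
    "consistent_load_vector",
    "solve_static",
    "make_standard_bc",
    "gauss_rule",
    "shape_functions",
    "constitutive_matrix",
]

#: default traction magnitude, N/mm^2, applied along the limb axis.  The
#: nominal patient weight behind the load model is 70 kg; the per-area
#: figure is the modelling input, the weight is documentation metadata.
DEFAULT_TRACTION_MPA = 1.0
REFERENCE_BODY_WEIGHT_KG = 70.0


# ---------------------------------------------------------------------------
# shape functions and quadrature

_Q4_XI = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
_Q8_XI = np.array(
    [[-1, -1], [1, -1], [1, 1], [-1, 1], [0, -1], [1, 0], [0, 1], [-1, 0]],
    dtype=float,
)


def shape_functions(order: str, xi: float, eta: float) -> tuple[np.ndarray, np.ndarray]:
    """Values N (n,) and parent-space gradients dN (n, 2) at (xi, eta)."""
    if order == "q4":
        xn, en = _Q4_XI[:, 0], _Q4_XI[:, 1]
        N = 0.25 * (1 + xi * xn) * (1 + eta * en)
        dN = np.column_stack(
            [0.25 * xn * (1 + eta * en), 0.25 * en * (1 + xi * xn)]
        )
        return N, dN
    if order == "q8":
        N = np.empty(8)
        dN = np.empty((8, 2))
        for i in range(4):
            xn, en = _Q8_XI[i]
            N[i] = 0.25 * (1 + xi * xn) * (1 + eta * en) * (xi * xn + eta * en - 1)
            dN[i, 0] = 0.25 * xn * (1 + eta * en) * (2 * xi * xn + eta * en)
            dN[i, 1] = 0.25 * en * (1 + xi * xn) * (xi * xn + 2 * eta * en)
        for i in range(4, 8):
            xn, en = _Q8_XI[i]
            if xn == 0:  # midside on a constant-eta edge
                N[i] = 0.5 * (1 - xi**2) * (1 + eta * en)
                dN[i, 0] = -xi * (1 + eta * en)
                dN[i, 1] = 0.5 * (1 - xi**2) * en
            else:  # midside on a constant-xi edge
                N[i] = 0.5 * (1 + xi * xn) * (1 - eta**2)
                dN[i, 0] = 0.5 * xn * (1 - eta**2)
                dN[i, 1] = -eta * (1 + xi * xn)
        return N, dN
    raise ValueError(f"unknown element order {order!r}")


def gauss_rule(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product Gauss-Legendre points/weights on [-1, 1]^2."""
    p, w = np.polynomial.legendre.leggauss(n)
    xi, eta = np.meshgrid(p, p)
    wx, wy = np.meshgrid(w, w)
    return np.column_stack([xi.ravel(), eta.ravel()]), (wx * wy).ravel()


def constitutive_matrix(E, nu, plane: str = "stress") -> np.ndarray:
    """Plane stress/strain elasticity matrix; broadcasts over element arrays."""
    E = np.asarray(E, dtype=float)
    nu = np.asarray(nu, dtype=float)
    D = np.zeros(np.broadcast_shapes(E.shape, nu.shape) + (3, 3))
    if plane == "stress":
        f = E / (1 - nu**2)
        D[..., 0, 0] = D[..., 1, 1] = f
        D[..., 0, 1] = D[..., 1, 0] = f * nu
        D[..., 2, 2] = f * (1 - nu) / 2
    elif plane == "strain":
        f = E / ((1 + nu) * (1 - 2 * nu))
        D[..., 0, 0] = D[..., 1, 1] = f * (1 - nu)
        D[..., 0, 1] = D[..., 1, 0] = f * nu
        D[..., 2, 2] = f * (1 - 2 * nu) / 2
    else:
        raise ValueError(f"unknown plane assumption {plane!r}")
    return D


def _batched_stiffness(
    coords: np.ndarray, D: np.ndarray, order: str, thickness: float, n_gauss: int | None = None
) -> np.ndarray:
    """Element stiffness matrices for a batch of elements.

    coords: (ne, n, 2); D: (ne, 3, 3).  Returns (ne, 2n, 2n).
    """
    nn = coords.shape[1]
    pts, wts = gauss_rule(n_gauss or (2 if order == "q4" else 3))
    ne = coords.shape[0]
    Ke = np.zeros((ne, 2 * nn, 2 * nn))
    for (xi, eta), w in zip(pts, wts):
        _, dN = shape_functions(order, xi, eta)
        J = np.einsum("ni,enj->eij", dN, coords)  # J[i,j] = dx_j/dxi_i
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        if np.any(detJ <= 0):
            raise ValueError("non-positive Jacobian: degenerate element geometry")
        invJ = (
            np.stack(
                [
                    np.stack([J[:, 1, 1], -J[:, 0, 1]], axis=-1),
                    np.stack([-J[:, 1, 0], J[:, 0, 0]], axis=-1),
                ],
                axis=1,
            )
            / detJ[:, None, None]
        )
        dNdx = np.einsum("eji,ni->enj", invJ, dN)  # (ne, n, 2)
        B = np.zeros((ne, 3, 2 * nn))
        B[:, 0, 0::2] = dNdx[:, :, 0]
        B[:, 1, 1::2] = dNdx[:, :, 1]
        B[:, 2, 0::2] = dNdx[:, :, 1]
        B[:, 2, 1::2] = dNdx[:, :, 0]
        Ke += (w * thickness) * detJ[:, None, None] * np.einsum(
            "eai,eab,ebj->eij", B, D, B
        )
    return Ke


def element_stiffness(
    E_MPa: float,
    nu: float,
    element_geometry: np.ndarray,
    order: str = "q4",
    plane: str = "stress",
    thickness_mm: float = 1.0,
    n_gauss: int | None = None,
) -> np.ndarray:
    """Stiffness matrix of a single element (8x8 for Q4, 16x16 for Q8)."""
    if not E_MPa > 0:
        raise ValueError("Young's modulus must be positive")
    if not 0 < nu < 0.5:
        raise ValueError("Poisson ratio must lie in (0, 0.5)")
    coords = np.asarray(element_geometry, dtype=float)[None]
    D = constitutive_matrix(E_MPa, nu, plane)[None]
    return _batched_stiffness(coords, D, order.lower(), thickness_mm, n_gauss)[0]


def assemble_stiffness(mesh: FEMesh, plane: str = "stress"):
    """Global sparse stiffness matrix (CSR)."""
    coords = mesh.node_coords[mesh.elements]
    D = constitutive_matrix(mesh.E, mesh.nu, plane)
    Ke = _batched_stiffness(coords, D, mesh.order, mesh.thickness_mm)
    nn = mesh.elements.shape[1]
    dofs = np.empty((mesh.n_elements, 2 * nn), dtype=np.int64)
    dofs[:, 0::2] = 2 * mesh.elements
    dofs[:, 1::2] = 2 * mesh.elements + 1
    rows = np.repeat(dofs, 2 * nn, axis=1).ravel()
    cols = np.tile(dofs, (1, 2 * nn)).ravel()
    K = coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(mesh.n_dofs, mesh.n_dofs)
    ).tocsr()
    return K


# ---------------------------------------------------------------------------
# boundary conditions


@dataclass
class BoundaryConditions:
    """Zero-displacement constraints plus edge tractions.

    ``load_edges`` is a list of ``(nodes, (tx, ty))`` where ``nodes`` is
    ``[end1, end2]`` for a linear edge or ``[end1, end2, mid]`` for a
    quadratic edge and the traction is in N/mm^2.
    """

    fixed_x: np.ndarray  # node ids with u_x = 0
    fixed_y: np.ndarray  # node ids with u_y = 0
    load_edges: list = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        self.fixed_x = np.asarray(self.fixed_x, dtype=np.int64)
        self.fixed_y = np.asarray(self.fixed_y, dtype=np.int64)
        if self.fixed_x.size == 0 and self.fixed_y.size == 0:
            raise ValueError("at least one constrained node is required")

    def fixed_dofs(self) -> np.ndarray:
        return np.unique(np.concatenate([2 * self.fixed_x, 2 * self.fixed_y + 1]))


def _top_edges(mesh: FEMesh, element_filter: np.ndarray | None = None) -> list:
    """Top-boundary element edges [(end1, end2, mid?), ...] for a pixel grid."""
    if mesh.grid_shape is None:
        raise ValueError("top-edge lookup requires a structured pixel mesh")
    ny, nx = mesh.grid_shape
    edges = []
    for c in range(nx):
        e = c  # first element row
        if element_filter is not None and not element_filter[e]:
            continue
        conn = mesh.elements[e]
        if mesh.order == "q4":
            edges.append(np.array([conn[0], conn[1]]))
        else:
            edges.append(np.array([conn[0], conn[1], conn[4]]))
    return edges


def make_standard_bc(
    mesh: FEMesh,
    traction_mpa: float = DEFAULT_TRACTION_MPA,
    base: str = "clamped",
    load_region: str = "tissue",
) -> BoundaryConditions:
    """Gravity-load boundary conditions for a radiograph model.

    base
        ``"clamped"`` removes both displacement components of every node
        on the bottom edge (the study configuration); ``"roller"`` fixes
        only the vertical component and pins one central node laterally
        (used by uniform-state verification problems).
    load_region
        ``"tissue"`` loads only top-edge segments whose element is not
        soft tissue (the articular surface); ``"full"`` loads the whole
        top edge.
    """
    if not traction_mpa > 0:
        raise ValueError("traction magnitude must be positive")
    bottom = mesh.bottom_nodes()
    if base == "clamped":
        fixed_x, fixed_y = bottom, bottom
    elif base == "roller":
        mid = bottom[np.argmin(np.abs(mesh.node_coords[bottom, 0] - mesh.node_coords[:, 0].mean()))]
        fixed_x, fixed_y = np.array([mid]), bottom
    else:
        raise ValueError(f"unknown base constraint {base!r}")

    if load_region == "tissue":
        if mesh.material is None:
            raise ValueError("mesh has no material classes; use load_region='full'")
        elem_filter = mesh.material != Tissue.SOFT_TISSUE
    elif load_region == "full":
        elem_filter = None
    else:
        raise ValueError(f"unknown load region {load_region!r}")

    edges = _top_edges(mesh, elem_filter)
    if not edges:
        raise ValueError("no loadable top-edge segments (top edge is all soft tissue)")
    # traction along +y: pushes toward the base (compression)
    load_edges = [(e, (0.0, float(traction_mpa))) for e in edges]
    return BoundaryConditions(
        fixed_x=fixed_x,
        fixed_y=fixed_y,
        load_edges=load_edges,
        description=f"{base} base, {traction_mpa} MPa axial traction on {load_region} top edge",
    )


def consistent_load_vector(mesh: FEMesh, bc: BoundaryConditions) -> np.ndarray:
    """Work-equivalent nodal forces of the edge tractions.

    A straight linear edge of length L receives (1/2, 1/2) t L;
    a quadratic edge receives (1/6, 1/6, 2/3) t L on (end, end, mid).
    Total force equals traction x total loaded length x thickness.
    """
    if not bc.load_edges:
        raise ValueError("empty load-edge set")
    f = np.zeros(mesh.n_dofs)
    t_fac = mesh.thickness_mm
    for nodes, (tx, ty) in bc.load_edges:
        nodes = np.asarray(nodes, dtype=np.int64)
        L = float(np.linalg.norm(mesh.node_coords[nodes[1]] - mesh.node_coords[nodes[0]]))
        if nodes.size == 2:
            w = np.array([0.5, 0.5])
        elif nodes.size == 3:
            w = np.array([1 / 6, 1 / 6, 2 / 3])
        else:
            raise ValueError("load edge must have 2 or 3 nodes")
        f[2 * nodes] += tx * L * t_fac * w
        f[2 * nodes + 1] += ty * L * t_fac * w
    return f


# ---------------------------------------------------------------------------
# solve


@dataclass
class StaticResult:
    """Displacements plus the equilibrium bookkeeping of one static solve."""

    u: np.ndarray  # (n_nodes, 2) mm
    f: np.ndarray  # (n_dofs,) applied nodal forces, N
    reactions: np.ndarray  # (n_dofs,) K u - f on fixed rows, zero elsewhere
    fixed_dofs: np.ndarray
    residual_rel: float
    plane: str

    @property
    def total_applied(self) -> np.ndarray:
        return np.array([self.f[0::2].sum(), self.f[1::2].sum()])

    @property
    def total_reaction(self) -> np.ndarray:
        return np.array([self.reactions[0::2].sum(), self.reactions[1::2].sum()])

    @property
    def equilibrium_error(self) -> float:
        """|sum reactions + sum applied| / |sum applied|."""
        applied = self.total_applied
        return float(
            np.linalg.norm(self.total_reaction + applied) / np.linalg.norm(applied)
        )


def solve_static(
    mesh: FEMesh,
    bc: BoundaryConditions,
    plane: str = "stress",
    extra_forces: np.ndarray | None = None,
) -> StaticResult:
    """Solve K u = f with zero prescribed displacements on the fixed DOFs.

    ``extra_forces`` adds caller-assembled nodal forces (N) to the edge
    tractions.  Uses sparse direct factorisation on the eliminated
    (free-free) block.  Raises if the relative residual exceeds 1e-8.
    """
    K = assemble_stiffness(mesh, plane)
    f = (
        consistent_load_vector(mesh, bc)
        if bc.load_edges
        else np.zeros(mesh.n_dofs)
    )
    if extra_forces is not None:
        f = f + np.asarray(extra_forces, dtype=float)
    fixed = bc.fixed_dofs()
    if fixed.size == 0:
        raise ValueError("unconstrained system")
    free = np.setdiff1d(np.arange(mesh.n_dofs), fixed, assume_unique=False)

    u = np.zeros(mesh.n_dofs)
    Kcc = K.tocsc()
    K_ff = Kcc[free][:, free]
    f_f = f[free]
    if np.any(f_f):
        u[free] = spsolve(K_ff.tocsc(), f_f)
    fn = np.linalg.norm(f_f)
    residual = float(np.linalg.norm(K_ff @ u[free] - f_f) / fn) if fn > 0 else 0.0
    if residual > 1e-8:
        raise RuntimeError(f"solver residual {residual:.3e} exceeds 1e-8")

    reactions = np.zeros(mesh.n_dofs)
    r_full = K @ u - f
    reactions[fixed] = r_full[fixed]

    return StaticResult(
        u=u.reshape(-1, 2),
        f=f,
        reactions=reactions,
        fixed_dofs=fixed,
        residual_rel=residual,
        plane=plane,
    )
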