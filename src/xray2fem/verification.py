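"""Closed-form verification benchmarks for the elasticity solver.

These problems have analytic solutions and exercise the same element,
assembly and solve machinery as the radiograph pipeline:

* **Uniaxial column (patch test)** -- a homogeneous rectangular column
  under uniform axial traction with a roller base reproduces the constant
  stress state sigma_yy = -t exactly; any discretisation error indicates a
  defect in the element formulation.
* **Kirsch plate with a circular hole** -- remote uniaxial tension around
  a traction-free hole concentrates the hoop stress to 3x the remote value
  at the hole equator.  A quarter plate with symmetry conditions is meshed
  boundary-fitted by transfinite interpolation between the hole arc and
  the outer square edges, with geometric radial grading so the innermost
  element layer is thin enough to sample the steep stress gradient.
* **Shear-loaded cantilever** -- tip deflection against the Timoshenko
  beam closed form ``P L^3 / (3 E I) + P L / (kappa G A)`` (kappa = 5/6
  for a rectangular section).
"""

from __future__ import annotations

import numpy as np

from .mesh import FEMesh, mesh_from_mapping
from .solver import BoundaryConditions, solve_static
from .stress import recover_stresses

__all__ = [
    "uniaxial_column",
    "kirsch_plate",
    "cantilever_tip_deflection",
]


def uniaxial_column(
    nx: int = 20,
    ny: int = 100,
    E: float = 5000.0,
    nu: float = 0.32,
    traction: float = 1.0,
    order: str = "q4",
    plane: str = "stress",
    base: str = "roller",
    h: float = 1.0,
):
    """Homogeneous column under uniform axial compression.

    Returns ``(result, stress, mesh)``.  With a roller base the exact
    solution is the uniform state sigma_yy = -traction with tip
    displacement ``ny*h * traction / E`` (plane stress) or
    ``ny*h * traction (1 - nu^2) / E`` (plane strain).
    """
    mapping = lambda u, v: (u * nx * h, v * ny * h)  # noqa: E731
    mesh = mesh_from_mapping(mapping, nx, ny, E=E, nu=nu, order=order)
    bottom = mesh.bottom_nodes()
    if base == "roller":
        mid = bottom[np.argmin(np.abs(mesh.node_coords[bottom, 0] - nx * h / 2))]
        fixed_x, fixed_y = np.array([mid]), bottom
    elif base == "clamped":
        fixed_x, fixed_y = bottom, bottom
    else:
        raise ValueError(f"unknown base {base!r}")
    edges = _boundary_edges(mesh, lambda x, y: y < 1e-12)
    bc = BoundaryConditions(
        fixed_x=fixed_x,
        fixed_y=fixed_y,
        load_edges=[(e, (0.0, traction)) for e in edges],
        description=f"{base} base uniaxial column",
    )
    result = solve_static(mesh, bc, plane=plane)
    stress = recover_stresses(result, mesh)
    return result, stress, mesh


def _boundary_edges(mesh: FEMesh, on_boundary) -> list[np.ndarray]:
    """Element edges whose corner (and mid) nodes all satisfy the predicate."""
    x, y = mesh.node_coords[:, 0], mesh.node_coords[:, 1]
    flags = on_boundary(x, y)
    edges = []
    corner_pairs = ((0, 1), (1, 2), (2, 3), (3, 0))
    for conn in mesh.elements:
        for k, (i, j) in enumerate(corner_pairs):
            nodes = [conn[i], conn[j]]
            if mesh.order == "q8":
                nodes.append(conn[4 + k])
            if all(flags[nd] for nd in nodes):
                edges.append(np.array(nodes))
    return edges


def _quarter_plate_mapping(a: float, W: float, growth: float):
    """Transfinite map: unit square -> quarter plate with hole.

    u parametrises the angular direction (0 at the x axis, 1 at the y
    axis); v the radial direction (0 on the hole arc, 1 on the outer
    boundary, a two-segment polyline (W,0)-(W,W)-(0,W)).  ``growth`` > 1
    expands radial layers geometrically away from the hole, so the first
    layer -- which samples the steep hoop-stress gradient -- is thin.
    """

    def mapping(u, v):
        # u runs from the y axis (u=0) to the x axis (u=1) so that the
        # (u, v) frame is right-handed in (x, y)
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        theta = (1 - u) * np.pi / 2
        xi, yi = a * np.cos(theta), a * np.sin(theta)
        xo = np.where(u <= 0.5, 2 * u * W, W)
        yo = np.where(u <= 0.5, W, (2 - 2 * u) * W)
        t = (growth**v - 1) / (growth - 1) if growth != 1 else v
        return xi + t * (xo - xi), yi + t * (yo - yi)

    return mapping


def kirsch_plate(
    a: float = 10.0,
    W: float = 100.0,
    n_theta: int = 32,
    n_r: int = 32,
    order: str = "q8",
    E: float = 5000.0,
    nu: float = 0.3,
    tension: float = 1.0,
):
    """Quarter plate with a central hole under remote x tension.

    Symmetry: u_x = 0 on the x = 0 edge, u_y = 0 on the y = 0 edge;
    uniform traction ``tension`` in +x on the outer x = W edge.  Returns
    ``(scf, result, stress, mesh)`` where ``scf`` is the maximum
    element-mean sigma_xx over the innermost ring, divided by the remote
    tension (infinite-plate value 3.0).
    """
    # growth 100 over the radial span puts the first layer at ~0.2 mm for
    # the defaults, thin enough to read the hole-surface concentration
    mapping = _quarter_plate_mapping(a, W, growth=100.0)
    mesh = mesh_from_mapping(mapping, n_theta, n_r, E=E, nu=nu, order=order)

    tol = 1e-9
    fixed_x = mesh.nodes_where(lambda x, y: x < tol)
    fixed_y = mesh.nodes_where(lambda x, y: y < tol)
    edges = _boundary_edges(mesh, lambda x, y: x > W - tol)
    bc = BoundaryConditions(
        fixed_x=fixed_x,
        fixed_y=fixed_y,
        load_edges=[(e, (tension, 0.0)) for e in edges],
        description="Kirsch quarter plate",
    )
    result = solve_static(mesh, bc, plane="stress")
    stress = recover_stresses(result, mesh)

    # hoop stress peaks at the hole point on the y axis; restrict to the
    # innermost element ring to read the concentration there
    inner = np.arange(mesh.n_elements).reshape(n_r, n_theta)[0]
    scf = float(stress.sigma_xx[inner].max() / tension)
    return scf, result, stress, mesh


def kirsch_strain_energy(n_theta: int, n_r: int, order: str = "q8", **kw) -> float:
    """Total strain energy 0.5 u.f of the Kirsch problem at a given mesh.

    For a traction-driven problem the displacement FEM underestimates the
    energy, and the energy-norm discretisation error is
    ``sqrt(U_exact - U_h)``; monotone growth of U_h under refinement is
    equivalent to monotone decay of the error.
    """
    _, result, _, _ = kirsch_plate(n_theta=n_theta, n_r=n_r, order=order, **kw)
    return float(0.5 * result.f @ result.u.ravel())


def cantilever_tip_deflection(
    L: float = 200.0,
    depth: float = 20.0,
    n_x: int = 200,
    n_y: int = 20,
    E: float = 1000.0,
    nu: float = 0.3,
    P: float = 10.0,
    order: str = "q8",
):
    """End-loaded cantilever; returns (fem_tip, timoshenko_tip).

    The beam spans x in [0, L] with the section centred on y = 0.  Support
    conditions follow the elasticity closed form: u_x = 0 over the root
    section, u_y = 0 at the root centroid; the shear load is applied as
    the parabolic traction ``tau(y) = P/(2I) (c^2 - y^2)`` on the tip
    section, integrated consistently edge by edge.
    """
    c = depth / 2
    I = depth**3 / 12  # noqa: E741
    mapping = lambda u, v: (u * L, v * depth - c)  # noqa: E731
    mesh = mesh_from_mapping(mapping, n_x, n_y, E=E, nu=nu, order=order)

    tol = 1e-9
    root = mesh.nodes_where(lambda x, y: x < tol)
    centroid = root[np.argmin(np.abs(mesh.node_coords[root, 1]))]

    bc = BoundaryConditions(
        fixed_x=root,
        fixed_y=np.array([centroid]),
        load_edges=[],
        description="cantilever, parabolic end shear",
    )
    # consistent nodal loads of the parabolic end shear (downward, -y),
    # integrated edge by edge with 3-pt Gauss (exact for these integrands)
    f = np.zeros(mesh.n_dofs)
    gp, gw = np.polynomial.legendre.leggauss(3)
    for nodes in _boundary_edges(mesh, lambda x, y: x > L - tol):
        ys = mesh.node_coords[nodes, 1]
        half = (ys[1] - ys[0]) / 2
        mid = (ys[1] + ys[0]) / 2
        for t, w in zip(gp, gw):
            y = mid + half * t
            tau = P / (2 * I) * (c**2 - y**2)
            if nodes.size == 2:
                N = np.array([(1 - t) / 2, (1 + t) / 2])
            else:
                N = np.array([t * (t - 1) / 2, t * (t + 1) / 2, 1 - t**2])
            f[2 * nodes + 1] += -tau * N * w * abs(half) * mesh.thickness_mm
    result = solve_static(mesh, bc, plane="stress", extra_forces=f)

    tip = mesh.nodes_where(lambda x, y: (x > L - tol) & (np.abs(y) < tol))[0]
    fem_tip = float(result.u[tip, 1])

    G = E / (2 * (1 + nu))
    kappa = 5 / 6
    A = depth * mesh.thickness_mm
    timo = -(P * L**3 / (3 * E * I) + P * L / (kappa * G * A))
    return fem_tip, timo
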