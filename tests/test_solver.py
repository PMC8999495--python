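"""Element stiffness, load vectors, and static solves."""

import numpy as np
import pytest

from xray2fem.mesh import mesh_from_mapping
from xray2fem.solver import (
    BoundaryConditions,
    consistent_load_vector,
    element_stiffness,
    make_standard_bc,
    solve_static,
)
from xray2fem.verification import uniaxial_column

# ---------------------------------------------------------------------------
# independent element-stiffness oracle: own shape functions, 10x10 Gauss


def _oracle_shape_grad(order, xi, eta):
    if order == "q4":
        s = [(-1, -1), (1, -1), (1, 1), (-1, 1)]
        return np.array(
            [[0.25 * a * (1 + eta * b), 0.25 * b * (1 + xi * a)] for a, b in s]
        )
    # Q8 serendipity, differentiated by complex-step differentiation of
    # the value formulas (machine-precision, no cancellation), so the
    # oracle shares no derivative code with the solver
    def val(xi, eta):
        s = [(-1, -1), (1, -1), (1, 1), (-1, 1), (0, -1), (1, 0), (0, 1), (-1, 0)]
        out = np.empty(8, dtype=complex)
        for i, (a, b) in enumerate(s):
            if i < 4:
                out[i] = 0.25 * (1 + xi * a) * (1 + eta * b) * (xi * a + eta * b - 1)
            elif a == 0:
                out[i] = 0.5 * (1 - xi**2) * (1 + eta * b)
            else:
                out[i] = 0.5 * (1 + xi * a) * (1 - eta**2)
        return out

    h = 1e-30
    dxi = val(xi + 1j * h, eta).imag / h
    deta = val(xi, eta + 1j * h).imag / h
    return np.column_stack([dxi, deta])


def oracle_stiffness(E, nu, coords, order, plane="stress", n_gp=10):
    if plane == "stress":
        f = E / (1 - nu**2)
        D = np.array([[f, f * nu, 0], [f * nu, f, 0], [0, 0, f * (1 - nu) / 2]])
    else:
        f = E / ((1 + nu) * (1 - 2 * nu))
        D = np.array(
            [[f * (1 - nu), f * nu, 0], [f * nu, f * (1 - nu), 0], [0, 0, f * (1 - 2 * nu) / 2]]
        )
    p, w = np.polynomial.legendre.leggauss(n_gp)
    nn = coords.shape[0]
    K = np.zeros((2 * nn, 2 * nn))
    for xi, wx in zip(p, w):
        for eta, wy in zip(p, w):
            dN = _oracle_shape_grad(order, xi, eta)
            J = dN.T @ coords
            detJ = np.linalg.det(J)
            dNdx = dN @ np.linalg.inv(J).T
            B = np.zeros((3, 2 * nn))
            B[0, 0::2] = dNdx[:, 0]
            B[1, 1::2] = dNdx[:, 1]
            B[2, 0::2] = dNdx[:, 1]
            B[2, 1::2] = dNdx[:, 0]
            K += wx * wy * detJ * B.T @ D @ B
    return K


def _random_quad(rng, order):
    """Random affine (parallelogram) element.

    Affine geometry keeps the Jacobian constant, so the solver's standard
    2x2 / 3x3 Gauss rules integrate the stiffness exactly and a high-order
    oracle must agree to rounding; general distorted quads would differ by
    the (legitimate) quadrature truncation of the rational integrand.
    """
    a = rng.uniform(0, np.pi / 3)
    b = rng.uniform(0, np.pi / 3)
    v1 = rng.uniform(0.3, 2.0) * np.array([np.cos(a), np.sin(a)])
    v2 = rng.uniform(0.3, 2.0) * np.array([-np.sin(b), np.cos(b)])
    p0 = rng.uniform(-1, 1, size=2)
    corners = np.array([p0, p0 + v1, p0 + v1 + v2, p0 + v2])
    if order == "q4":
        return corners
    mids = (corners + np.roll(corners, -1, axis=0)) / 2
    return np.vstack([corners, mids])


UNIT_SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)


class TestElementStiffness:
    @pytest.mark.parametrize("order", ["q4", "q8"])
    def test_symmetry(self, order):
        rng = np.random.default_rng(7)
        for _ in range(5):
            K = element_stiffness(
                rng.uniform(1, 1e5), rng.uniform(0.05, 0.45), _random_quad(rng, order), order
            )
            assert np.allclose(K, K.T, rtol=1e-12, atol=1e-12 * np.abs(K).max())

    @pytest.mark.parametrize("order, size", [("q4", 8), ("q8", 16)])
    def test_three_rigid_body_modes(self, order, size):
        geom = UNIT_SQUARE if order == "q4" else np.vstack(
            [UNIT_SQUARE, (UNIT_SQUARE + np.roll(UNIT_SQUARE, -1, axis=0)) / 2]
        )
        K = element_stiffness(1.0, 0.3, geom, order)
        assert K.shape == (size, size)
        w = np.linalg.eigvalsh(K)
        assert (np.abs(w[:3]) < 1e-10 * w[-1]).all()
        assert (w[3:] > 1e-8 * w[-1]).all()

    @pytest.mark.parametrize("order", ["q4", "q8"])
    @pytest.mark.parametrize("plane", ["stress", "strain"])
    def test_matches_independent_quadrature_oracle(self, order, plane):
        rng = np.random.default_rng(42)
        for _ in range(5):
            E, nu = rng.uniform(1, 1e5), rng.uniform(0.05, 0.45)
            coords = _random_quad(rng, order)
            K = element_stiffness(E, nu, coords, order, plane)
            K_ref = oracle_stiffness(E, nu, coords, order, plane)
            assert np.allclose(K, K_ref, rtol=1e-9, atol=1e-9 * np.abs(K_ref).max())

    def test_degenerate_geometry_rejected(self):
        inverted = UNIT_SQUARE[::-1]  # clockwise ordering: negative Jacobian
        with pytest.raises(ValueError, match="Jacobian"):
            element_stiffness(1.0, 0.3, inverted, "q4")
        collinear = np.array([[0, 0], [1, 0], [2, 0], [3, 0]], dtype=float)
        with pytest.raises(ValueError, match="Jacobian"):
            element_stiffness(1.0, 0.3, collinear, "q4")

    def test_nonphysical_material_rejected(self):
        with pytest.raises(ValueError):
            element_stiffness(-1.0, 0.3, UNIT_SQUARE, "q4")
        with pytest.raises(ValueError):
            element_stiffness(1.0, 0.55, UNIT_SQUARE, "q4")


class TestLoadVector:
    def _column(self, order, nx=2, ny=2):
        mapping = lambda u, v: (u * nx, v * ny)  # noqa: E731
        return mesh_from_mapping(mapping, nx, ny, E=1000.0, nu=0.3, order=order)

    def test_q4_edge_splits_half_half(self):
        mesh = self._column("q4", nx=1, ny=1)
        bc = BoundaryConditions(
            fixed_x=[3], fixed_y=[2, 3], load_edges=[(np.array([0, 1]), (0.0, 1.0))]
        )
        f = consistent_load_vector(mesh, bc)
        assert f[1] == pytest.approx(0.5)
        assert f[3] == pytest.approx(0.5)
        assert f.sum() == pytest.approx(1.0)

    def test_q8_edge_weights_match_1d_quadrature_oracle(self):
        # oracle: integrate the quadratic edge shape functions exactly
        p, w = np.polynomial.legendre.leggauss(3)
        N = lambda t: np.array([t * (t - 1) / 2, t * (t + 1) / 2, 1 - t**2])  # noqa: E731
        weights = sum(wi * N(ti) for ti, wi in zip(p, w)) / 2  # edge length 1
        assert np.allclose(weights, [1 / 6, 1 / 6, 2 / 3])

        mesh = self._column("q8", nx=1, ny=1)
        # the top edge of the single element: corners 0, 1 and mid 4
        bc = BoundaryConditions(
            fixed_x=[2], fixed_y=[2, 3], load_edges=[(mesh.elements[0][[0, 1, 4]], (0.0, 1.0))]
        )
        f = consistent_load_vector(mesh, bc)
        loaded = f[f != 0]
        assert sorted(loaded) == pytest.approx([1 / 6, 1 / 6, 2 / 3])

    def test_total_force_is_traction_times_length(self, solved_phantom_cache):
        _, _, _, mesh, result, _ = solved_phantom_cache("A1", "GNF", seed=1)
        total = result.total_applied
        assert total[0] == pytest.approx(0.0, abs=1e-12)
        # 1 N/mm^2 x loaded length x 1 mm thickness, loaded length = whole mm
        assert total[1] == pytest.approx(round(total[1]))
        assert total[1] > 0

    def test_empty_load_edges_rejected(self):
        mesh = self._column("q4")
        bc = BoundaryConditions(fixed_x=[0], fixed_y=[0])
        with pytest.raises(ValueError, match="empty"):
            consistent_load_vector(mesh, bc)


class TestStaticSolve:
    def test_zero_traction_gives_zero_displacement(self):
        mapping = lambda u, v: (u * 4, v * 4)  # noqa: E731
        mesh = mesh_from_mapping(mapping, 4, 4, E=100.0, nu=0.3)
        bottom = mesh.bottom_nodes()
        bc = BoundaryConditions(
            fixed_x=bottom,
            fixed_y=bottom,
            load_edges=[(np.array([0, 1]), (0.0, 0.0))],
        )
        result = solve_static(mesh, bc)
        assert np.abs(result.u).max() == 0.0

    @pytest.mark.parametrize("order", ["q4", "q8"])
    @pytest.mark.parametrize("plane", ["stress", "strain"])
    def test_uniaxial_column_closed_form(self, order, plane):
        # 20x100 column, E=5000, nu=0.32, roller base, 1 MPa compression:
        # uniform sigma_yy = -1; tip displacement L*sigma/E (plane stress)
        # or L*sigma*(1-nu^2)/E (plane strain)
        result, stress, mesh = uniaxial_column(order=order, plane=plane)
        assert np.abs(stress.sigma_yy + 1.0).max() < 1e-8
        assert np.abs(stress.sigma_xx).max() < 1e-8
        nu, E, L = 0.32, 5000.0, 100.0
        exact = L / E * (1.0 if plane == "stress" else 1 - nu**2)
        tip = np.abs(result.u[:, 1]).max()
        assert tip == pytest.approx(exact, rel=1e-8)

    def test_clamped_column_reaction_sum(self):
        # 20 mm wide x 1 MPa x 1 mm thickness -> 20 N held at the base
        result, _, _ = uniaxial_column(order="q4", base="clamped")
        assert result.total_reaction[1] == pytest.approx(-20.0, rel=1e-8)
        assert result.equilibrium_error < 1e-8

    def test_residual_contract(self, gnf_a2_model):
        _, _, _, _, result, _ = gnf_a2_model
        assert result.residual_rel <= 1e-8
        assert result.equilibrium_error <= 1e-8

    def test_unconstrained_system_rejected(self):
        with pytest.raises(ValueError):
            BoundaryConditions(fixed_x=[], fixed_y=[])


class TestStandardBc:
    def test_tissue_load_skips_soft_columns(self, solved_phantom_cache):
        spec, rad, mask, mesh, _, _ = solved_phantom_cache("A1", "GNF", seed=1)
        bc = make_standard_bc(mesh)
        loaded_cols = {int(mesh.node_coords[e[0], 0]) for e, _ in bc.load_edges}
        soft_top = set(np.flatnonzero(mask.labels[0] == 0).tolist())
        assert not (loaded_cols & soft_top)

    def test_full_load_spans_whole_top_edge(self, solved_phantom_cache):
        _, _, _, mesh, _, _ = solved_phantom_cache("A1", "GNF", seed=1)
        bc = make_standard_bc(mesh, load_region="full")
        assert len(bc.load_edges) == mesh.grid_shape[1]
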