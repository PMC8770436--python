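import numpy as np
import pytest

from micromotion_fem import fem
from micromotion_fem.fem import (apply_boundary_conditions, assemble,
                                 compute_strain_field, constrain,
                                 element_stiffness, solve, von_mises_strain)
from micromotion_fem.geometry import (REGION_TISSUE, box_mesh,
                                      unit_cube_mesh)
from micromotion_fem.materials import Material

UNIT_CUBE = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
], dtype=float)

MAT = Material("m", 1.0, 0.3)


def _rng_distorted_cube(seed=0, scale=0.12):
    rng = np.random.default_rng(seed)
    return UNIT_CUBE + scale * rng.standard_normal((8, 3))


def _oracle_stiffness(coords, mat, n_gauss=4):
    """Independent B-bar stiffness via explicit Voigt B matrices and
    high-order Gauss-Legendre quadrature."""
    pts, wts = np.polynomial.legendre.leggauss(n_gauss)
    corners = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]])

    def grads_at(xi):
        g = np.empty((8, 3))
        for a, s in enumerate(corners):
            g[a, 0] = s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2]) / 8
            g[a, 1] = s[1] * (1 + s[0] * xi[0]) * (1 + s[2] * xi[2]) / 8
            g[a, 2] = s[2] * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) / 8
        J = g.T @ coords
        return np.linalg.solve(J, g.T).T, np.linalg.det(J)

    def b_matrix(G):
        B = np.zeros((6, 24))
        for a in range(8):
            gx, gy, gz = G[a]
            B[0, 3 * a] = gx
            B[1, 3 * a + 1] = gy
            B[2, 3 * a + 2] = gz
            B[3, 3 * a], B[3, 3 * a + 1] = gy, gx          # gamma_xy
            B[4, 3 * a + 1], B[4, 3 * a + 2] = gz, gy      # gamma_yz
            B[5, 3 * a], B[5, 3 * a + 2] = gz, gx          # gamma_zx
        return B

    lam, mu = mat.lam, mat.mu
    m = np.array([1.0, 1, 1, 0, 0, 0])
    D = lam * np.outer(m, m) + 2 * mu * np.diag([1, 1, 1, 0.5, 0.5, 0.5])

    # Element-average dilatation row (volume integral at high order).
    vol, bbar = 0.0, np.zeros(24)
    quad = [(np.array([x, y, z]), wx * wy * wz)
            for x, wx in zip(pts, wts) for y, wy in zip(pts, wts)
            for z, wz in zip(pts, wts)]
    for xi, w in quad:
        G, detJ = grads_at(xi)
        bbar += w * detJ * G.reshape(24)
        vol += w * detJ
    bbar /= vol

    K = np.zeros((24, 24))
    for xi, w in quad:
        G, detJ = grads_at(xi)
        B = b_matrix(G)
        Bvol = np.outer(m, B[:3].sum(axis=0)) / 3.0
        Bbar = B - Bvol + np.outer(m, bbar) / 3.0
        K += w * detJ * (Bbar.T @ D @ Bbar)
    return K


class TestElementStiffness:
    @pytest.mark.parametrize("coords", [UNIT_CUBE, _rng_distorted_cube()],
                             ids=["cube", "distorted"])
    def test_symmetric_psd_with_rigid_nullspace(self, coords):
        K = element_stiffness(coords, MAT)
        assert np.abs(K - K.T).max() <= 1e-12 * np.abs(K).max()
        w = np.linalg.eigvalsh(K)
        assert w.min() >= -1e-10 * w.max()
        # 3 translations + 3 rotations annihilated
        for i in range(3):
            r = np.zeros((8, 3))
            r[:, i] = 1.0
            assert np.abs(K @ r.ravel()).max() <= 1e-10 * np.abs(K).max()
        for ax in range(3):
            r = np.zeros((8, 3))
            a, b = (ax + 1) % 3, (ax + 2) % 3
            r[:, a], r[:, b] = -coords[:, b], coords[:, a]
            assert np.abs(K @ r.ravel()).max() <= 1e-10 * np.abs(K).max()
        assert np.sum(w < 1e-10 * w.max()) == 6

    @pytest.mark.parametrize("coords,n_gauss",
                             [(UNIT_CUBE, 4), (_rng_distorted_cube(3), 2)],
                             ids=["cube_high_order", "distorted_matched_rule"])
    def test_matches_independent_quadrature_oracle(self, coords, n_gauss):
        """Cross-check against an independently coded stiffness (explicit
        Voigt B matrices). On the affine cube any rule >= 2 points is exact,
        so a 4-point oracle must agree; on a distorted element the integrand
        is rational and the oracle uses the same 2-point rule."""
        K = element_stiffness(coords, MAT)
        K_oracle = _oracle_stiffness(coords, MAT, n_gauss=n_gauss)
        assert np.abs(K - K_oracle).max() <= 1e-10 * np.abs(K_oracle).max()

    def test_inverted_element_rejected(self):
        bad = UNIT_CUBE.copy()
        bad[[0, 1]] = bad[[1, 0]]
        with pytest.raises(ValueError, match="Jacobian"):
            element_stiffness(bad, MAT)


class TestAssembly:
    def test_single_element_equals_element_matrix(self):
        mesh = unit_cube_mesh(1)
        system = assemble(mesh, {REGION_TISSUE: MAT})
        Ke = element_stiffness(mesh.nodes[mesh.elements[0]], MAT)
        edof = (3 * mesh.elements[0][:, None] + np.arange(3)).ravel()
        Kd = system.K.toarray()[np.ix_(edof, edof)]
        assert np.allclose(Kd, Ke, rtol=1e-12, atol=1e-14)

    def test_matches_dense_assembly_oracle(self):
        mesh = box_mesh(2.0, 1.0, 1.0, 2, 1, 1)
        system = assemble(mesh, {REGION_TISSUE: MAT})
        n = 3 * mesh.n_nodes
        Kd = np.zeros((n, n))
        for conn in mesh.elements:
            Ke = element_stiffness(mesh.nodes[conn], MAT)
            edof = (3 * conn[:, None] + np.arange(3)).ravel()
            for i, gi in enumerate(edof):
                for j, gj in enumerate(edof):
                    Kd[gi, gj] += Ke[i, j]
        assert np.allclose(system.K.toarray(), Kd, rtol=1e-12, atol=1e-14)

    def test_element_order_invariance(self):
        mesh = unit_cube_mesh(2)
        K1 = assemble(mesh, {REGION_TISSUE: MAT}).K
        mesh.elements = mesh.elements[::-1].copy()
        mesh.region = mesh.region[::-1].copy()
        K2 = assemble(mesh, {REGION_TISSUE: MAT}).K
        assert abs(K1 - K2).max() <= 1e-12 * abs(K1).max()

    def test_missing_material_tag_rejected(self):
        mesh = unit_cube_mesh(1)
        mesh.region[:] = 1
        with pytest.raises(KeyError):
            assemble(mesh, {REGION_TISSUE: MAT})

    def test_symmetry_and_rigid_modes_of_global_operator(self):
        mesh = box_mesh(3.0, 2.0, 1.0, 3, 2, 1)
        system = assemble(mesh, {REGION_TISSUE: MAT})
        assert system.symmetry_error() <= 1e-12
        assert system.rigid_body_residual() <= 1e-10


def _uniaxial_system(n=2, d=1.0):
    mesh = unit_cube_mesh(n)
    system = assemble(mesh, {REGION_TISSUE: MAT})
    xyz = mesh.nodes
    fixed = np.flatnonzero(np.abs(xyz[:, 0]) < 1e-12)
    moved = np.flatnonzero(np.abs(xyz[:, 0] - 1.0) < 1e-12)
    return mesh, system, fixed, moved


class TestBoundaryConditionsAndSolve:
    def test_zero_displacement_gives_zero_solution(self):
        mesh, system, fixed, moved = _uniaxial_system()
        apply_boundary_conditions(system, fixed, moved, 0.0)
        u, _ = solve(system)
        assert np.abs(u).max() == 0.0

    def test_prescribed_values_reproduced_exactly(self):
        mesh, system, fixed, moved = _uniaxial_system()
        apply_boundary_conditions(system, fixed, moved, 0.5)
        u, _ = solve(system)
        assert np.array_equal(u[moved, 0], np.full(len(moved), 0.5))
        assert np.array_equal(u[fixed], np.zeros((len(fixed), 3)))

    def test_overlapping_sets_rejected(self):
        mesh, system, fixed, moved = _uniaxial_system()
        with pytest.raises(ValueError, match="overlap"):
            apply_boundary_conditions(system, fixed, fixed, 1.0)

    def test_displacement_outside_micromotion_range_warns(self):
        mesh, system, fixed, moved = _uniaxial_system()
        with pytest.warns(UserWarning, match="micromotion"):
            apply_boundary_conditions(system, fixed, moved, 100.0)

    def test_solution_scales_linearly_with_displacement(self):
        u = {}
        for d in (0.5, 1.0):
            mesh, system, fixed, moved = _uniaxial_system(d=d)
            apply_boundary_conditions(system, fixed, moved, d)
            u[d], _ = solve(system)
        assert np.allclose(u[1.0], 2.0 * u[0.5], rtol=1e-10, atol=1e-15)

    def test_direct_and_cg_solvers_agree(self):
        mesh, system, fixed, moved = _uniaxial_system(n=3)
        apply_boundary_conditions(system, fixed, moved, 1.0)
        ud, _ = solve(system, method="direct")
        uc, info = solve(system, method="cg", tol=1e-10)
        assert info.iterations is not None
        assert np.abs(ud - uc).max() <= 1e-8 * np.abs(ud).max()


class TestStrainRecovery:
    def test_rigid_translation_gives_zero_strain(self):
        mesh = unit_cube_mesh(2)
        u = np.tile([0.3, -0.2, 0.7], (mesh.n_nodes, 1))
        f = compute_strain_field(mesh, u)
        assert np.abs(f.tensor).max() <= 1e-14
        assert np.abs(f.von_mises).max() <= 1e-14

    def test_linear_field_recovers_constant_gradient(self):
        mesh = unit_cube_mesh(3)
        alpha = 2.5e-4
        u = np.zeros((mesh.n_nodes, 3))
        u[:, 0] = alpha * mesh.nodes[:, 0]
        f = compute_strain_field(mesh, u)
        assert np.allclose(f.tensor[:, 0], alpha, rtol=1e-12)
        assert np.abs(f.tensor[:, 1:]).max() <= 1e-16

    def test_manufactured_field_convergence(self):
        """Centroid strain of a smooth manufactured displacement converges
        to the analytic gradient at rate >= 1."""
        def err_at(n):
            mesh = unit_cube_mesh(n)
            x = mesh.nodes
            u = np.zeros((mesh.n_nodes, 3))
            u[:, 0] = 1e-3 * np.sin(np.pi * x[:, 0]) * np.cos(np.pi * x[:, 1])
            f = compute_strain_field(mesh, u)
            c = mesh.element_centroids()
            exact = 1e-3 * np.pi * np.cos(np.pi * c[:, 0]) * np.cos(np.pi * c[:, 1])
            return np.abs(f.tensor[:, 0] - exact).max()

        e1, e2 = err_at(4), err_at(8)
        assert e2 <= e1 / 2.0  # rate >= 1

    def test_objectivity_rigid_offset_leaves_strain_unchanged(self):
        mesh = unit_cube_mesh(2)
        rng = np.random.default_rng(1)
        u = 1e-3 * rng.standard_normal((mesh.n_nodes, 3))
        f0 = compute_strain_field(mesh, u)
        f1 = compute_strain_field(mesh, u + np.array([5.0, -3.0, 2.0]))
        assert np.allclose(f0.tensor, f1.tensor, atol=1e-12)


class TestVonMisesStrain:
    def test_zero_tensor(self):
        assert von_mises_strain(np.zeros((3, 3))) == 0.0

    def test_uniaxial_closed_form_nu_zero(self):
        eps = np.diag([1e-3, 0.0, 0.0])
        assert von_mises_strain(eps, 0.0) == pytest.approx(1e-3, rel=1e-12)

    def test_pure_shear_matches_principal_strain_oracle(self):
        gam = 1e-3
        eps = np.array([[0, gam / 2, 0], [gam / 2, 0, 0], [0, 0, 0.0]])
        nu = 0.45
        e = np.linalg.eigvalsh(eps)  # independent principal-strain route
        expected = np.sqrt(((e[0] - e[1]) ** 2 + (e[1] - e[2]) ** 2
                            + (e[2] - e[0]) ** 2) / 2.0) / (1 + nu)
        assert von_mises_strain(eps, nu) == pytest.approx(expected, rel=1e-12)

    def test_hydrostatic_tensor_gives_zero(self):
        assert von_mises_strain(1e-3 * np.eye(3), 0.3) <= 1e-18

    def test_asymmetric_tensor_rejected(self):
        bad = np.array([[0, 1e-3, 0], [0, 0, 0], [0, 0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            von_mises_strain(bad)

    def test_invalid_nu_eff_rejected(self):
        with pytest.raises(ValueError):
            von_mises_strain(np.zeros((3, 3)), 0.6)


class TestPatchLevelExactness:
    def test_global_linear_field_reproduced_and_energy_positive(self):
        """Imposing a linear displacement on the entire boundary of a
        multi-element block reproduces it in the interior to 1e-10 and the
        strain energy is strictly positive."""
        mesh = box_mesh(1.0, 1.0, 1.0, 3, 3, 3)
        system = assemble(mesh, {REGION_TISSUE: MAT})
        A = np.array([[1.0, 0.3, 0.0], [0.3, -0.5, 0.2], [0.0, 0.2, 0.4]]) * 1e-3
        exact = mesh.nodes @ A.T
        xyz = mesh.nodes
        boundary = np.flatnonzero(np.any((xyz < 1e-12) | (xyz > 1 - 1e-12),
                                         axis=1))
        dofs = (3 * boundary[:, None] + np.arange(3)).ravel()
        constrain(system, dofs, exact[boundary].ravel())
        u, _ = solve(system, tol=1e-12, method="direct")
        assert np.abs(u - exact).max() <= 1e-10 * np.abs(exact).max()
        energy = u.ravel() @ (system.K @ u.ravel())
        assert energy > 0
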