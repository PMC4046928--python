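"""Element, assembly, and mixed-boundary-value solver correctness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from femtfm import (
    BarModel1D,
    HexMesh,
    MixedBCSet,
    RankDeficiencyError,
    SubstrateModel,
    assemble_global,
    bar_solve_mbvp,
    bar_stiffness_1d,
    hex8_stiffness,
    solve_mbvp,
)
from femtfm.errors import GeometryError, InputError, MaterialError

CORNERS = np.array([(a, b, c) for c in (0, 1) for b in (0, 1) for a in (0, 1)], float)


class TestHex8Stiffness:
    def test_symmetric_exactly(self):
        K = hex8_stiffness(1.0, 0.3, 1.0, 2.0, 0.5)
        assert np.array_equal(K, K.T)

    @pytest.mark.parametrize("nu", [0.0, 0.3, 0.45, 0.49])
    def test_exactly_six_rigid_body_modes(self, nu):
        K = hex8_stiffness(2.0, nu, 1.0, 1.0, 1.0)
        w = np.linalg.eigvalsh(K)
        assert np.all(np.abs(w[:6]) < 1e-12 * w[-1])
        assert w[6] > 1e-8 * w[-1]

    def test_rigid_translations_cost_nothing(self):
        K = hex8_stiffness(1.0, 0.45, 2.0, 1.0, 3.0)
        for ax in range(3):
            u = np.zeros(24)
            u[ax::3] = 1.0
            assert np.abs(K @ u).max() < 1e-14

    def test_uniaxial_strain_closed_form_at_nu_zero(self):
        # ν=0: uniform strain εx=0.01 on a unit cube of E=1 kPa gives the
        # uniform stress σx = E εx = 0.01 kPa; each face node carries a
        # quarter of the 1 µm² face force, 0.0025 nN, inward/outward.
        K = hex8_stiffness(1.0, 0.0, 1.0, 1.0, 1.0)
        u = np.zeros(24)
        u[0::3] = 0.01 * CORNERS[:, 0]
        f = K @ u
        expect = np.where(CORNERS[:, 0] > 0, 0.0025, -0.0025)
        np.testing.assert_allclose(f[0::3], expect, atol=1e-15)
        np.testing.assert_allclose(f[1::3], 0.0, atol=1e-15)
        np.testing.assert_allclose(f[2::3], 0.0, atol=1e-15)

    @pytest.mark.parametrize(
        "bad", [dict(E=1, nu=0.5), dict(E=-1, nu=0.3), dict(E=1, nu=0.3, hx=0.0)]
    )
    def test_invalid_material_or_geometry_rejected(self, bad):
        kw = dict(E=1.0, nu=0.3, hx=1.0, hy=1.0, hz=1.0)
        kw.update(bad)
        with pytest.raises((MaterialError, GeometryError)):
            hex8_stiffness(kw["E"], kw["nu"], kw["hx"], kw["hy"], kw["hz"])


def _substrate_for_mesh(mesh, E=1.0, nu=0.3):
    return SubstrateModel(
        E,
        nu,
        (mesh.nz - 1) * mesh.spacing_z,
        (mesh.nx - 1) * mesh.spacing_x,
        (mesh.ny - 1) * mesh.spacing_y,
    )


class TestAssembly:
    def test_single_element_mesh_equals_element_matrix(self):
        mesh = HexMesh(2, 2, 2, 1.0, 1.0, 1.0)
        K = assemble_global(mesh, _substrate_for_mesh(mesh)).toarray()
        np.testing.assert_array_equal(K, hex8_stiffness(1.0, 0.3, 1.0, 1.0, 1.0))

    def test_two_element_hand_assembly(self):
        # 3×2×2 nodes = two elements sharing the i=1 node plane; scatter the
        # element matrix by hand and compare
        mesh = HexMesh(3, 2, 2, 1.0, 1.0, 1.0)
        K = assemble_global(mesh, _substrate_for_mesh(mesh)).toarray()
        Ke = hex8_stiffness(1.0, 0.3, 1.0, 1.0, 1.0)
        ref = np.zeros((36, 36))
        for n0 in (0, 1):  # first node of each element
            nodes = [n0 + int(a + 3 * (b + 2 * c)) for (a, b, c) in CORNERS.astype(int)]
            dofs = np.array([3 * n + d for n in nodes for d in range(3)])
            ref[np.ix_(dofs, dofs)] += Ke
        np.testing.assert_allclose(K, ref, atol=1e-14)

    def test_symmetry_and_translation_equilibrium(self):
        mesh = HexMesh(4, 3, 3, 1.5, 1.0, 2.0)
        K = assemble_global(mesh, _substrate_for_mesh(mesh, nu=0.45))
        assert abs(K - K.T).max() < 1e-14
        for ax in range(3):
            u = np.zeros(mesh.n_dofs)
            u[ax::3] = 1.0
            assert np.abs(K @ u).max() < 1e-12

    def test_mesh_substrate_mismatch_rejected(self):
        mesh = HexMesh(3, 3, 3, 1.0, 1.0, 1.0)
        with pytest.raises(GeometryError):
            assemble_global(mesh, SubstrateModel(1.0, 0.3, 5.0, 2.0, 2.0))


def _uniform_strain_field(mesh, A):
    i, j, k = np.meshgrid(
        np.arange(mesh.nx), np.arange(mesh.ny), np.arange(mesh.nz), indexing="ij"
    )
    X = np.zeros((mesh.n_nodes, 3))
    idx = mesh.node_index(i, j, k).ravel()
    X[idx] = np.stack(
        [
            (i * mesh.spacing_x).ravel(),
            (j * mesh.spacing_y).ravel(),
            (k * mesh.spacing_z).ravel(),
        ],
        axis=1,
    )
    return X, X @ np.asarray(A).T


class TestSolveMbvp:
    @pytest.mark.parametrize("nu", [0.0, 0.3, 0.49])
    def test_patch_test(self, nu):
        # boundary displacements of a uniform-strain field must reproduce
        # that field exactly in the interior
        mesh = HexMesh(4, 4, 4, 1.0, 1.3, 0.8)
        K = assemble_global(mesh, _substrate_for_mesh(mesh, E=2.0, nu=nu))
        A = np.array([[0.01, 0.005, 0.002], [0.005, -0.003, 0.001], [0.002, 0.001, 0.004]])
        X, U = _uniform_strain_field(mesh, A)
        hx = np.array([mesh.spacing_x, mesh.spacing_y, mesh.spacing_z])
        extent = (np.array([mesh.nx, mesh.ny, mesh.nz]) - 1) * hx
        on_bnd = np.any((X <= 1e-12) | (X >= extent - 1e-12), axis=1)
        bc = MixedBCSet(mesh.n_dofs)
        bnd = np.flatnonzero(on_bnd)
        for ax in range(3):
            bc.prescribe_displacement(MixedBCSet.dofs(bnd, ax), U[bnd, ax])
        sol = solve_mbvp(K, bc)
        err = np.abs(sol.displacements.reshape(-1, 3) - U).max()
        assert err < 1e-10 * np.abs(U).max()

    def test_all_dirichlet_zero_gives_zero(self):
        mesh = HexMesh(3, 3, 3, 1.0, 1.0, 1.0)
        K = assemble_global(mesh, _substrate_for_mesh(mesh))
        bc = MixedBCSet(mesh.n_dofs)
        bc.prescribe_displacement(np.arange(mesh.n_dofs), 0.0)
        sol = solve_mbvp(K, bc)
        assert np.abs(sol.displacements).max() == 0.0
        assert np.abs(sol.reactions).max() == 0.0

    def test_linearity_in_boundary_data(self):
        mesh = HexMesh(4, 3, 3, 1.0, 1.0, 1.0)
        K = assemble_global(mesh, _substrate_for_mesh(mesh))
        rng = np.random.default_rng(0)
        bc = MixedBCSet(mesh.n_dofs)
        fixed = mesh.fixed_boundary_nodes()
        for ax in range(3):
            bc.prescribe_displacement(
                MixedBCSet.dofs(fixed, ax), 0.01 * rng.normal(size=fixed.size)
            )
        top = mesh.top_surface_nodes()[1:-1, 1:-1]
        bc.prescribe_force(MixedBCSet.dofs(top, 0), 0.2)
        sol1 = solve_mbvp(K, bc)
        sol3 = solve_mbvp(K, bc.scaled(3.0))
        np.testing.assert_allclose(sol3.displacements, 3 * sol1.displacements, atol=1e-12)
        np.testing.assert_allclose(sol3.reactions, 3 * sol1.reactions, atol=1e-12)

    def test_dense_brute_force_oracle(self):
        # independent oracle: dense partitioned solve with plain numpy
        mesh = HexMesh(3, 3, 3, 1.0, 1.0, 1.0)
        K = assemble_global(mesh, _substrate_for_mesh(mesh, nu=0.4))
        rng = np.random.default_rng(1)
        bc = MixedBCSet(mesh.n_dofs)
        fixed = mesh.fixed_boundary_nodes()
        for ax in range(3):
            bc.prescribe_displacement(
                MixedBCSet.dofs(fixed, ax), 0.05 * rng.normal(size=fixed.size)
            )
        free_nodes = mesh.top_surface_nodes()[1:-1, 1:-1]
        bc.prescribe_force(MixedBCSet.dofs(free_nodes, 2), rng.normal(size=free_nodes.size))
        sol = solve_mbvp(K, bc)

        Kd = K.toarray()
        d = bc.is_dirichlet
        f = ~d
        u = np.zeros(mesh.n_dofs)
        u[d] = bc.value[d]
        u[f] = np.linalg.solve(Kd[np.ix_(f, f)], bc.value[f] - Kd[np.ix_(f, d)] @ u[d])
        scale = np.abs(u).max()
        assert np.abs(sol.displacements - u).max() < 1e-10 * scale
        react = Kd @ u
        assert np.abs(sol.reactions[d] - react[d]).max() < 1e-10 * np.abs(react[d]).max()

    def test_global_equilibrium(self, small_fixture, small_disp):
        # forward solve of the two-cell fixture: reactions at fixed
        # boundaries balance the applied forces to solver tolerance
        from femtfm.domain import domain_for_grid

        dom = domain_for_grid(small_fixture.grid, small_fixture.substrate)
        bc = MixedBCSet(dom.mesh.n_dofs)
        fixed = dom.mesh.fixed_boundary_nodes()
        for ax in range(3):
            bc.prescribe_displacement(MixedBCSet.dofs(fixed, ax), 0.0)
        top = dom.top_interior_nodes()
        inner = (slice(1, -1), slice(1, -1))
        bc.prescribe_force(MixedBCSet.dofs(top, 0), small_fixture.fx[inner].ravel())
        bc.prescribe_force(MixedBCSet.dofs(top, 1), small_fixture.fy[inner].ravel())
        sol = solve_mbvp(dom.stiffness, bc)
        total_applied = np.abs(small_fixture.fx).sum() + np.abs(small_fixture.fy).sum()
        for ax in range(3):
            balance = sol.reactions[ax::3].sum() + bc.value[ax::3][~bc.is_dirichlet[ax::3]].sum()
            assert abs(balance) < 1e-8 * max(total_applied, 1.0)

    def test_unconstrained_rigid_modes_rejected(self):
        mesh = HexMesh(3, 3, 3, 1.0, 1.0, 1.0)
        K = assemble_global(mesh, _substrate_for_mesh(mesh))
        bc = MixedBCSet(mesh.n_dofs)  # pure Neumann everywhere
        with pytest.raises(RankDeficiencyError):
            solve_mbvp(K, bc)


class TestBar1D:
    def test_stiffness_matrices(self):
        np.testing.assert_array_equal(bar_stiffness_1d([1.0]), [[1, -1], [-1, 1]])
        np.testing.assert_array_equal(
            bar_stiffness_1d([1.0, 1.0]), [[1, -1, 0], [-1, 2, -1], [0, -1, 1]]
        )
        np.testing.assert_array_equal(
            bar_stiffness_1d([2.0, 3.0]), [[2, -2, 0], [-2, 5, -3], [0, -3, 3]]
        )

    @given(st.lists(st.floats(0.1, 10.0), min_size=1, max_size=6))
    @settings(deadline=None)
    def test_rigid_translation_annihilated(self, ks):
        K = bar_stiffness_1d(ks)
        assert np.array_equal(K, K.T)
        assert np.abs(K @ np.ones(len(ks) + 1)).max() < 1e-12 * max(ks)

    def test_invalid_stiffnesses_rejected(self):
        with pytest.raises(InputError):
            bar_stiffness_1d([])
        with pytest.raises(InputError):
            bar_stiffness_1d([1.0, -1.0])

    def test_contractile_cell_example(self):
        # the canonical worked example: unit springs, node 1 pinned, node 2
        # pulled by one unit, node 3 traction-free.  Force appears at the
        # zero-displacement node and displacement at the zero-force node.
        bar = BarModel1D((1.0, 1.0), (("u", 0.0), ("u", -1.0), ("f", 0.0)))
        u, F = bar_solve_mbvp(bar)
        np.testing.assert_allclose(u, [0.0, -1.0, -1.0], atol=1e-14)
        np.testing.assert_allclose(F, [1.0, -1.0, 0.0], atol=1e-14)
        assert F[0] != 0.0 and u[2] != 0.0
        assert abs(F.sum()) < 1e-14

    def test_zero_prescriptions_give_zero(self):
        bar = BarModel1D((1.0, 1.0), (("u", 0.0), ("u", 0.0), ("f", 0.0)))
        u, F = bar_solve_mbvp(bar)
        assert np.abs(u).max() == 0.0 and np.abs(F).max() < 1e-15

    @given(
        st.lists(st.floats(0.1, 5.0), min_size=2, max_size=5),
        st.data(),
    )
    @settings(deadline=None, max_examples=50)
    def test_total_force_always_balances(self, ks, data):
        # the traction the "cell" applies is self-equilibrated: ΣF = 0
        n = len(ks) + 1
        kinds = data.draw(
            st.lists(st.sampled_from(["u", "f"]), min_size=n, max_size=n).filter(
                lambda kk: "u" in kk
            )
        )
        vals = data.draw(
            st.lists(st.floats(-2.0, 2.0), min_size=n, max_size=n)
        )
        bar = BarModel1D(tuple(ks), tuple(zip(kinds, vals)))
        u, F = bar_solve_mbvp(bar)
        assert abs(F.sum()) < 1e-9

    def test_all_force_prescriptions_rejected(self):
        bar = BarModel1D((1.0,), (("f", 1.0), ("f", -1.0)))
        with pytest.raises(RankDeficiencyError):
            bar_solve_mbvp(bar)


class TestSubstrateModel:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(youngs_modulus=0.0),
            dict(poissons_ratio=0.5),
            dict(poissons_ratio=-0.1),
            dict(thickness=-1.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        base = dict(
            youngs_modulus=1.0,
            poissons_ratio=0.45,
            thickness=70.0,
            lateral_size_x=100.0,
            lateral_size_y=100.0,
        )
        base.update(kw)
        with pytest.raises((MaterialError, GeometryError)):
            SubstrateModel(**base)
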