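"""Assembly, boundary conditions, static solve, tension-only iteration."""

import numpy as np
import pytest
import scipy.sparse as sp

from spondylofem.fem.elements import (BeamElement, BeamSection,
                                      SpringElement)
from spondylofem.fem.mesh import DofMap, SpineModel
from spondylofem.fem.solve import (
    ActiveSetError,
    BoundaryConditions,
    SingularSystemError,
    apply_boundary_conditions,
    assemble_global_stiffness,
    resolve_tension_only,
    solve_static,
    spring_elongations,
)

SEC = BeamSection(E=10000.0, G=4000.0, A=50.0, Iy=400.0, Iz=400.0, J=800.0)


def empty_hex_arrays():
    return dict(hex_conn=np.zeros((0, 8), dtype=int), hex_E=np.zeros(0),
                hex_nu=np.zeros(0), hex_region=[])


def bar_chain(n_el, L=100.0):
    pos = np.zeros((n_el + 1, 3))
    pos[:, 0] = np.linspace(0, L, n_el + 1)
    beams = [BeamElement((i, i + 1), SEC) for i in range(n_el)]
    return SpineModel(positions=pos, beams=beams, **empty_hex_arrays())


class TestAssembly:
    def test_global_matrix_is_symmetric(self, small_model):
        sys_ = assemble_global_stiffness(small_model)
        asym = (sys_.K - sys_.K.T)
        assert abs(asym).max() <= 1e-9 * abs(sys_.K).max()

    def test_springs_in_series_equivalent_stiffness(self):
        pos = np.array([[0, 0, 0], [0, 0, 10], [0, 0, 25]], dtype=float)
        k1, k2 = 30.0, 70.0
        model = SpineModel(positions=pos,
                           springs=[SpringElement((0, 1), k1),
                                    SpringElement((1, 2), k2)],
                           **empty_hex_arrays())
        bcs = BoundaryConditions()
        bcs.fix_node(0, dofs=(0, 1, 2))
        bcs.fix_node(1, dofs=(0, 1))  # keep the lateral DOFs constrained
        bcs.fix_node(2, dofs=(0, 1))
        sys_ = assemble_global_stiffness(model)
        con = apply_boundary_conditions(sys_, bcs)
        dm = sys_.dofmap
        f = np.zeros(dm.ndof)
        F = 5.0
        f[dm.dof(2, 2)] = F
        u = solve_static(con, f)
        keq = k1 * k2 / (k1 + k2)
        assert u[dm.dof(2, 2)] == pytest.approx(F / keq, rel=1e-9)

    def test_strain_energy_equals_sum_over_elements(self, rng):
        """Global 0.5 u'Ku equals the brute-force sum of element energies."""
        model = bar_chain(10)
        dm = DofMap(model)
        sys_ = assemble_global_stiffness(model, dm)
        u = rng.normal(size=dm.ndof) * 0.1
        from spondylofem.fem.elements import beam_element_stiffness
        total = 0.0
        for b in model.beams:
            i, j = b.nodes
            Ke = beam_element_stiffness(b, model.positions[i],
                                        model.positions[j])
            ue = np.r_[u[dm.node_dofs(i)], u[dm.node_dofs(j)]]
            total += 0.5 * ue @ Ke @ ue
        assert 0.5 * u @ sys_.K @ u == pytest.approx(total, rel=1e-9)

    def test_dangling_node_reference_raises(self):
        with pytest.raises(ValueError):
            SpineModel(positions=np.zeros((2, 3)),
                       beams=[BeamElement((0, 5), SEC)],
                       **empty_hex_arrays())


class TestBoundaryConditions:
    def test_fixing_a_node_removes_six_dofs(self):
        model = bar_chain(3)
        sys_ = assemble_global_stiffness(model)
        bcs = BoundaryConditions()
        bcs.fix_node(0)
        con = apply_boundary_conditions(sys_, bcs)
        assert (~con.free).sum() == 6

    def test_torsion_spring_adds_to_rotational_diagonal(self):
        model = bar_chain(2)
        sys_ = assemble_global_stiffness(model)
        dm = sys_.dofmap
        k = 1234.0
        bcs = BoundaryConditions(ground_springs=[(0, 3, k)])
        con = apply_boundary_conditions(sys_, bcs)
        d = dm.dof(0, 3)
        assert con.K_mod[d, d] - sys_.K[d, d] == pytest.approx(k)

    def test_bc_on_missing_dof_raises(self, small_model):
        sys_ = assemble_global_stiffness(small_model)
        bcs = BoundaryConditions(fixed=[(0, 4)])  # solid node, no rotation
        with pytest.raises(KeyError):
            apply_boundary_conditions(sys_, bcs)

    def test_unconstrained_system_detected_as_singular(self):
        model = bar_chain(4)
        sys_ = assemble_global_stiffness(model)
        con = apply_boundary_conditions(sys_, BoundaryConditions())
        f = np.zeros(sys_.dofmap.ndof)
        f[0] = 1.0
        with pytest.raises(SingularSystemError):
            solve_static(con, f)


class TestSolveStatic:
    def test_recovers_prescribed_displacement(self, rng):
        model = bar_chain(5)
        bcs = BoundaryConditions()
        bcs.fix_node(0)
        sys_ = assemble_global_stiffness(model)
        con = apply_boundary_conditions(sys_, bcs)
        u_true = np.zeros(sys_.dofmap.ndof)
        u_true[con.free] = rng.normal(size=con.free.sum())
        f = con.K_mod @ u_true
        u = solve_static(con, f)
        np.testing.assert_allclose(u, u_true, atol=1e-8 * np.abs(u_true).max())

    def test_cantilever_chain_tip_deflection(self):
        """10-element cantilever vs the Euler-Bernoulli closed form."""
        L, P = 200.0, 10.0
        model = bar_chain(10, L=L)
        bcs = BoundaryConditions()
        bcs.fix_node(0)
        sys_ = assemble_global_stiffness(model)
        con = apply_boundary_conditions(sys_, bcs)
        dm = sys_.dofmap
        f = np.zeros(dm.ndof)
        f[dm.dof(10, 1)] = P
        u = solve_static(con, f)
        expected = P * L**3 / (3 * SEC.E * SEC.Iz)
        assert u[dm.dof(10, 1)] == pytest.approx(expected, rel=1e-3)

    def test_beam_chain_is_nodally_exact_for_tip_load(self):
        """Cubic Hermite beams solve the tip-load cantilever exactly at
        any discretization."""
        L, P = 200.0, 10.0
        expected = P * L**3 / (3 * SEC.E * SEC.Iz)
        for n in (1, 2, 4):
            model = bar_chain(n, L=L)
            bcs = BoundaryConditions()
            bcs.fix_node(0)
            con = apply_boundary_conditions(
                assemble_global_stiffness(model), bcs)
            dm = con.system.dofmap
            f = np.zeros(dm.ndof)
            f[dm.dof(n, 1)] = P
            u = solve_static(con, f)
            assert u[dm.dof(n, 1)] == pytest.approx(expected, rel=1e-9)

    def test_hex_refinement_ladder_converges_monotonically(self):
        """Solid-brick cantilever: bending error against the slender-beam
        closed form decreases monotonically over a 3-level ladder."""
        E, nu = 1000.0, 0.3
        W, L, P = 2.0, 32.0, 1.0
        inertia = W**4 / 12.0
        expected = P * L**3 / (3 * E * inertia)
        errors = []
        for (nx, nz) in ((1, 8), (2, 16), (4, 32)):
            xs = np.linspace(0, W, nx + 1)
            zs = np.linspace(0, L, nz + 1)
            npl = (nx + 1) ** 2
            pos = np.array([[x, y, z] for z in zs for x in xs for y in xs])

            def nid(k, i, j):
                return k * npl + i * (nx + 1) + j

            conn = [[nid(k, i, j), nid(k, i + 1, j), nid(k, i + 1, j + 1),
                     nid(k, i, j + 1), nid(k + 1, i, j), nid(k + 1, i + 1, j),
                     nid(k + 1, i + 1, j + 1), nid(k + 1, i, j + 1)]
                    for k in range(nz) for i in range(nx) for j in range(nx)]
            n_el = len(conn)
            model = SpineModel(positions=pos, hex_conn=np.array(conn),
                               hex_E=np.full(n_el, E),
                               hex_nu=np.full(n_el, nu),
                               hex_region=["solid"] * n_el)
            bcs = BoundaryConditions()
            for node in range(npl):
                bcs.fix_node(node, dofs=(0, 1, 2))
            con = apply_boundary_conditions(
                assemble_global_stiffness(model), bcs)
            dm = con.system.dofmap
            f = np.zeros(dm.ndof)
            tip = np.arange(nz * npl, (nz + 1) * npl)
            f[dm.translation_dofs(tip)[:, 0]] = P / npl  # transverse tip load
            u = solve_static(con, f)
            tip_def = u[dm.translation_dofs(tip)[:, 0]].mean()
            errors.append(abs(tip_def - expected) / expected)
        assert errors[0] > errors[1] > errors[2]


class TestTensionOnly:
    def three_spring_model(self, tension_only=(True, True)):
        pos = np.array([[0, 0, 0], [0, 0, 100], [0, 0, 200],
                        [50, 0, 100]], dtype=float)
        springs = [SpringElement((0, 1), 10.0, tension_only[0]),
                   SpringElement((1, 2), 10.0, tension_only[1]),
                   SpringElement((1, 3), 5.0)]
        model = SpineModel(positions=pos, springs=springs,
                           **empty_hex_arrays())
        bcs = BoundaryConditions()
        for n in (0, 2, 3):
            bcs.fix_node(n, dofs=(0, 1, 2))
        bcs.fix_node(1, dofs=(1,))
        return model, bcs

    def test_all_tension_matches_plain_linear_solve(self):
        model, bcs = self.three_spring_model()
        dm = DofMap(model)
        f = np.zeros(dm.ndof)
        f[dm.dof(1, 2)] = 0.0
        f[dm.dof(1, 0)] = -1.0  # pulls node away from the lateral anchor
        u_ref = solve_static(apply_boundary_conditions(
            assemble_global_stiffness(model, dm), bcs), f)
        u, active = resolve_tension_only(model, bcs, f, dofmap=dm)
        elong = spring_elongations(model, dm, u_ref)
        assert (elong >= -1e-12).all()
        assert active.all()
        np.testing.assert_allclose(u, u_ref, atol=1e-12)

    def test_compressed_spring_is_removed(self):
        """Pushing the middle node down compresses the lower spring; the
        result must match a model with that spring deleted."""
        model, bcs = self.three_spring_model()
        dm = DofMap(model)
        f = np.zeros(dm.ndof)
        f[dm.dof(1, 2)] = -2.0
        u, active = resolve_tension_only(model, bcs, f, dofmap=dm)
        assert active.tolist() == [False, True, True]
        reduced = SpineModel(positions=model.positions.copy(),
                             springs=model.springs[1:], **empty_hex_arrays())
        u_ref = solve_static(apply_boundary_conditions(
            assemble_global_stiffness(reduced, DofMap(reduced)), bcs), f)
        np.testing.assert_allclose(u, u_ref, atol=1e-12)

    def test_iteration_limit_raises(self):
        model, bcs = self.three_spring_model()
        dm = DofMap(model)
        f = np.zeros(dm.ndof)
        f[dm.dof(1, 2)] = -2.0  # forces an active-set change
        with pytest.raises(ActiveSetError):
            resolve_tension_only(model, bcs, f, max_iter=0, dofmap=dm)

    def test_no_active_tension_only_spring_is_compressed(self, small_model,
                                                         small_solution):
        """Complementarity on the full spine model's converged state."""
        bcs = small_solution["bcs"]
        dm = DofMap(small_model, extra_rotation_nodes=bcs.rotation_nodes())
        elong = spring_elongations(small_model, dm, small_solution["u"])
        active = small_solution["diag"].active_springs
        assert active is not None
        for s, act, e in zip(small_model.springs, active, elong):
            if s.tension_only and act:
                assert e >= -1e-9
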