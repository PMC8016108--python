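"""Element matrices, assembly, penalty boundary conditions and the solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from follisim import (
    BeamElementSpec,
    SpringElementSpec,
    apply_boundary_conditions,
    assemble_global,
    beam_element_stiffness,
    oracle_constrained_solve,
    solve_displacements,
    spring_element_stiffness,
)
from follisim.fem_core import (
    AssemblyError,
    InvalidParameterError,
    penalty_factor_for,
)
from follisim.follicle_model import N_DOFS, FollicleParameters, build_model

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


def unit_beam(E=1.0, I=1.0, L=1.0):
    return BeamElementSpec(
        youngs_modulus=E, second_moment=I, length=L, dof_indices=(1, 2, 3, 4)
    )


class TestBeamElement:
    def test_unit_parameters_give_canonical_matrix(self):
        K = beam_element_stiffness(unit_beam())
        expected = np.array(
            [
                [12, 6, -12, 6],
                [6, 4, -6, 2],
                [-12, -6, 12, -6],
                [6, 2, -6, 4],
            ],
            dtype=float,
        )
        np.testing.assert_allclose(K, expected)

    @given(E=positive, I=positive, L=positive)
    @settings(max_examples=50, derandomize=True)
    def test_rigid_body_modes_and_symmetry(self, E, I, L):
        K = beam_element_stiffness(unit_beam(E, I, L))
        np.testing.assert_allclose(K, K.T)
        # pure translation and rigid rotation are force-free
        translation = np.array([1.0, 0.0, 1.0, 0.0])
        rotation = np.array([0.0, 1.0, L, 1.0])
        scale = np.abs(K).max()
        assert np.abs(K @ translation).max() <= 1e-10 * scale
        assert np.abs(K @ rotation).max() <= 1e-9 * scale * max(L, 1.0)
        assert np.linalg.matrix_rank(K / scale) == 2

    def test_linearity_in_flexural_rigidity(self):
        np.testing.assert_allclose(
            beam_element_stiffness(unit_beam(E=2.0)),
            2.0 * beam_element_stiffness(unit_beam()),
        )

    @pytest.mark.parametrize("bad", [dict(L=0.0), dict(L=-1.0), dict(E=-2.0), dict(I=0.0)])
    def test_nonpositive_parameters_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            unit_beam(**{k: v for k, v in bad.items()})


class TestSpringElement:
    def test_matrix_shape(self):
        K = spring_element_stiffness(SpringElementSpec(stiffness=5.0, dof_indices=(1, 2)))
        np.testing.assert_allclose(K, [[5, -5], [-5, 5]])

    def test_zero_stiffness_allowed(self):
        K = spring_element_stiffness(SpringElementSpec(stiffness=0.0, dof_indices=(1, 2)))
        np.testing.assert_allclose(K, np.zeros((2, 2)))

    @given(k=positive)
    @settings(max_examples=25, derandomize=True)
    def test_row_sums_vanish(self, k):
        K = spring_element_stiffness(SpringElementSpec(stiffness=k, dof_indices=(3, 7)))
        np.testing.assert_allclose(K.sum(axis=1), 0.0)

    def test_negative_stiffness_rejected(self):
        with pytest.raises(InvalidParameterError):
            SpringElementSpec(stiffness=-1.0, dof_indices=(1, 2))


class TestAssembly:
    def test_two_spring_chain(self):
        springs = [
            SpringElementSpec(stiffness=1.0, dof_indices=(1, 2)),
            SpringElementSpec(stiffness=1.0, dof_indices=(2, 3)),
        ]
        K = assemble_global([], springs, 3).stiffness_matrix
        np.testing.assert_allclose(K, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_follicle_layout_k3_scatter(self, default_params):
        beams, springs, _ = build_model(default_params)
        K = assemble_global(beams, springs, N_DOFS).stiffness_matrix
        np.testing.assert_allclose(K, K.T)
        # the RS spring couples DOFs 5 and 15 with stiffness k3
        k3 = default_params.k3
        assert K[4, 14] == pytest.approx(-k3)
        assert K[14, 4] == pytest.approx(-k3)
        # its diagonal contributions are summed with the beam terms
        beams_only = assemble_global(beams, [], N_DOFS).stiffness_matrix
        assert K[4, 4] - beams_only[4, 4] == pytest.approx(k3)
        assert K[14, 14] - beams_only[14, 14] == pytest.approx(k3)

    def test_assembly_order_irrelevant(self, default_params):
        beams, springs, _ = build_model(default_params)
        K1 = assemble_global(beams, springs, N_DOFS).stiffness_matrix
        K2 = assemble_global(beams[::-1], springs[::-1], N_DOFS).stiffness_matrix
        np.testing.assert_allclose(K1, K2)

    def test_out_of_range_dof_rejected(self):
        spring = SpringElementSpec(stiffness=1.0, dof_indices=(1, 21))
        with pytest.raises(AssemblyError):
            assemble_global([], [spring], 20)

    def test_rigid_body_mode_without_ground_springs(self, default_params):
        # drop the two ground springs: a uniform translation of every beam
        # node is then force-free
        beams, springs, _ = build_model(default_params)
        K = assemble_global(beams, springs[:4], N_DOFS).stiffness_matrix
        v = np.zeros(N_DOFS)
        v[[0, 2, 4, 6, 8, 10, 12, 14, 16]] = 1.0
        assert np.abs(K @ v).max() <= 1e-10 * np.abs(K).max()


class TestBoundaryConditionsAndSolve:
    def test_load_vector_entries(self, default_params):
        beams, springs, constraints = build_model(default_params)
        system = assemble_global(beams, springs, N_DOFS)
        constrained = apply_boundary_conditions(system, constraints)
        f = constrained.load_vector
        beta = constrained.penalty_factor
        assert f[7] == pytest.approx(beta * default_params.deflection_angle)
        # ground constraints prescribe zero, so those loads vanish
        assert f[18] == 0.0 and f[19] == 0.0
        assert np.count_nonzero(f) == 1
        K0, K1 = system.stiffness_matrix, constrained.stiffness_matrix
        for dof in (8, 19, 20):
            assert K1[dof - 1, dof - 1] == pytest.approx(K0[dof - 1, dof - 1] + beta)

    def test_empty_constraints_leave_system_unchanged(self, default_params):
        beams, springs, _ = build_model(default_params)
        system = assemble_global(beams, springs, N_DOFS)
        out = apply_boundary_conditions(system, {})
        np.testing.assert_array_equal(out.stiffness_matrix, system.stiffness_matrix)
        np.testing.assert_array_equal(out.load_vector, system.load_vector)

    def test_duplicate_constraint_rejected(self, default_params):
        beams, springs, constraints = build_model(default_params)
        system = assemble_global(beams, springs, N_DOFS)
        once = apply_boundary_conditions(system, constraints)
        with pytest.raises(AssemblyError):
            apply_boundary_conditions(once, {8: 0.1})

    def test_zero_prescribed_deflection_gives_zero_solution(self, default_params):
        import dataclasses

        params = dataclasses.replace(default_params, deflection_angle=0.0)
        beams, springs, constraints = build_model(params)
        system = assemble_global(beams, springs, N_DOFS)
        d = solve_displacements(
            apply_boundary_conditions(system, constraints)
        ).displacement_vector
        assert np.abs(d).max() == 0.0

    def test_solution_linear_in_prescribed_angle(self, default_params):
        import dataclasses

        from follisim import solve_model

        d0 = solve_model(default_params)[0].displacement_vector
        for c in (-1.0, 0.5, 2.0):
            params = dataclasses.replace(
                default_params, deflection_angle=c * default_params.deflection_angle
            )
            dc = solve_model(params)[0].displacement_vector
            np.testing.assert_allclose(dc, c * d0, rtol=1e-10, atol=1e-10 * np.abs(d0).max())

    def test_ground_dofs_within_penalty_tolerance(self, default_params):
        from follisim import solve_model

        d, system = solve_model(default_params)
        vec = d.displacement_vector
        mean_diag = np.mean(np.diag(system.stiffness_matrix))
        bound = 10.0 * np.abs(vec).max() / (system.penalty_factor / mean_diag)
        assert abs(d[19]) <= bound and abs(d[20]) <= bound


class TestOracle:
    def test_single_spring_hookes_law(self):
        # one spring to ground, prescribed end displacement: reaction = k*delta
        k, delta = 50.0, 0.2
        spring = SpringElementSpec(stiffness=k, dof_indices=(1, 2))
        sol = oracle_constrained_solve([], [spring], {1: delta, 2: 0.0}, 2)
        d = sol.displacement_vector
        np.testing.assert_allclose(d, [delta, 0.0])
        force = k * (d[0] - d[1])
        assert force == pytest.approx(k * delta)

    def test_penalty_matches_oracle_on_default_model(self, default_params):
        from follisim import solve_model

        beams, springs, constraints = build_model(default_params)
        oracle = oracle_constrained_solve(beams, springs, constraints, N_DOFS)
        penalty = solve_model(default_params)[0]
        err = np.linalg.norm(
            penalty.displacement_vector - oracle.displacement_vector
        ) / np.linalg.norm(oracle.displacement_vector)
        assert err < 1e-5

    def test_zero_prescribed_values_give_zero_solution(self, default_params):
        beams, springs, _ = build_model(default_params)
        sol = oracle_constrained_solve(beams, springs, {8: 0.0, 19: 0.0, 20: 0.0}, N_DOFS)
        assert np.abs(sol.displacement_vector).max() <= 1e-20

    def test_penalty_error_decays_with_beta(self, default_params):
        """Penalty error decays ~1/beta until it reaches the roundoff floor."""
        beams, springs, constraints = build_model(default_params)
        system = assemble_global(beams, springs, N_DOFS)
        oracle = oracle_constrained_solve(beams, springs, constraints, N_DOFS)
        ref = np.linalg.norm(oracle.displacement_vector)
        mean_diag = np.mean(np.diag(system.stiffness_matrix))

        def error(factor):
            st_ = apply_boundary_conditions(
                system, constraints, penalty_factor=factor * mean_diag
            )
            d = solve_displacements(st_).displacement_vector
            return np.linalg.norm(d - oracle.displacement_vector) / ref

        # 100x improvement over four decades in the beta range where the
        # penalty error dominates float64 roundoff
        assert error(1e0) >= 100.0 * error(1e4)
        # and no degradation at the very large default-scale betas
        assert error(1e9) <= error(1e5)
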