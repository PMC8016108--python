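"""Finite-element machinery for small beam-and-spring structures.

Implements the generic building blocks used by the follicle model: 4-DOF
Euler-Bernoulli beam element stiffness matrices, 2-DOF linear spring
matrices, scatter assembly into a dense global stiffness matrix, essential
boundary conditions by the penalty method, and a direct dense solve.  A
Lagrange-multiplier solver that enforces the constraints exactly is provided
as an independent cross-check of the penalty route; it is intended for
validation, not production use.

DOF labels are 1-based throughout, matching the published global layout
``d = [u1, th2, u3, th4, ..., u19, u20]`` in which translations and
rotations alternate along each beam.  Internally everything is converted to
0-based indices at assembly time.

All quantities are SI: metres, newtons, pascals, radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "BeamElementSpec",
    "SpringElementSpec",
    "GlobalSystem",
    "NodalSolution",
    "beam_element_stiffness",
    "spring_element_stiffness",
    "assemble_global",
    "apply_boundary_conditions",
    "solve_displacements",
    "oracle_constrained_solve",
    "InvalidParameterError",
    "AssemblyError",
    "SingularSystemError",
]

#: Default penalty magnitude relative to the mean stiffness diagonal.
DEFAULT_PENALTY_RATIO = 1.0e7

class InvalidParameterError(ValueError):
    """An element specification violates its physical invariants."""


class AssemblyError(ValueError):
    """A DOF index falls outside the global system, or constraints clash."""


class SingularSystemError(np.linalg.LinAlgError):
    """The (penalised) stiffness matrix is singular or hopelessly conditioned."""


@dataclass(frozen=True)
class BeamElementSpec:
    """A planar Euler-Bernoulli beam segment.

    Parameters
    ----------
    youngs_modulus : float
        Young's modulus E in Pa.
    second_moment : float
        Area moment of inertia I in m^4.
    length : float
        Element length in m.
    dof_indices : tuple[int, int, int, int]
        Global 1-based DOF labels ``(a, b, c, d)``: translation and rotation
        at the first node, then at the second node.
    """

    youngs_modulus: float
    second_moment: float
    length: float
    dof_indices: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise InvalidParameterError(
                f"Young's modulus must be positive, got {self.youngs_modulus}"
            )
        if self.second_moment <= 0:
            raise InvalidParameterError(
                f"second moment must be positive, got {self.second_moment}"
            )
        if self.length <= 0:
            raise InvalidParameterError(f"length must be positive, got {self.length}")
        if len(set(self.dof_indices)) != 4:
            raise InvalidParameterError(
                f"beam DOF indices must be 4 distinct labels, got {self.dof_indices}"
            )


@dataclass(frozen=True)
class SpringElementSpec:
    """A linear spring between two translational DOFs.

    ``stiffness`` is in N/m; ``dof_indices`` are the two global 1-based DOF
    labels the spring couples.
    """

    stiffness: float
    dof_indices: tuple[int, int]

    def __post_init__(self) -> None:
        if self.stiffness < 0:
            raise InvalidParameterError(
                f"spring stiffness must be non-negative, got {self.stiffness}"
            )
        if len(set(self.dof_indices)) != 2:
            raise InvalidParameterError(
                f"spring DOF indices must be 2 distinct labels, got {self.dof_indices}"
            )


@dataclass
class GlobalSystem:
    """Assembled global stiffness system, before or after penalty BCs.

    ``constrained_dofs`` maps 1-based DOF labels to prescribed values; it is
    empty until :func:`apply_boundary_conditions` runs.  ``penalty_factor``
    is the β actually added to the constrained diagonal entries.
    """

    stiffness_matrix: np.ndarray
    load_vector: np.ndarray
    penalty_factor: float = 0.0
    constrained_dofs: dict[int, float] = field(default_factory=dict)

    @property
    def n_dofs(self) -> int:
        return self.stiffness_matrix.shape[0]


@dataclass
class NodalSolution:
    """Solved nodal displacement vector (translations in m, rotations in rad)."""

    displacement_vector: np.ndarray

    def __getitem__(self, dof_label: int) -> float:
        """Return the solution entry for a 1-based DOF label."""
        return float(self.displacement_vector[dof_label - 1])


# ---------------------------------------------------------------------------
# Element matrices
# ---------------------------------------------------------------------------

def beam_element_stiffness(spec: BeamElementSpec) -> np.ndarray:
    """4x4 Euler-Bernoulli bending stiffness matrix for one beam element.

    Rows/columns are ordered (u_a, th_a, u_b, th_b).  The matrix is symmetric
    and has rank 2: rigid translation and rigid rotation of the element are
    in its null space.
    """
    EI = spec.youngs_modulus * spec.second_moment
    L = spec.length
    return (EI / L**3) * np.array(
        [
            [12.0, 6.0 * L, -12.0, 6.0 * L],
            [6.0 * L, 4.0 * L**2, -6.0 * L, 2.0 * L**2],
            [-12.0, -6.0 * L, 12.0, -6.0 * L],
            [6.0 * L, 2.0 * L**2, -6.0 * L, 4.0 * L**2],
        ]
    )


def spring_element_stiffness(spec: SpringElementSpec) -> np.ndarray:
    """2x2 stiffness matrix ``[[k, -k], [-k, k]]`` of a linear spring."""
    k = spec.stiffness
    return np.array([[k, -k], [-k, k]])


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _scatter(global_k: np.ndarray, local_k: np.ndarray, dofs: tuple[int, ...]) -> None:
    idx = np.asarray(dofs) - 1
    global_k[np.ix_(idx, idx)] += local_k


def assemble_global(
    beams: list[BeamElementSpec],
    springs: list[SpringElementSpec],
    n_dofs: int,
) -> GlobalSystem:
    """Assemble the global stiffness matrix by scattering element matrices.

    Entries shared between elements are summed.  There are no external nodal
    loads in this model, so the load vector starts at zero; prescribed
    displacements enter later through the penalty terms.
    """
    for spec in beams + springs:
        for dof in spec.dof_indices:
            if not 1 <= dof <= n_dofs:
                raise AssemblyError(
                    f"DOF label {dof} outside [1, {n_dofs}] in {spec!r}"
                )
    K = np.zeros((n_dofs, n_dofs))
    for beam in beams:
        _scatter(K, beam_element_stiffness(beam), beam.dof_indices)
    for spring in springs:
        _scatter(K, spring_element_stiffness(spring), spring.dof_indices)
    return GlobalSystem(stiffness_matrix=K, load_vector=np.zeros(n_dofs))


# ---------------------------------------------------------------------------
# Boundary conditions and solve
# ---------------------------------------------------------------------------

def penalty_factor_for(
    system: GlobalSystem,
    mode: str = "mean_diag",
    youngs_modulus: float | None = None,
    ratio: float = DEFAULT_PENALTY_RATIO,
) -> float:
    """Choose β for the penalty method.

    ``mode="mean_diag"`` scales 1e7 by the mean diagonal of K, which keeps the
    penalised matrix well conditioned regardless of the unit system.
    ``mode="modulus"`` uses 1e7 times Young's modulus directly.
    """
    if mode == "mean_diag":
        return ratio * float(np.mean(np.diag(system.stiffness_matrix)))
    if mode == "modulus":
        if youngs_modulus is None:
            raise ValueError("mode='modulus' requires youngs_modulus")
        return ratio * youngs_modulus
    raise ValueError(f"unknown penalty mode {mode!r}")


def apply_boundary_conditions(
    system: GlobalSystem,
    constraints: dict[int, float],
    penalty_factor: float | None = None,
) -> GlobalSystem:
    """Impose prescribed displacements via the penalty method.

    Adds β to the diagonal at each constrained DOF and β times the prescribed
    value to the load vector.  Returns a new :class:`GlobalSystem`; the input
    is not modified.  Raises :class:`AssemblyError` on a duplicate constraint
    or an out-of-range DOF label.
    """
    if len(constraints) == 0:
        return GlobalSystem(
            stiffness_matrix=system.stiffness_matrix.copy(),
            load_vector=system.load_vector.copy(),
        )
    labels = list(constraints)
    if len(set(labels)) != len(labels):  # defensive; dict already unique
        raise AssemblyError("duplicate constraint")
    for dof in labels:
        if not 1 <= dof <= system.n_dofs:
            raise AssemblyError(f"constrained DOF {dof} outside [1, {system.n_dofs}]")
    if system.constrained_dofs:
        dup = set(labels) & set(system.constrained_dofs)
        if dup:
            raise AssemblyError(f"DOFs already constrained: {sorted(dup)}")
    beta = (
        penalty_factor
        if penalty_factor is not None
        else penalty_factor_for(system)
    )
    K_tot = system.stiffness_matrix.copy()
    f = system.load_vector.copy()
    for dof, value in constraints.items():
        K_tot[dof - 1, dof - 1] += beta
        f[dof - 1] += beta * value
    return GlobalSystem(
        stiffness_matrix=K_tot,
        load_vector=f,
        penalty_factor=beta,
        constrained_dofs={**system.constrained_dofs, **constraints},
    )


def solve_displacements(system: GlobalSystem) -> NodalSolution:
    """Solve ``K_tot d = f`` for the nodal displacements.

    Accuracy is judged by the relative residual ``|K d - f| / |f|`` rather
    than a raw condition number: the matrix mixes translational (m) and
    rotational (rad) DOFs, so its unscaled condition number is large even
    when the solve is perfectly accurate.  Raises
    :class:`SingularSystemError` (with a condition estimate) when the matrix
    is singular or the residual exceeds 1e-8 relative.
    """
    K = system.stiffness_matrix
    try:
        d = np.linalg.solve(K, system.load_vector)
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(f"singular stiffness matrix: {exc}") from exc
    residual = np.linalg.norm(K @ d - system.load_vector)
    scale = np.linalg.norm(system.load_vector)
    bad = not np.all(np.isfinite(d)) or (scale > 0 and residual > 1e-8 * scale)
    if bad:
        cond = np.linalg.cond(K, 1)
        raise SingularSystemError(
            f"solver residual {residual:.3e} exceeds 1e-8 relative "
            f"(cond_1 ~ {cond:.3e})"
        )
    return NodalSolution(displacement_vector=d)


def oracle_constrained_solve(
    beams: list[BeamElementSpec],
    springs: list[SpringElementSpec],
    constraints: dict[int, float],
    n_dofs: int,
) -> NodalSolution:
    """Solve the constrained system exactly with Lagrange multipliers.

    Builds the bordered KKT system ``[[K, C^T], [C, 0]] [d; lam] = [0; g]``
    where ``C`` selects the constrained DOFs and ``g`` their prescribed
    values.  This enforces the essential boundary conditions without penalty
    error and serves as the independent oracle for the penalty route.
    """
    system = assemble_global(beams, springs, n_dofs)
    K = system.stiffness_matrix
    m = len(constraints)
    if m == 0:
        raise AssemblyError("oracle requires at least one constraint")
    C = np.zeros((m, n_dofs))
    g = np.zeros(m)
    for row, (dof, value) in enumerate(constraints.items()):
        if not 1 <= dof <= n_dofs:
            raise AssemblyError(f"constrained DOF {dof} outside [1, {n_dofs}]")
        C[row, dof - 1] = 1.0
        g[row] = value
    kkt = np.block([[K, C.T], [C, np.zeros((m, m))]])
    rhs = np.concatenate([system.load_vector, g])
    try:
        sol = scipy.linalg.solve(kkt, rhs)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SingularSystemError(f"inconsistent constraints: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise SingularSystemError("inconsistent or redundant constraints")
    return NodalSolution(displacement_vector=sol[:n_dofs])
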