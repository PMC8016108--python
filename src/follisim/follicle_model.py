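"""The 13-element beam-and-spring model of the follicle sinus complex.

The whisker (vibrissa) is an Euler-Bernoulli beam running along the follicle
axis; the follicle wall is a second, effectively rigid beam.  Four internal
springs couple whisker to wall at the hair bulb (HB, k1), cavernous sinus
(CS, k2), ring sinus (RS, k3) and follicle entrance (k4); two external
springs couple the wall to ground at its deep end (k5) and entrance (k6),
standing in for intrinsic muscle and surrounding tissue.  A whisker
deflection is imposed as a prescribed rotation of the whisker at the
follicle entrance, and the two ground translations are fixed at zero.

Node/DOF layout (1-based labels, translations and rotations alternating):

==========  =====================  ==========
structure   nodes (axial pos.)     DOF labels
==========  =====================  ==========
vibrissa    HB, CS, RS, entrance,  1..10
            external tip
wall        HB, CS, RS, entrance   11..18
ground      two supports           19, 20 (translation only)
==========  =====================  ==========

so e.g. the RS spring k3 couples DOFs (5, 15).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .fem_core import (
    BeamElementSpec,
    GlobalSystem,
    InvalidParameterError,
    NodalSolution,
    SpringElementSpec,
    apply_boundary_conditions,
    assemble_global,
    penalty_factor_for,
    solve_displacements,
)

__all__ = [
    "FollicleParameters",
    "DeformationProfiles",
    "build_model",
    "solve_model",
    "compute_profiles",
    "validate_anatomical_constraints",
    "N_DOFS",
]

N_DOFS = 20

#: Spring DOF pairs in the fixed 20-DOF layout: k1..k6 in order.
SPRING_DOF_PAIRS = ((1, 11), (3, 13), (5, 15), (7, 17), (11, 19), (17, 20))

#: Wall translational DOF labels at the HB, CS, RS and entrance nodes.
WALL_TRANSLATION_DOFS = (11, 13, 15, 17)

#: DOF label of the prescribed whisker rotation at the follicle entrance.
ENTRANCE_ROTATION_DOF = 8


@dataclass(frozen=True)
class FollicleParameters:
    """Physical and geometric parameters of one follicle model instance.

    All values are SI (m, Pa, N/m, rad).  Defaults describe a rat mystacial
    vibrissa: E = 3.5 GPa, base radius 75 um (150 um diameter), follicle
    length 1 mm, and spring stiffnesses k1=1e3, k2=1e4, k3=1e5, k4=1e6 N/m
    with external support k5+k6=1e4 N/m split 3:7 (k6/k5 = 7/3, the stiffer
    spring at the skin surface).  The prescribed entrance rotation of -10 deg
    simulates a 10 deg whisker deflection; positive deflection is rostral.

    ``spring_positions`` are the axial stations of the four internal springs
    as fractions of the follicle length L: HB at 0, CS at 0.3, RS at 0.6,
    entrance at 1.  ``wall_rigidity_factor`` multiplies the vibrissa EI for
    the wall elements, realising the rigid wall while keeping the 20-DOF
    beam structure.  ``external_segment_length`` is the free whisker stub
    beyond the entrance (default 0.2 L); with the rotation prescribed at the
    entrance it carries no load and does not affect the internal solution.
    ``skin_modulus`` is used only by the anatomical-constraint checks.
    """

    vibrissa_modulus: float = 3.5e9
    vibrissa_radius: float = 75e-6
    follicle_length: float = 1e-3
    k1: float = 1e3
    k2: float = 1e4
    k3: float = 1e5
    k4: float = 1e6
    k5: float = 3e3
    k6: float = 7e3
    spring_positions: tuple[float, float, float, float] = (0.0, 0.3, 0.6, 1.0)
    wall_rigidity_factor: float = 1e4
    external_segment_length: float | None = None
    deflection_angle: float = math.radians(-10.0)
    skin_modulus: float = 8e6
    penalty_mode: str = "mean_diag"

    def __post_init__(self) -> None:
        x1, x2, x3, x4 = self.spring_positions
        if not (x1 == 0.0 and x4 == 1.0 and x1 < x2 < x3 < x4):
            raise InvalidParameterError(
                f"spring positions must satisfy 0 = x1 < x2 < x3 < x4 = 1, "
                f"got {self.spring_positions}"
            )
        for name in ("k1", "k2", "k3", "k4", "k5", "k6"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not -math.pi / 2 < self.deflection_angle < math.pi / 2:
            raise InvalidParameterError(
                "deflection angle must lie in (-90, 90) degrees"
            )
        for name in ("vibrissa_modulus", "vibrissa_radius", "follicle_length",
                     "wall_rigidity_factor", "skin_modulus"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.external_segment_length is None:
            object.__setattr__(
                self, "external_segment_length", 0.2 * self.follicle_length
            )
        elif self.external_segment_length <= 0:
            raise InvalidParameterError("external_segment_length must be positive")

    @property
    def second_moment(self) -> float:
        """Area moment of inertia I = pi R^4 / 4 of the whisker base."""
        return math.pi * self.vibrissa_radius**4 / 4.0

    @property
    def external_length(self) -> float:
        """Length of the whisker stub beyond the follicle entrance."""
        return self.external_segment_length

    @property
    def stiffnesses(self) -> tuple[float, ...]:
        return (self.k1, self.k2, self.k3, self.k4, self.k5, self.k6)

    def with_springs(self, **updates: float) -> "FollicleParameters":
        """Return a copy with some of k1..k6 replaced (sweep helper)."""
        return replace(self, **updates)

    def vibrissa_node_positions(self) -> np.ndarray:
        """Axial positions (m) of the five whisker nodes."""
        L = self.follicle_length
        x1, x2, x3, x4 = self.spring_positions
        return np.array([x1 * L, x2 * L, x3 * L, x4 * L, x4 * L + self.external_length])

    def wall_node_positions(self) -> np.ndarray:
        """Axial positions (m) of the four wall nodes."""
        L = self.follicle_length
        return np.array([x * L for x in self.spring_positions])


@dataclass
class DeformationProfiles:
    """Continuous displacement profiles reconstructed from a nodal solution.

    ``absolute`` is the whisker displacement u(x), ``wall`` the follicle-wall
    displacement f(x), ``relative`` their difference r(x) = u(x) - f(x), and
    ``shear`` the whisker shear force V(x) = EI u'''(x), all sampled on
    ``sample_positions`` in [0, L].  r(x) is the quantity that loads the
    mechanoreceptors.
    """

    sample_positions: np.ndarray
    absolute: np.ndarray
    wall: np.ndarray
    relative: np.ndarray
    shear: np.ndarray
    nodal: NodalSolution
    params: FollicleParameters = field(repr=False, default=None)

    def relative_at(self, x: float) -> float:
        """Interpolate r at axial position ``x`` (m)."""
        return float(np.interp(x, self.sample_positions, self.relative))

    @property
    def rs_position(self) -> float:
        """Axial position (m) of the ring-sinus spring."""
        return self.params.spring_positions[2] * self.params.follicle_length

    @property
    def rs_displacement(self) -> float:
        """Relative whisker displacement r at the ring-sinus level (m)."""
        return self.relative_at(self.rs_position)

    @property
    def deflection_direction(self) -> int:
        """Sign of the whisker's motion outside the follicle (+1 or -1)."""
        tip = self.nodal[9]  # translation of the external tip node
        return 1 if tip >= 0 else -1


def build_model(
    params: FollicleParameters,
) -> tuple[list[BeamElementSpec], list[SpringElementSpec], dict[int, float]]:
    """Construct the 13-element system for one parameter set.

    Returns the four whisker beam elements, three wall beam elements (EI
    scaled by ``wall_rigidity_factor``), six springs wired per the fixed DOF
    layout, and the boundary constraints: the prescribed entrance rotation
    and the two fixed ground translations.
    """
    E = params.vibrissa_modulus
    I = params.second_moment
    xv = params.vibrissa_node_positions()
    xw = params.wall_node_positions()

    beams: list[BeamElementSpec] = []
    for i in range(4):
        beams.append(
            BeamElementSpec(
                youngs_modulus=E,
                second_moment=I,
                length=float(xv[i + 1] - xv[i]),
                dof_indices=(2 * i + 1, 2 * i + 2, 2 * i + 3, 2 * i + 4),
            )
        )
    for j in range(3):
        beams.append(
            BeamElementSpec(
                youngs_modulus=E,
                second_moment=I * params.wall_rigidity_factor,
                length=float(xw[j + 1] - xw[j]),
                dof_indices=(11 + 2 * j, 12 + 2 * j, 13 + 2 * j, 14 + 2 * j),
            )
        )

    springs = [
        SpringElementSpec(stiffness=k, dof_indices=pair)
        for k, pair in zip(params.stiffnesses, SPRING_DOF_PAIRS)
    ]

    constraints = {ENTRANCE_ROTATION_DOF: params.deflection_angle, 19: 0.0, 20: 0.0}
    return beams, springs, constraints


def solve_model(params: FollicleParameters) -> tuple[NodalSolution, GlobalSystem]:
    """Assemble, apply boundary conditions and solve one model instance."""
    beams, springs, constraints = build_model(params)
    system = assemble_global(beams, springs, N_DOFS)
    beta = penalty_factor_for(
        system, mode=params.penalty_mode, youngs_modulus=params.vibrissa_modulus
    )
    constrained = apply_boundary_conditions(system, constraints, penalty_factor=beta)
    return solve_displacements(constrained), constrained


def _hermite_eval(
    x: np.ndarray, xa: float, xb: float, ua: float, ta: float, ub: float, tb: float
) -> tuple[np.ndarray, float]:
    """Cubic Hermite displacement on one element and its (constant) u'''."""
    Le = xb - xa
    xi = (x - xa) / Le
    n1 = 1 - 3 * xi**2 + 2 * xi**3
    n2 = Le * (xi - 2 * xi**2 + xi**3)
    n3 = 3 * xi**2 - 2 * xi**3
    n4 = Le * (-(xi**2) + xi**3)
    u = n1 * ua + n2 * ta + n3 * ub + n4 * tb
    u_xxx = (12 * (ua - ub) + 6 * Le * (ta + tb)) / Le**3
    return u, u_xxx


def compute_profiles(
    params: FollicleParameters, n_samples: int = 201
) -> DeformationProfiles:
    """Solve the model and reconstruct u(x), f(x), r(x) and V(x) on [0, L].

    The whisker profile u(x) is the elementwise cubic Hermite interpolant of
    the nodal translations and rotations, which solves EI u''' = V exactly
    between nodes since all loads are nodal spring forces.  The wall profile
    f(x) is the linear interpolant of the wall nodal translations (the wall
    is rigid, so its displacement field is affine).  The shear V(x) = EI u'''
    is piecewise constant, one value per whisker segment.
    """
    if n_samples < 2:
        raise InvalidParameterError("n_samples must be >= 2")
    nodal, _ = solve_model(params)
    d = nodal.displacement_vector
    L = params.follicle_length
    xv = params.vibrissa_node_positions()
    xw = params.wall_node_positions()
    EI = params.vibrissa_modulus * params.second_moment

    x = np.linspace(0.0, L, n_samples)
    u = np.empty_like(x)
    shear = np.empty_like(x)
    # whisker segments inside the follicle: nodes 1-2, 2-3, 3-4
    for i in range(3):
        mask = (x >= xv[i]) & (x <= xv[i + 1])
        ua, ta, ub, tb = d[2 * i], d[2 * i + 1], d[2 * i + 2], d[2 * i + 3]
        vals, u_xxx = _hermite_eval(x[mask], xv[i], xv[i + 1], ua, ta, ub, tb)
        u[mask] = vals
        shear[mask] = EI * u_xxx

    wall_nodal = d[[dof - 1 for dof in WALL_TRANSLATION_DOFS]]
    f = np.interp(x, xw, wall_nodal)
    return DeformationProfiles(
        sample_positions=x,
        absolute=u,
        wall=f,
        relative=u - f,
        shear=shear,
        nodal=nodal,
        params=params,
    )


#: Human-readable anatomical stiffness rules checked by
#: :func:`validate_anatomical_constraints`.
_RULES = (
    "k1 <= k2 < k4 (internal stiffness rises toward the entrance)",
    "k1 <= k3 < k4 (internal stiffness rises toward the entrance)",
    "k5 < k6 (skin end of the external support is the stiffer one)",
    "k4 >= 100 (k5 + k6) (entrance effectively clamps the whisker)",
    "k5 + k6 ~ E_skin * L (relaxed external support matches skin stiffness)",
)


def validate_anatomical_constraints(params: FollicleParameters) -> list[str]:
    """Check the stiffness orderings and magnitudes implied by anatomy.

    Returns an empty list when all rules hold, otherwise one message per
    violated rule.  The approximate skin-stiffness rule is enforced to within
    a factor of 3 either side (it is stated as an order-of-magnitude match).
    """
    k1, k2, k3, k4, k5, k6 = params.stiffnesses
    violations: list[str] = []
    if not (k1 <= k2 < k4):
        violations.append(f"violated: {_RULES[0]} -- k1={k1:g}, k2={k2:g}, k4={k4:g}")
    if not (k1 <= k3 < k4):
        violations.append(f"violated: {_RULES[1]} -- k1={k1:g}, k3={k3:g}, k4={k4:g}")
    if not k5 < k6:
        violations.append(f"violated: {_RULES[2]} -- k5={k5:g}, k6={k6:g}")
    if not k4 >= 100.0 * (k5 + k6):
        violations.append(
            f"violated: {_RULES[3]} -- k4={k4:g}, k5+k6={k5 + k6:g}"
        )
    skin_target = params.skin_modulus * params.follicle_length
    total = k5 + k6
    if total > 0 and not (skin_target / 3.0 <= total <= 3.0 * skin_target):
        violations.append(
            f"violated: {_RULES[4]} -- k5+k6={total:g}, E_skin*L={skin_target:g}"
        )
    return violations
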