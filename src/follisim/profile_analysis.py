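"""Classification and feasibility analysis of follicle deformation profiles.

The relative whisker displacement r(x) inside the follicle falls into three
shape classes distinguished by how often it crosses the resting axis:
C-shapes (no crossing, the whisker bows to one side), S1-shapes (one
crossing, a hook) and S2-shapes (two crossings).  An ex vivo imaging
experiment constrains the physically plausible profiles: the displacement
at the ring-sinus (RS) level must stay below 4.8 um for a 10 degree
deflection (12 um under a relaxed reading of the same data), and within the
RS window [0.55 L, 0.65 L] the whisker must displace to a single side,
opposite the deflection direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .follicle_model import DeformationProfiles, FollicleParameters

__all__ = [
    "ProfileClass",
    "FeasibilityVerdict",
    "classify_profile",
    "feasibility_test",
    "internal_force_rs",
    "DegenerateProfileError",
    "RS_BOUND_DEFAULT",
    "RS_BOUND_RELAXED",
    "RS_WINDOW",
]

#: Ex vivo displacement bound at the RS level (m): mean observed displacement.
RS_BOUND_DEFAULT = 4.8e-6
#: Relaxed bound (m): maximal observed displacement.
RS_BOUND_RELAXED = 12e-6
#: RS window as fractions of follicle length.
RS_WINDOW = (0.55, 0.65)

#: Samples with |r| below this fraction of max|r| are treated as zero when
#: counting axis crossings (suppresses spurious crossings near the clamped
#: entrance where r ~ 0).
CROSSING_EPSILON = 1e-3


#: Fraction of L adjacent to the follicle entrance excluded from crossing
#: counting.  The entrance spring k4 is stiff but finite, so every profile
#: carries a small real recoil excursion (|r| of order 0.1 um) immediately
#: below the entrance; it is invisible at plot scale and not part of the
#: C/S1/S2 taxonomy, yet its magnitude overlaps genuine ring-sinus
#: excursions, so it is excluded by position rather than by amplitude.  The
#: 0.05 L layer mirrors the half-width of the RS window.
ENTRANCE_EXCLUSION = 0.05


class DegenerateProfileError(ValueError):
    """The relative displacement is identically ~0; no shape class applies."""


@dataclass(frozen=True)
class ProfileClass:
    """Shape class of a deformation profile.

    ``label`` is "C", "S1" or "S2" for 0, 1 or 2 axis crossings of r(x) on
    the open interval (0, L); ``crossing_positions`` are the interpolated
    crossing locations in metres.
    """

    label: str
    crossing_positions: tuple[float, ...]

    @property
    def n_crossings(self) -> int:
        return len(self.crossing_positions)


@dataclass(frozen=True)
class FeasibilityVerdict:
    """Outcome of testing a profile against the ex vivo constraints."""

    feasible: bool
    rs_displacement: float
    reasons: tuple[str, ...]


def classify_profile(
    profiles: DeformationProfiles, epsilon: float = CROSSING_EPSILON
) -> ProfileClass:
    """Classify r(x) by its number of axis crossings inside (0, 0.95 L).

    Endpoint samples and the entrance boundary layer (the top
    :data:`ENTRANCE_EXCLUSION` fraction of L, see note there) are excluded,
    and samples with ``|r| < epsilon * max|r|`` are ignored.  Crossing
    positions are found by linear interpolation between the flanking
    significant samples.
    """
    x = profiles.sample_positions
    r = profiles.relative
    if len(x) < 50:
        raise ValueError("profile must be sampled on at least 50 points")
    rmax = np.max(np.abs(r))
    if rmax == 0.0:
        raise DegenerateProfileError("relative displacement is identically zero")
    L = profiles.params.follicle_length
    interior = (x > x[0]) & (x < (1.0 - ENTRANCE_EXCLUSION) * L)
    xi, ri = x[interior], r[interior]
    keep = np.abs(ri) >= epsilon * rmax
    if not np.any(keep):
        raise DegenerateProfileError("relative displacement is ~0 everywhere")
    xs, rs = xi[keep], ri[keep]
    signs = np.sign(rs)
    flips = np.nonzero(signs[1:] != signs[:-1])[0]
    crossings = []
    for i in flips:
        x0, x1, r0, r1 = xs[i], xs[i + 1], rs[i], rs[i + 1]
        crossings.append(float(x0 - r0 * (x1 - x0) / (r1 - r0)))
    n = len(crossings)
    label = {0: "C", 1: "S1", 2: "S2"}.get(n, f"S{n}")
    return ProfileClass(label=label, crossing_positions=tuple(crossings))


def feasibility_test(
    profiles: DeformationProfiles, rs_bound: float = RS_BOUND_DEFAULT
) -> FeasibilityVerdict:
    """Test a profile against the ex vivo RS-level constraints.

    Feasible iff (i) |r| at the RS level is strictly below ``rs_bound``,
    (ii) r keeps a constant sign throughout the RS window [0.55 L, 0.65 L],
    and (iii) that sign is opposite the direction of the external whisker
    deflection.  ``rs_bound`` defaults to the 4.8 um mean-displacement bound;
    pass :data:`RS_BOUND_RELAXED` for the 12 um variant.
    """
    x = profiles.sample_positions
    r = profiles.relative
    L = profiles.params.follicle_length
    rs_disp = profiles.rs_displacement
    reasons: list[str] = []

    if not abs(rs_disp) < rs_bound:
        reasons.append(
            f"|r| at RS = {abs(rs_disp) * 1e6:.3g} um >= bound {rs_bound * 1e6:g} um"
        )

    lo, hi = RS_WINDOW
    window = (x >= lo * L) & (x <= hi * L)
    rw = r[window]
    signs = set(np.sign(rw[rw != 0.0]))
    if len(signs) > 1:
        reasons.append("sign change of r inside the RS window")
        window_sign = 0
    elif not signs:
        window_sign = 0
    else:
        window_sign = int(signs.pop())

    direction = profiles.deflection_direction
    if window_sign != 0 and window_sign != -direction:
        reasons.append(
            "r in the RS window points along the deflection direction, "
            "not opposite to it"
        )

    return FeasibilityVerdict(
        feasible=not reasons, rs_displacement=rs_disp, reasons=tuple(reasons)
    )


def internal_force_rs(
    params: FollicleParameters, profiles: DeformationProfiles
) -> float:
    """Signed internal force (N) on the tissue at the ring-sinus level.

    The force between whisker shaft and RS tissue is the spring force
    k3 * r at the RS station.
    """
    return params.k3 * profiles.rs_displacement
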