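"""Parameter-sweep experiments over the follicle model.

Four deterministic sweeps probe how the stiffness parameters shape the
relative whisker displacement r(x):

* :func:`k1_sensitivity_sweep` -- vary the hair-bulb spring k1 over four
  decades under a grid of (k2, k3) pairs; the spread of the resulting
  profile bundle shows where k1 matters (near the cavernous sinus) and where
  it does not (at the ring sinus).
* :func:`k2k3_feasibility_map` -- classify the profile (C/S1/S2) and test ex
  vivo feasibility over a log grid of (k2, k3) pairs with k1 fixed.
* :func:`external_support_sweep` -- vary the total external support k5+k6
  (muscle tone) and its balance k5/k6; stiffer and more balanced support
  both increase r at the ring sinus, the proposed signature of active
  whisking.
* :func:`blood_pressure_sweep` -- vary the ring-sinus spring k3 (a proxy for
  sinus blood pressure); displacement at the RS falls but the internal force
  k3*r rises.

Each sweep returns a :class:`SweepResult` holding a tidy table (one row per
grid point) plus the grid definition, and is bit-reproducible: the pipeline
contains no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .follicle_model import DeformationProfiles, FollicleParameters, compute_profiles
from .profile_analysis import (
    RS_BOUND_DEFAULT,
    classify_profile,
    feasibility_test,
    internal_force_rs,
)

__all__ = [
    "SweepResult",
    "k1_sensitivity_sweep",
    "mean_rs_spread",
    "max_cs_spread",
    "k2k3_feasibility_map",
    "external_support_sweep",
    "blood_pressure_sweep",
    "CS_WINDOW_HALF_WIDTH",
]

#: Half-width (fraction of L) of the window around the cavernous-sinus spring
#: used when reporting the maximal k1-induced profile spread "near the CS";
#: mirrors the half-width of the ring-sinus window [0.55 L, 0.65 L].
CS_WINDOW_HALF_WIDTH = 0.05

_DEF_N_1D = 9
_DEF_N_MAP = 13


@dataclass
class SweepResult:
    """Tidy result of one parameter sweep.

    ``table`` has one row per grid point; ``metadata`` records the grid
    definition and base parameters so the sweep can be reproduced exactly.
    ``profiles`` optionally keeps full r(x) arrays keyed by grid point for
    downstream plotting or window statistics.
    """

    table: pd.DataFrame
    metadata: dict
    profiles: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _profile_row(profiles: DeformationProfiles, rs_bound: float) -> dict:
    cls = classify_profile(profiles)
    verdict = feasibility_test(profiles, rs_bound=rs_bound)
    return {
        "rs_disp_um": profiles.rs_displacement * 1e6,
        "class": cls.label,
        "feasible": verdict.feasible,
        "force_N": internal_force_rs(profiles.params, profiles),
    }


def k1_sensitivity_sweep(
    base: FollicleParameters,
    k1_range: Sequence[float] | None = None,
    k2_values: Sequence[float] | None = None,
    k3_values: Sequence[float] | None = None,
    n_samples: int = 201,
) -> SweepResult:
    """Spread of r(x) over k1, for each (k2, k3) combination.

    Defaults: k1 on a 9-point log grid over [1e2, 1e6] N/m, k2 over four
    log-spaced values in [1e3, 1e6], k3 over four in [1e4, 1e6].  For each
    (k2, k3) the sweep records the spread (max minus min over k1) of r at
    the ring-sinus level, and the profile-wise maximal spread with its
    location.  Full spread profiles are kept in ``profiles`` keyed by
    ``(k2, k3)``.
    """
    k1s = np.asarray(k1_range if k1_range is not None else np.logspace(2, 6, _DEF_N_1D))
    k2s = np.asarray(k2_values if k2_values is not None else np.logspace(3, 6, 4))
    k3s = np.asarray(k3_values if k3_values is not None else np.logspace(4, 6, 4))

    rows = []
    spread_profiles: dict = {}
    for k2 in k2s:
        for k3 in k3s:
            bundle = []
            for k1 in k1s:
                p = compute_profiles(
                    base.with_springs(k1=float(k1), k2=float(k2), k3=float(k3)),
                    n_samples,
                )
                bundle.append(p.relative)
            x = p.sample_positions
            bundle = np.asarray(bundle)
            spread = bundle.max(axis=0) - bundle.min(axis=0)
            spread_profiles[(float(k2), float(k3))] = spread
            rs_x = p.rs_position
            i_max = int(np.argmax(spread))
            rows.append(
                {
                    "k2_N_per_m": float(k2),
                    "k3_N_per_m": float(k3),
                    "spread_rs_um": float(np.interp(rs_x, x, spread)) * 1e6,
                    "spread_max_um": float(spread[i_max]) * 1e6,
                    "spread_max_x_mm": float(x[i_max]) * 1e3,
                }
            )
    table = pd.DataFrame(rows)
    meta = {
        "sweep": "k1_sensitivity",
        "k1_grid": k1s.tolist(),
        "k2_grid": k2s.tolist(),
        "k3_grid": k3s.tolist(),
        "n_samples": n_samples,
        "base": _base_meta(base),
    }
    return SweepResult(
        table=table,
        metadata=meta,
        profiles={"x": np.linspace(0, base.follicle_length, n_samples), **spread_profiles},
    )


def mean_rs_spread(result: SweepResult) -> float:
    """Mean over (k2, k3) combinations of the k1-spread at the RS level (m)."""
    return float(result.table["spread_rs_um"].mean()) * 1e-6


def max_cs_spread(
    result: SweepResult,
    base: FollicleParameters,
    k2: float | None = None,
    half_width: float = CS_WINDOW_HALF_WIDTH,
) -> float:
    """Maximal k1-spread (m) near the cavernous sinus for one k2 column.

    ``k2`` defaults to the smallest swept value, where the spread is widest.
    The window is ``CS position +/- half_width * L``.
    """
    x = result.profiles["x"]
    L = base.follicle_length
    cs = base.spring_positions[1]
    window = (x >= (cs - half_width) * L) & (x <= (cs + half_width) * L)
    combos = [key for key in result.profiles if isinstance(key, tuple)]
    if k2 is None:
        k2 = min(kk2 for kk2, _ in combos)
    best = 0.0
    for kk2, kk3 in combos:
        if kk2 != k2:
            continue
        best = max(best, float(result.profiles[(kk2, kk3)][window].max()))
    return best


def k2k3_feasibility_map(
    base: FollicleParameters,
    grid_bounds: tuple[float, float] = (1e3, 1e6),
    n_per_axis: int = _DEF_N_MAP,
    rs_bound: float = RS_BOUND_DEFAULT,
    k1: float = 1e3,
    n_samples: int = 201,
) -> SweepResult:
    """Shape class and feasibility over a log grid of (k2, k3) pairs.

    k1 is held at an intermediate value (default 1e3 N/m, justified by its
    negligible effect at the RS).  Metadata records per-class counts.
    """
    lo, hi = grid_bounds
    grid = np.logspace(np.log10(lo), np.log10(hi), n_per_axis)
    rows = []
    profs: dict = {}
    for k2 in grid:
        for k3 in grid:
            p = compute_profiles(
                base.with_springs(k1=k1, k2=float(k2), k3=float(k3)), n_samples
            )
            row = {"k2_N_per_m": float(k2), "k3_N_per_m": float(k3)}
            row.update(_profile_row(p, rs_bound))
            rows.append(row)
            profs[(float(k2), float(k3))] = p.relative
    table = pd.DataFrame(rows)
    counts = table["class"].value_counts().to_dict()
    meta = {
        "sweep": "k2k3_feasibility_map",
        "grid": grid.tolist(),
        "k1": k1,
        "rs_bound_um": rs_bound * 1e6,
        "n_samples": n_samples,
        "class_counts": counts,
        "base": _base_meta(base),
    }
    profs["x"] = np.linspace(0, base.follicle_length, n_samples)
    return SweepResult(table=table, metadata=meta, profiles=profs)


def _support_params(
    base: FollicleParameters, total: float, ratio: float
) -> FollicleParameters:
    """Parameters with external support of given total k5+k6 and ratio k5/k6."""
    k6 = total / (1.0 + ratio)
    k5 = total - k6
    return base.with_springs(k5=k5, k6=k6)


def external_support_sweep(
    base: FollicleParameters,
    total_values: Sequence[float] | None = None,
    ratio_values: Sequence[float] | None = None,
    rs_bound: float = RS_BOUND_DEFAULT,
    n_samples: int = 201,
) -> SweepResult:
    """Effect of external (muscle/tissue) support on r at the ring sinus.

    Two 1-D scans: the *total* scan varies k5+k6 over [1e4, 1e5] N/m at the
    resting balance k6/k5 = 7/3; the *ratio* scan varies k5/k6 over
    [1/20, 20] at total 1e4 N/m.  Each row records r at the RS and its value
    relative to the scan baseline (total 1e4 N/m, resp. balanced ratio 1).
    """
    totals = np.asarray(
        total_values if total_values is not None else np.logspace(4, 5, _DEF_N_1D)
    )
    ratios = np.asarray(
        ratio_values
        if ratio_values is not None
        else np.logspace(np.log10(1 / 20), np.log10(20), _DEF_N_1D)
    )
    rows = []
    for total in totals:
        p = compute_profiles(_support_params(base, float(total), 3.0 / 7.0), n_samples)
        row = {
            "scan": "total",
            "k5_plus_k6_N_per_m": float(total),
            "k5_over_k6": 3.0 / 7.0,
        }
        row.update(_profile_row(p, rs_bound))
        rows.append(row)
    for ratio in ratios:
        p = compute_profiles(_support_params(base, 1e4, float(ratio)), n_samples)
        row = {
            "scan": "ratio",
            "k5_plus_k6_N_per_m": 1e4,
            "k5_over_k6": float(ratio),
        }
        row.update(_profile_row(p, rs_bound))
        rows.append(row)
    table = pd.DataFrame(rows)

    # relative change vs the scan baseline
    tot_mask = table["scan"] == "total"
    base_tot = table.loc[tot_mask].iloc[
        int(np.argmin(np.abs(totals - totals.min())))
    ]["rs_disp_um"]
    rat_mask = table["scan"] == "ratio"
    i_balanced = int(np.argmin(np.abs(np.log(ratios))))
    base_rat = table.loc[rat_mask].iloc[i_balanced]["rs_disp_um"]
    rel = np.where(
        tot_mask, table["rs_disp_um"] / base_tot, table["rs_disp_um"] / base_rat
    )
    table["rs_disp_rel_baseline"] = rel

    meta = {
        "sweep": "external_support",
        "total_grid": totals.tolist(),
        "ratio_grid": ratios.tolist(),
        "rs_bound_um": rs_bound * 1e6,
        "n_samples": n_samples,
        "base": _base_meta(base),
    }
    return SweepResult(table=table, metadata=meta)


def blood_pressure_sweep(
    base: FollicleParameters,
    k3_values: Sequence[float] | None = None,
    rs_bound: float = RS_BOUND_DEFAULT,
    n_samples: int = 201,
) -> SweepResult:
    """Effect of ring-sinus stiffness k3 (blood-pressure proxy) at the RS.

    k3 runs over [1e5, 1e6] N/m by default.  Each row records r at the RS,
    the internal force k3*r, and both relative to the base state k3 = the
    smallest swept value.
    """
    k3s = np.asarray(
        k3_values if k3_values is not None else np.logspace(5, 6, _DEF_N_1D)
    )
    rows = []
    for k3 in k3s:
        p = compute_profiles(base.with_springs(k3=float(k3)), n_samples)
        row = {"k3_N_per_m": float(k3)}
        row.update(_profile_row(p, rs_bound))
        rows.append(row)
    table = pd.DataFrame(rows)
    base_row = table.iloc[int(np.argmin(k3s))]
    table["rs_disp_rel_base"] = table["rs_disp_um"] / base_row["rs_disp_um"]
    table["force_rel_base"] = table["force_N"] / base_row["force_N"]
    meta = {
        "sweep": "blood_pressure",
        "k3_grid": k3s.tolist(),
        "rs_bound_um": rs_bound * 1e6,
        "n_samples": n_samples,
        "base": _base_meta(base),
    }
    return SweepResult(table=table, metadata=meta)


def _base_meta(base: FollicleParameters) -> dict:
    return {
        "vibrissa_modulus_Pa": base.vibrissa_modulus,
        "vibrissa_radius_m": base.vibrissa_radius,
        "follicle_length_m": base.follicle_length,
        "k_N_per_m": list(base.stiffnesses),
        "spring_positions": list(base.spring_positions),
        "wall_rigidity_factor": base.wall_rigidity_factor,
        "deflection_angle_rad": base.deflection_angle,
        "penalty_mode": base.penalty_mode,
    }
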