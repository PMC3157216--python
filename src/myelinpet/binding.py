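"""Single-site saturable ligand-target binding.

Equilibrium of L + T <-> LT with dissociation constant Kd.  With total
concentrations L (ligand) and T (target), the bound complex LT solves

    LT^2 - (T + L + Kd) LT + T L = 0,

and the physical root is the one not exceeding min(T, L).  The quadratic is
evaluated in the cancellation-free form 2TL / (b + sqrt(b^2 - 4TL)) because
T/Kd spans many orders of magnitude in myelin imaging (up to ~1e6).

The kinetic rates obey koff = kon * Kd, so the rate pair is parameterised by
(kd, kon) only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BindingParams:
    """Agent-target binding parameters.

    kd : molar dissociation constant (> 0)
    kon : association rate in M^-1 s^-1 (> 0)
    koff : dissociation rate in s^-1, derived exactly as kon * kd
    """

    kd: float
    kon: float

    def __post_init__(self) -> None:
        if self.kd <= 0.0:
            raise ValueError(f"kd must be > 0, got {self.kd}")
        if self.kon <= 0.0:
            raise ValueError(f"kon must be > 0, got {self.kon}")

    @property
    def koff(self) -> float:
        return self.kon * self.kd


def bound_complex_concentration(total_target: float, total_ligand: float, kd: float) -> float:
    """Equilibrium complex concentration LT (same units as the inputs)."""
    if kd <= 0.0:
        raise ValueError("kd must be > 0")
    if total_target < 0.0 or total_ligand < 0.0:
        raise ValueError("concentrations must be >= 0")
    if total_target == 0.0 or total_ligand == 0.0:
        return 0.0
    b = total_target + total_ligand + kd
    disc = b * b - 4.0 * total_target * total_ligand
    # disc >= kd^2 > 0 analytically; guard against rounding.
    root = math.sqrt(max(disc, 0.0))
    return 2.0 * total_target * total_ligand / (b + root)


def equilibrium_bound_fraction(total_target: float, total_ligand: float, kd: float) -> float:
    """Fraction of total ligand bound at equilibrium, in [0, 1].

    Returns 0 for zero total ligand by convention.  In the trace-ligand limit
    the result approaches the closed form T / (T + Kd).
    """
    if total_ligand == 0.0:
        if total_target < 0.0:
            raise ValueError("concentrations must be >= 0")
        return 0.0
    lt = bound_complex_concentration(total_target, total_ligand, kd)
    return min(lt / total_ligand, 1.0)


def bound_fraction_curve(target_over_kd, ligand_over_kd: float) -> np.ndarray:
    """Bound-ligand fraction along a grid of target/Kd ratios.

    Concentrations are normalised to Kd = 1, so the curve depends only on the
    two ratios.  Non-decreasing in ``target_over_kd``; equals x/(x+1) in the
    trace-ligand limit.
    """
    grid = np.asarray(target_over_kd, dtype=float)
    if grid.size == 0:
        raise ValueError("empty target_over_kd grid")
    if np.any(grid < 0.0) or ligand_over_kd < 0.0:
        raise ValueError("ratios must be >= 0")
    return np.array(
        [equilibrium_bound_fraction(t, ligand_over_kd, 1.0) for t in grid.ravel()]
    ).reshape(grid.shape)


def binding_curve_frame(target_over_kd, ligand_over_kd: float):
    """Curve as a two-column DataFrame, convenient for CSV export."""
    import pandas as pd

    grid = np.asarray(target_over_kd, dtype=float)
    return pd.DataFrame(
        {
            "target_over_kd": grid,
            "bound_fraction": bound_fraction_curve(grid, ligand_over_kd),
        }
    )
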