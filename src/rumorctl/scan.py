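"""Parameter-space classification of the positive equilibria.

For a fixed base parameter set, varying the recovery contact rate ``alpha``
and the control threshold ``Ith`` moves the two positive equilibria between
regular and virtual: the free subsystem's spreader level is I_S1 = mu/alpha
and the controlled subsystem's I_S2 < I_S1 whenever both exist.  The ordering
of Ith against these two levels yields the three-region bifurcation set whose
boundary curves in the (alpha, Ith) plane are Ith = mu/alpha and
Ith = I_S2(alpha); between the curves both equilibria are virtual and the
sliding flow's pseudo-equilibrium takes over.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_model import ModelParams
from .equilibria import positive_root_S2
from .sliding import pseudo_equilibrium

__all__ = ["RegionLabel", "classify_region", "bifurcation_grid", "boundary_curves"]


@dataclass(frozen=True)
class RegionLabel:
    """Three-way region label plus the raw free-subsystem case index."""

    label: str  # P13_regular_P22_virtual | both_virtual_pseudo |
    #             P22_regular_P13_virtual | no_positive_equilibrium | other
    s1_case: str | None  # "i".."vi" per the free-subsystem case list, if applicable


def _s1_case(p: ModelParams) -> str | None:
    """Raw case index for the two internal equilibria of the free subsystem."""
    if not (p.Lambda * p.beta > p.mu**2):
        return None  # no internal equilibrium at all
    I12 = (p.Lambda * p.beta - p.mu**2) / (p.beta * p.mu)
    I13 = p.mu / p.alpha
    if I12 < I13:  # positive equilibrium absent
        if I12 < p.Ith:
            return "i"
        return "ii"
    if I13 < I12 < p.Ith:
        return "iii"
    if I13 < p.Ith < I12:
        return "iv"
    if p.Ith < I13 < I12:
        return "vi"
    return None  # a tie between the dividing quantities


def classify_region(alpha: float, Ith: float, base: ModelParams) -> RegionLabel:
    """Region of the (alpha, Ith) plane at one point, base parameters fixed.

    Recomputes I_S1 = mu/alpha and I_S2 at the overridden alpha and orders the
    threshold against them.
    """
    if not (alpha > 0.0 and Ith > 0.0):
        raise ValueError("alpha and Ith must be positive")
    p = replace(base, alpha=alpha, Ith=Ith)
    s1_case = _s1_case(p)
    exists_13 = p.beta * p.Lambda * p.alpha - p.mu**2 * (p.alpha + p.beta) > 0.0
    R2 = positive_root_S2(p)
    if not exists_13 or R2 is None:
        return RegionLabel("no_positive_equilibrium", s1_case)
    I_S1 = p.mu / p.alpha
    I_S2 = p.mu * R2 / (p.alpha * R2 + p.q)
    if Ith < I_S2 < I_S1:
        return RegionLabel("P22_regular_P13_virtual", s1_case)
    if I_S2 < Ith < I_S1 and pseudo_equilibrium(p) is not None:
        return RegionLabel("both_virtual_pseudo", s1_case)
    if I_S2 < I_S1 < Ith:
        return RegionLabel("P13_regular_P22_virtual", s1_case)
    return RegionLabel("other", s1_case)


def boundary_curves(alphas: np.ndarray, base: ModelParams) -> pd.DataFrame:
    """The two region boundaries Ith = mu/alpha and Ith = I_S2(alpha)."""
    rows = []
    for a in np.asarray(alphas, dtype=float):
        p = replace(base, alpha=float(a))
        R2 = positive_root_S2(p)
        I_S2 = p.mu * R2 / (p.alpha * R2 + p.q) if R2 is not None else np.nan
        rows.append({"alpha": float(a), "Ith_IS1": p.mu / a, "Ith_IS2": I_S2})
    return pd.DataFrame(rows)


def bifurcation_grid(
    alpha_range: tuple[float, float],
    Ith_range: tuple[float, float],
    n_alpha: int,
    n_Ith: int,
    base: ModelParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rectangular grid of region labels plus the sampled boundary curves."""
    if n_alpha < 2 or n_Ith < 2:
        raise ValueError("grid needs at least 2 points per axis")
    if not (alpha_range[0] > 0.0 and Ith_range[0] > 0.0):
        raise ValueError("ranges must be positive")
    alphas = np.linspace(*alpha_range, n_alpha)
    Iths = np.linspace(*Ith_range, n_Ith)
    rows = []
    for a in alphas:
        for ith in Iths:
            lab = classify_region(float(a), float(ith), base)
            rows.append(
                {"alpha": float(a), "Ith": float(ith), "label": lab.label, "s1_case": lab.s1_case}
            )
    return pd.DataFrame(rows), boundary_curves(alphas, base)
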