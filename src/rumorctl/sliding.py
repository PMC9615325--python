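"""Sliding-mode geometry and dynamics on the switching plane I = Ith.

Both smooth fields point toward the plane on the band

    Sigma_S = {(S, Ith, R) : mu <= beta*S - alpha*R <= mu + q},

bounded by the two tangency lines.  On the band, Utkin's equivalent control

    eps = (beta*S - alpha*R - mu) / q

is the convex weight in [0, 1] that annihilates the normal (I) component of the
combined field, and coincides with the Filippov convex coefficient.  Replacing
the discontinuous control by eps*q*Ith gives the planar sliding flow

    dS/dt = Lambda - beta*S*Ith - mu*S
    dR/dt = Ith*beta*S - mu*R - mu*Ith          (derived variant)

in which the delayed recovery terms cancel algebraically, so the sliding flow
is delay-free.  The "printed" variant keeps the delay on the R-removal term
(dR/dt = Ith*beta*S - mu*R(t-tau) - mu*Ith); it is retained for comparison
since the two variants have different stability (the printed one obeys the
Hayes criterion mu*tau < pi/2 instead of being unconditionally stable).

The rest point of the sliding flow is the pseudo-equilibrium

    S_p = Lambda / (beta*Ith + mu),   R_p = Ith*(beta*S_p - mu)/mu,

admissible whenever eps(S_p, R_p) lies strictly inside (0, 1).
"""

from __future__ import annotations

import math

from .core_model import ModelParams, State
from .equilibria import Equilibrium

__all__ = [
    "sigma",
    "equivalent_control",
    "sliding_drift",
    "pseudo_equilibrium",
    "pseudo_stability",
    "sliding_band",
]


def sigma(S: float, R: float, p: ModelParams) -> float:
    """Product of the two fields' normal components on I = Ith.

    Negative exactly on the open sliding segment (both fields point toward the
    plane); zero on the tangency lines.
    """
    g = p.beta * S - p.alpha * R - p.mu
    return g * (g - p.q) * p.Ith**2


def equivalent_control(S: float, R: float, p: ModelParams) -> float:
    """Utkin equivalent control eps = (beta*S - alpha*R - mu)/q.

    Lies in [0, 1] exactly on the sliding band; the caller checks
    admissibility.  Identical to the Filippov convex coefficient on the plane.
    """
    return (p.beta * S - p.alpha * R - p.mu) / p.q


def sliding_band(S: float, R: float, p: ModelParams) -> bool:
    """True iff (S, Ith, R) lies in the closed sliding band."""
    g = p.beta * S - p.alpha * R
    return p.mu <= g <= p.mu + p.q


def sliding_drift(
    S: float,
    delayed_R: float,
    R: float,
    p: ModelParams,
    variant: str = "derived",
) -> tuple[float, float]:
    """(dS, dR) of the sliding flow with I pinned at Ith.

    ``variant="derived"`` removes the instantaneous R (the delayed terms
    cancel when the equivalent control is substituted); ``variant="printed"``
    removes the delayed R instead.  The two agree whenever delayed_R == R, in
    particular at every rest point and for tau = 0.
    """
    dS = p.Lambda - p.beta * S * p.Ith - p.mu * S
    if variant == "derived":
        dR = p.Ith * p.beta * S - p.mu * R - p.mu * p.Ith
    elif variant == "printed":
        dR = p.Ith * p.beta * S - p.mu * delayed_R - p.mu * p.Ith
    else:
        raise ValueError(f"unknown sliding variant {variant!r}")
    return dS, dR


def pseudo_equilibrium(p: ModelParams) -> Equilibrium | None:
    """Rest point of the sliding flow, if it lies strictly inside the band.

    Returns None when the equivalent control at the rest point leaves (0, 1),
    i.e. when the threshold is outside the (I_S2, I_S1) window.
    """
    Sp = p.Lambda / (p.beta * p.Ith + p.mu)
    Rp = p.Ith * (p.beta * Sp - p.mu) / p.mu
    eps = equivalent_control(Sp, Rp, p)
    if not (0.0 < eps < 1.0):
        return None
    return Equilibrium(State(Sp, p.Ith, Rp), "sliding", "positive", "pseudo")


def pseudo_stability(p: ModelParams, variant: str = "derived") -> bool:
    """Local stability of the pseudo-equilibrium under the chosen sliding flow.

    The S-equation contributes the always-stable factor lambda = -(beta*Ith+mu).
    The derived flow's R-factor is lambda = -mu, stable for every delay; the
    printed flow's R-factor is lambda + mu*e^{-lambda*tau} = 0, stable iff
    mu*tau < pi/2 (Hayes criterion).
    """
    if pseudo_equilibrium(p) is None:
        raise ValueError("pseudo-equilibrium does not exist for these parameters")
    if variant == "derived":
        return True
    if variant == "printed":
        return p.mu * p.tau < math.pi / 2.0
    raise ValueError(f"unknown sliding variant {variant!r}")
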