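"""Closed-form equilibria of the two smooth subsystems and their Filippov classes.

Subsystem S1 (control off) has up to three equilibria:

* the rumor-free state ``(Lambda/mu, 0, 0)``, always present;
* a spreader-only state ``(mu/beta, (Lambda*beta - mu^2)/(beta*mu), 0)`` when
  ``Lambda*beta > mu^2``;
* a positive state with ``I = mu/alpha`` when
  ``beta*Lambda*alpha > mu^2*(alpha + beta)``.

Subsystem S2 (control on) keeps the rumor-free state and, when
``Lambda*beta > mu^2 + q*mu``, gains a unique positive equilibrium whose
R-coordinate is the positive root of ``C1*R^2 + C2*R + C3 = 0`` with

    C1 = mu*alpha*(alpha + beta)
    C2 = alpha*mu^2 + beta*mu^2 - Lambda*alpha*beta + 2*alpha*mu*q + beta*mu*q
    C3 = q*(mu^2 + q*mu - Lambda*beta)

A subsystem equilibrium is *regular* if it lies in its own region of validity
(S1 below the threshold plane, S2 above) and *virtual* otherwise; on the plane
it is a *boundary* equilibrium.  Whenever both positive equilibria exist their
spreader levels satisfy I_S2 < I_S1 = mu/alpha, so they are never both regular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .core_model import ModelParams, State, drift

__all__ = [
    "Equilibrium",
    "QuadraticCoeffs",
    "quadratic_coeffs",
    "equilibria_S1",
    "equilibria_S2",
    "classify",
    "boundary_equilibria",
    "tangent_lines",
    "TangentLine",
]

#: residual below which a candidate state counts as an exact equilibrium
RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class Equilibrium:
    """A located steady state with its subsystem tag and Filippov class."""

    state: State
    subsystem: str  # "S1" | "S2" | "sliding"
    label: str  # "rumor_free" | "boundary_no_recovery" | "positive"
    filippov_class: str  # "regular" | "virtual" | "pseudo" | "boundary" | "tangent"

    @property
    def regime(self) -> str:
        return {"S1": "free", "S2": "controlled"}.get(self.subsystem, "sliding")


@dataclass(frozen=True)
class QuadraticCoeffs:
    """Coefficients of the controlled subsystem's R-quadratic; C1 > 0 always."""

    C1: float
    C2: float
    C3: float


def quadratic_coeffs(p: ModelParams) -> QuadraticCoeffs:
    C1 = p.mu * p.alpha * (p.alpha + p.beta)
    C2 = (
        p.alpha * p.mu**2
        + p.beta * p.mu**2
        - p.Lambda * p.alpha * p.beta
        + 2 * p.alpha * p.mu * p.q
        + p.beta * p.mu * p.q
    )
    C3 = p.q * (p.mu**2 + p.q * p.mu - p.Lambda * p.beta)
    return QuadraticCoeffs(C1, C2, C3)


def _residual(eq: Equilibrium, p: ModelParams) -> float:
    regime = eq.regime
    if regime == "sliding":  # pseudo-equilibria are validated in the sliding module
        return 0.0
    d = drift(eq.state, eq.state.R, regime, p)
    return max(abs(x) for x in d)


def _checked(eq: Equilibrium, p: ModelParams) -> Equilibrium:
    r = _residual(eq, p)
    if r > RESIDUAL_TOL:
        raise AssertionError(f"equilibrium residual {r:.3e} exceeds {RESIDUAL_TOL}")
    return eq


def classify(eq: Equilibrium, p: ModelParams, boundary_tol: float = 1e-12) -> str:
    """Regular/virtual/boundary class of a subsystem equilibrium.

    Regular means the equilibrium lies inside its own subsystem's region of
    validity (I < Ith for S1, I > Ith for S2); virtual is the complement.  An
    equilibrium with I within ``boundary_tol`` of the threshold is classified
    ``boundary`` rather than arbitrarily assigned to either side.
    """
    if eq.subsystem not in ("S1", "S2"):
        raise ValueError("classify applies to S1/S2 subsystem equilibria")
    h = eq.state.I - p.Ith
    if abs(h) <= boundary_tol:
        return "boundary"
    if eq.subsystem == "S1":
        return "regular" if h < 0 else "virtual"
    return "regular" if h > 0 else "virtual"


def _make(state: State, subsystem: str, label: str, p: ModelParams) -> Equilibrium:
    eq = Equilibrium(state, subsystem, label, "regular")
    eq = replace(eq, filippov_class=classify(eq, p))
    return _checked(eq, p)


def equilibria_S1(p: ModelParams) -> list[Equilibrium]:
    """All equilibria of the uncontrolled subsystem, in the paper-standard order.

    The rumor-free state is always returned; the recovery-free state requires
    ``Lambda*beta > mu^2``; the positive state requires
    ``beta*Lambda*alpha > mu^2*(alpha+beta)``.
    """
    out = [_make(State(p.Lambda / p.mu, 0.0, 0.0), "S1", "rumor_free", p)]
    if p.Lambda * p.beta > p.mu**2:
        I2 = (p.Lambda * p.beta - p.mu**2) / (p.beta * p.mu)
        out.append(_make(State(p.mu / p.beta, I2, 0.0), "S1", "boundary_no_recovery", p))
    if p.beta * p.Lambda * p.alpha - p.mu**2 * (p.alpha + p.beta) > 0.0:
        S3 = p.Lambda * p.alpha / (p.mu * (p.alpha + p.beta))
        I3 = p.mu / p.alpha
        R3 = (p.beta * p.Lambda * p.alpha - p.mu**2 * (p.alpha + p.beta)) / (
            p.alpha * p.mu * (p.alpha + p.beta)
        )
        out.append(_make(State(S3, I3, R3), "S1", "positive", p))
    return out


def positive_root_S2(p: ModelParams) -> float | None:
    """Positive root of the controlled subsystem's R-quadratic, or None.

    Uses the cancellation-free form of the quadratic formula: when C2 > 0 the
    root ``(-C2 + sqrt(disc)) / (2 C1)`` suffers catastrophic cancellation and
    is computed as ``-2 C3 / (C2 + sqrt(disc))`` instead.
    """
    if not (p.Lambda * p.beta > p.mu**2 + p.q * p.mu):
        return None
    c = quadratic_coeffs(p)
    disc = c.C2**2 - 4.0 * c.C1 * c.C3
    # C3 < 0 under the existence condition, so disc > C2^2 >= 0
    assert disc > 0.0, "discriminant must be positive when C3 < 0"
    s = math.sqrt(disc)
    if c.C2 <= 0.0:
        return (-c.C2 + s) / (2.0 * c.C1)
    return -2.0 * c.C3 / (c.C2 + s)


def equilibria_S2(p: ModelParams) -> list[Equilibrium]:
    """Equilibria of the controlled subsystem.

    The rumor-free state (always virtual for Ith > 0) is always returned; the
    unique positive equilibrium exists iff ``Lambda*beta > mu^2 + q*mu``.
    """
    out = [_make(State(p.Lambda / p.mu, 0.0, 0.0), "S2", "rumor_free", p)]
    R = positive_root_S2(p)
    if R is not None:
        I = p.mu * R / (p.alpha * R + p.q)
        S = (p.alpha * R + p.mu + p.q) / p.beta
        out.append(_make(State(S, I, R), "S2", "positive", p))
    return out


def boundary_equilibria(p: ModelParams, tol: float = 1e-9) -> list[Equilibrium]:
    """Equilibria sitting exactly on the switching plane I = Ith.

    These require knife-edge parameter coincidences (measure zero), so the
    defining equalities are tested within ``tol``.  Three candidates exist:
    the recovery-free boundary state of the free field, the interior boundary
    state of the free field (Ith = mu/alpha), and the boundary state of the
    controlled field.
    """
    if not (tol > 0.0):
        raise ValueError("tol must be positive")
    out: list[Equilibrium] = []
    S_in = p.Lambda / (p.beta * p.Ith + p.mu)

    # control-off (epsilon = 0), R = 0 branch: needs S = mu/beta = Lambda/(beta*Ith+mu)
    if abs(S_in - p.mu / p.beta) < tol:
        out.append(
            Equilibrium(State(p.mu / p.beta, p.Ith, 0.0), "S1", "boundary_no_recovery", "boundary")
        )

    # control-off interior branch: needs Ith = mu/alpha
    if abs(p.mu / p.alpha - p.Ith) < tol:
        R = (p.beta * p.Lambda - p.mu * (p.beta * p.Ith + p.mu)) / (
            p.alpha * (p.beta * p.Ith + p.mu)
        )
        if R > 0.0:
            out.append(Equilibrium(State(S_in, p.Ith, R), "S1", "positive", "boundary"))

    # control-on (epsilon = 1) branch: the two closed forms for R must agree
    if p.mu > p.alpha * p.Ith and p.beta * p.Lambda > (p.mu + p.q) * (p.beta * p.Ith + p.mu):
        R_from_S = (p.beta * p.Lambda - (p.mu + p.q) * (p.beta * p.Ith + p.mu)) / (
            p.alpha * (p.beta * p.Ith + p.mu)
        )
        R_from_I = p.q * p.Ith / (p.mu - p.alpha * p.Ith)
        if abs(R_from_S - R_from_I) < tol:
            out.append(Equilibrium(State(S_in, p.Ith, R_from_I), "S2", "positive", "boundary"))
    return out


@dataclass(frozen=True)
class TangentLine:
    """Line a*S + b*R = c in the switching plane I = Ith where a field is tangent."""

    a: float
    b: float
    c: float
    regime: str  # "free" | "controlled"


def tangent_lines(p: ModelParams) -> tuple[TangentLine, TangentLine]:
    """Tangency loci of the two fields in the plane I = Ith.

    The free field is tangent on ``beta*S - alpha*R = mu`` and the controlled
    field on ``beta*S - alpha*R = mu + q``; the lines are parallel (same
    normal ``(beta, -alpha)``) and bound the sliding band between them.
    """
    return (
        TangentLine(p.beta, -p.alpha, p.mu, "free"),
        TangentLine(p.beta, -p.alpha, p.mu + p.q, "controlled"),
    )
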