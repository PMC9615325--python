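"""Delay-dependent linear stability and Hopf crossings at the positive equilibria.

Linearizing either smooth subsystem at its positive equilibrium gives a
transcendental characteristic equation

    lambda^3 + a1*lambda^2 + a2*lambda + a3
        + (a4*lambda^2 + a5*lambda + a6) * exp(-lambda*tau) = 0.

At tau = 0 the Routh-Hurwitz conditions on the reduced cubic decide stability.
For tau > 0, purely imaginary roots lambda = i*omega require omega^2 = v to be
a positive root of the crossing cubic

    h(v) = v^3 + B1*v^2 + B2*v + B3,
    B1 = a1^2 - 2*a2 - a4^2,
    B2 = a2^2 - 2*a1*a3 + 2*a4*a6 - a5^2,
    B3 = a3^2 - a6^2.

Each crossing frequency omega yields an arithmetic sequence of critical delays
tau_j = (theta + 2*pi*j)/omega, where theta in [0, 2*pi) is the principal angle
solving the simultaneous sine/cosine system, i.e. exp(-i*omega*tau) =
-P(i*omega)/Q(i*omega) with P the cubic and Q the delayed quadratic part.  The
sign of h'(omega^2) gives the crossing direction: +1 means a conjugate root
pair enters the right half plane as tau increases through each tau_j.

Counting entries (+1) and exits (-1) over the sorted critical delays assembles
the stability intervals in tau, reproducing the stability-switching pattern in
which the equilibrium alternates between stable and unstable windows before
becoming permanently unstable.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field

import numpy as np

from .core_model import ModelParams
from .equilibria import Equilibrium

__all__ = [
    "CharCoeffs",
    "CrossingCubic",
    "Crossing",
    "HopfResult",
    "StabilityIntervals",
    "DegenerateCrossingError",
    "char_coeffs",
    "char_residual",
    "tau0_stable",
    "crossing_cubic",
    "hopf_frequencies",
    "critical_delays",
    "crossing_direction",
    "hopf_result",
    "stability_intervals",
]


class DegenerateCrossingError(ValueError):
    """Raised at a non-transversal or coincident imaginary-axis crossing."""


@dataclass(frozen=True)
class CharCoeffs:
    """Coefficients of lambda^3+a1 l^2+a2 l+a3 + (a4 l^2+a5 l+a6) e^{-l tau}."""

    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    a6: float
    subsystem: str = "S1"
    convention: str = "derived"

    def P(self, lam: complex) -> complex:
        """Non-delayed cubic part evaluated at lambda."""
        return lam**3 + self.a1 * lam**2 + self.a2 * lam + self.a3

    def Q(self, lam: complex) -> complex:
        """Delayed quadratic part evaluated at lambda."""
        return self.a4 * lam**2 + self.a5 * lam + self.a6


@dataclass(frozen=True)
class CrossingCubic:
    """h(v) = v^3 + B1 v^2 + B2 v + B3 with v = omega^2, and Delta = 4B1^2-12B2."""

    B1: float
    B2: float
    B3: float

    @property
    def Delta(self) -> float:
        return 4.0 * self.B1**2 - 12.0 * self.B2

    def h(self, v: float) -> float:
        return v**3 + self.B1 * v**2 + self.B2 * v + self.B3

    def hprime(self, v: float) -> float:
        return 3.0 * v**2 + 2.0 * self.B1 * v + self.B2


def char_coeffs(eq: Equilibrium, p: ModelParams, convention: str = "derived") -> CharCoeffs:
    """Characteristic coefficients at a positive equilibrium of S1 or S2.

    For the free subsystem both conventions coincide.  For the controlled
    subsystem the constant term of the delayed part differs:
    ``convention="derived"`` uses the Jacobian-consistent
    ``a6 = alpha*I*((alpha*R+q)*(beta*I+mu) - beta^2*S*I)`` (validated by the
    characteristic-determinant residual), while ``convention="printed"`` drops
    the leading ``alpha*I`` factor, matching a commonly quoted closed form.
    """
    if convention not in ("derived", "printed"):
        raise ValueError(f"unknown convention {convention!r}")
    if eq.label != "positive" or eq.subsystem not in ("S1", "S2"):
        raise ValueError("characteristic coefficients are defined at positive S1/S2 equilibria")
    S, I, R = eq.state
    if min(S, I, R) <= 0.0:
        raise ValueError("equilibrium must have strictly positive components")
    a, b, m = p.alpha, p.beta, p.mu
    a1 = 2 * m + b * I
    a2 = m * (b * I + m) + b**2 * S * I
    a3 = b**2 * S * I * m
    a4 = -a * I
    if eq.subsystem == "S1":
        a5 = a**2 * R * I - a * I * (b * I + m)
        a6 = (b * I + m) * a**2 * R * I - b**2 * a * S * I**2
    else:
        a5 = a * I * (-b * I + a * R - m + p.q)
        core = (a * R + p.q) * (b * I + m) - b**2 * S * I
        a6 = a * I * core if convention == "derived" else core
    return CharCoeffs(a1, a2, a3, a4, a5, a6, eq.subsystem, convention)


def char_residual(c: CharCoeffs, omega: float, tau: float) -> float:
    """|P(i omega) + Q(i omega) e^{-i omega tau}| — zero at a true crossing."""
    lam = 1j * omega
    return abs(c.P(lam) + c.Q(lam) * cmath.exp(-lam * tau))


def tau0_stable(c: CharCoeffs) -> bool:
    """Routh-Hurwitz test of the tau = 0 cubic l^3+(a1+a4)l^2+(a2+a5)l+(a3+a6)."""
    p1 = c.a1 + c.a4
    p2 = c.a2 + c.a5
    p3 = c.a3 + c.a6
    return p1 > 0.0 and p3 > 0.0 and p1 * p2 - p3 > 0.0


def crossing_cubic(c: CharCoeffs) -> CrossingCubic:
    B1 = c.a1**2 - 2.0 * c.a2 - c.a4**2
    B2 = c.a2**2 - 2.0 * c.a1 * c.a3 + 2.0 * c.a4 * c.a6 - c.a5**2
    B3 = c.a3**2 - c.a6**2
    return CrossingCubic(B1, B2, B3)


def hopf_frequencies(cc: CrossingCubic, tol: float = 1e-9) -> list[float]:
    """Positive crossing frequencies sqrt(v) over real roots v > tol of h, descending."""
    roots = np.roots([1.0, cc.B1, cc.B2, cc.B3])
    vs = sorted(
        (float(r.real) for r in roots if abs(r.imag) <= tol and r.real > tol),
        reverse=True,
    )
    return [math.sqrt(v) for v in vs]


def critical_delays(c: CharCoeffs, omega: float, jmax: int) -> list[float]:
    """Critical delays tau_0..tau_jmax for one crossing frequency.

    The principal angle theta in [0, 2*pi) is obtained from the complex ratio
    ``e^{-i omega tau} = -P(i omega)/Q(i omega)``, which solves the sine and
    cosine equations of the imaginary-axis system simultaneously and therefore
    fixes the quadrant unambiguously.  Consecutive delays differ by exactly
    2*pi/omega.
    """
    if jmax < 0:
        raise ValueError("jmax must be nonnegative")
    cc = crossing_cubic(c)
    if abs(cc.h(omega**2)) > 1e-6:
        raise ValueError(f"omega={omega} is not a crossing frequency (|h(omega^2)|>1e-6)")
    lam = 1j * omega
    z = -c.P(lam) / c.Q(lam)
    theta = (-cmath.phase(z)) % (2.0 * math.pi)
    if theta <= 0.0:  # keep all critical delays strictly positive
        theta += 2.0 * math.pi
    return [(theta + 2.0 * math.pi * j) / omega for j in range(jmax + 1)]


def crossing_direction(cc: CrossingCubic, omega: float) -> int:
    """Sign of h'(omega^2): +1 if a root pair enters the right half plane."""
    hp = cc.hprime(omega**2)
    if abs(hp) < 1e-10:
        raise DegenerateCrossingError(
            f"non-transversal crossing at omega={omega}: |h'(omega^2)|={abs(hp):.2e}"
        )
    return 1 if hp > 0.0 else -1


@dataclass(frozen=True)
class Crossing:
    """One crossing frequency with its critical-delay sequence and direction."""

    omega: float
    taus: list[float]
    direction: int


@dataclass(frozen=True)
class HopfResult:
    """All imaginary-axis crossings of one characteristic equation."""

    crossings: list[Crossing]

    @property
    def tau_star(self) -> float | None:
        """First Hopf delay: the smallest tau_0 over all crossings."""
        if not self.crossings:
            return None
        return min(cr.taus[0] for cr in self.crossings)


def hopf_result(c: CharCoeffs, jmax: int = 4) -> HopfResult:
    cc = crossing_cubic(c)
    crossings = [
        Crossing(w, critical_delays(c, w, jmax), crossing_direction(cc, w))
        for w in hopf_frequencies(cc)
    ]
    return HopfResult(crossings)


@dataclass(frozen=True)
class StabilityIntervals:
    """Critical delays on [0, tau_max] and RHP root-pair counts between them.

    ``breakpoints`` are the sorted critical delays; ``rhp_pairs[k]`` is the
    number of right-half-plane root pairs on the open interval between
    breakpoint k-1 and k (with k = 0 the interval starting at tau = 0).  An
    interval is stable iff its count is zero.
    """

    tau_max: float
    breakpoints: list[float]
    rhp_pairs: list[int]
    directions: list[int] = field(default_factory=list)

    def stable_intervals(self) -> list[tuple[float, float]]:
        edges = [0.0] + list(self.breakpoints) + [self.tau_max]
        return [
            (edges[k], edges[k + 1]) for k, n in enumerate(self.rhp_pairs) if n == 0
        ]

    def is_stable(self, tau: float) -> bool:
        k = sum(1 for b in self.breakpoints if b < tau)
        return self.rhp_pairs[k] == 0


def _initial_pair_count(c: CharCoeffs) -> int:
    if tau0_stable(c):
        return 0
    roots = np.roots([1.0, c.a1 + c.a4, c.a2 + c.a5, c.a3 + c.a6])
    n = int(sum(1 for r in roots if r.real > 0.0))
    # a lone real RHP root never exits through +/- i*omega; count it as one pair
    return (n + 1) // 2


def stability_intervals(c: CharCoeffs, tau_max: float, jmax: int | None = None) -> StabilityIntervals:
    """Merge all critical-delay sequences on [0, tau_max] into stability windows.

    ``jmax`` caps the number of delays taken per crossing; by default every
    delay up to ``tau_max`` is enumerated.  Breakpoints from different
    frequencies closer than 1e-9 are rejected as degenerate.
    """
    if not (tau_max > 0.0):
        raise ValueError("tau_max must be positive")
    cc = crossing_cubic(c)
    events: list[tuple[float, int]] = []
    for w in hopf_frequencies(cc):
        direction = crossing_direction(cc, w)
        period = 2.0 * math.pi / w
        tau0 = critical_delays(c, w, 0)[0]
        if jmax is None:
            n_here = max(0, math.floor((tau_max - tau0) / period) + 1)
        else:
            n_here = jmax + 1
        events.extend((tau0 + j * period, direction) for j in range(n_here))
    events = [e for e in events if e[0] <= tau_max]
    events.sort(key=lambda e: e[0])
    for (t1, _), (t2, _) in zip(events, events[1:]):
        if t2 - t1 < 1e-9:
            raise DegenerateCrossingError(f"coincident critical delays at tau={t1}")
    count = _initial_pair_count(c)
    counts = [count]
    for _, direction in events:
        count += direction
        if count < 0:
            raise AssertionError("right-half-plane pair count went negative")
        counts.append(count)
    return StabilityIntervals(
        tau_max=tau_max,
        breakpoints=[t for t, _ in events],
        rhp_pairs=counts,
        directions=[d for _, d in events],
    )
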