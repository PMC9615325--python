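"""Delayed SIR-type rumor spreading model with a discontinuous threshold control.

The population is split into rumor-susceptible S, rumor-propagating I and
rumor-recovered R individuals.  Spreaders recover on contact with recovered
individuals who debunk the rumor, with a delay ``tau`` between contact and
recovery taking effect, so the recovery terms read ``±alpha*I*R(t-tau)``.
A government control removes spreaders at rate ``q*I``, but only once the
spreader level exceeds a threshold ``Ith``:

    T(I) = 0        for I < Ith,
    T(I) = q*I      for I > Ith.

The discontinuity at ``I = Ith`` makes this a Filippov system with two smooth
vector fields: the free field (control off, region G1: I < Ith) and the
controlled field (control on, region G2: I > Ith).  On the switching plane
``H = I - Ith = 0`` the right-hand side is the Filippov convex hull of the two
fields; the set-valued control there is the interval ``[0, q*I]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple

__all__ = [
    "ModelParams",
    "State",
    "SaturatedControlParams",
    "drift",
    "control_flow",
    "switching_H",
    "load_params",
]


class State(NamedTuple):
    """Population state (S, I, R); all components nonnegative and finite."""

    S: float
    I: float
    R: float


@dataclass(frozen=True)
class ModelParams:
    """Rate constants, delay and control threshold of the rumor model.

    Parameters
    ----------
    Lambda : constant immigration rate of susceptibles (individuals/time, >0).
    beta : susceptible-spreader contact rate (>0).
    mu : removal (emigration) rate of every class (>0).
    alpha : spreader-recovered contact rate (>0); contact with a recovered
        individual who debunks the rumor converts a spreader.
    q : control strength (>0); the controlled removal term is q*I.
    tau : delay between spreader-recovered contact and recovery (time, >=0).
    Ith : spreader threshold above which the control is applied (>0).
    """

    Lambda: float
    beta: float
    mu: float
    alpha: float
    q: float
    tau: float = 0.0
    Ith: float = 1.0

    def __post_init__(self) -> None:
        for name in ("Lambda", "beta", "mu", "alpha", "q", "Ith"):
            v = getattr(self, name)
            if not (v > 0.0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not (self.tau >= 0.0):
            raise ValueError(f"tau must be nonnegative, got {self.tau!r}")


@dataclass(frozen=True)
class SaturatedControlParams:
    """Parameters of the saturated control T(I) = beta1*I / (1 + alpha1*I)."""

    beta1: float
    alpha1: float

    def __post_init__(self) -> None:
        if not (self.beta1 > 0.0 and self.alpha1 > 0.0):
            raise ValueError("beta1 and alpha1 must be strictly positive")


def _check_state(state: State) -> None:
    if not all(x >= 0.0 for x in state):
        raise ValueError(f"state components must be nonnegative, got {tuple(state)}")


def drift(
    state: State,
    delayed_R: float,
    regime: str,
    p: ModelParams,
) -> tuple[float, float, float]:
    """Right-hand side of one smooth regime.

    ``delayed_R`` is the value of R at time ``t - tau``; it enters only the
    ``±alpha*I*R(t-tau)`` recovery terms, so passing ``delayed_R = R`` yields
    the equilibrium residual.  ``regime`` is ``"free"`` (control off, field of
    region G1) or ``"controlled"`` (T = q*I, field of region G2).

    The control term cancels between dI and dR, so in both regimes
    ``dS + dI + dR == Lambda - mu*(S + I + R)`` exactly.
    """
    state = State(*state)
    _check_state(state)
    if not (delayed_R >= 0.0):
        raise ValueError(f"delayed_R must be nonnegative, got {delayed_R!r}")
    if regime == "free":
        T = 0.0
    elif regime == "controlled":
        T = p.q * state.I
    else:
        raise ValueError(f"regime must be 'free' or 'controlled', got {regime!r}")
    S, I, R = state
    recover = p.alpha * I * delayed_R
    dS = p.Lambda - p.beta * S * I - p.mu * S
    dI = p.beta * S * I - recover - p.mu * I - T
    dR = recover - p.mu * R + T
    return dS, dI, dR


def control_flow(I: float, p: ModelParams) -> tuple[float, float]:
    """Filippov set of admissible control values at spreader level ``I``.

    Returns the (min, max) of the set: ``(0, 0)`` below the threshold,
    ``(qI, qI)`` above it, and the full convexification ``(0, qI)`` exactly at
    ``I == Ith``, where the single-valued law is undefined.
    """
    if not (I >= 0.0):
        raise ValueError(f"I must be nonnegative, got {I!r}")
    if I < p.Ith:
        return (0.0, 0.0)
    if I > p.Ith:
        return (p.q * I, p.q * I)
    return (0.0, p.q * I)


def switching_H(state: State, p: ModelParams) -> float:
    """Switching function H = I - Ith; its gradient in (S, I, R) is (0, 1, 0)."""
    state = State(*state)
    _check_state(state)
    return state.I - p.Ith


_PARAM_KEYS = ("Lambda", "beta", "mu", "alpha", "q", "tau", "Ith")


def load_params(source: str | Path | Mapping) -> ModelParams:
    """Build ModelParams from a flat mapping or a JSON/YAML file of one.

    The mapping uses the keys Lambda, beta, mu, alpha, q, tau, Ith; tau and
    Ith are optional (defaults 0 and 1).  Extra keys are ignored so that a
    combined simulation config can be passed through.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            mapping = yaml.safe_load(text)
        else:
            mapping = json.loads(text)
    else:
        mapping = dict(source)
    if not isinstance(mapping, Mapping):
        raise ValueError("parameter config must be a flat mapping")
    missing = [k for k in ("Lambda", "beta", "mu", "alpha", "q") if k not in mapping]
    if missing:
        raise KeyError(f"missing required parameter keys: {missing}")
    kwargs = {k: float(mapping[k]) for k in _PARAM_KEYS if k in mapping}
    return ModelParams(**kwargs)
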