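"""Discrete-time update maps and orbit simulation.

Three schemes are provided:

* ``nsfd`` — the Mickens nonstandard scheme.  Loss terms are placed in the
  denominators, so both components stay strictly positive for positive input
  and the equilibria of the ODE are preserved exactly for every step size.
* ``euler`` — explicit Euler, shipped as the comparison scheme; it can and
  does produce negative populations.
* ``controlled`` — the hybrid bifurcation-control map: a convex combination
  of the NSFD update and the identity with gain sin(b), b in (0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import Parameters, State, ode_rhs

__all__ = [
    "ControlGain",
    "Orbit",
    "BoundednessReport",
    "nsfd_step",
    "euler_step",
    "controlled_step",
    "step_function",
    "simulate_orbit",
    "boundedness_certificate",
]

DIVERGENCE_GUARD = 1e12

SCHEMES = ("nsfd", "euler", "controlled")


def validate_h(h: float, positive: bool = False) -> float:
    if not (0.0 <= h < 1.0) or not math.isfinite(h):
        raise ValueError(f"step size h must lie in [0, 1), got {h!r}")
    if positive and h == 0.0:
        raise ValueError("step size h must be positive for dynamics")
    return float(h)


@dataclass(frozen=True)
class ControlGain:
    """Hybrid-control parameter b in (0, 1]; the applied gain is sin(b)."""

    b: float

    def __post_init__(self) -> None:
        if not (0.0 < self.b <= 1.0):
            raise ValueError(f"control parameter b must lie in (0, 1], got {self.b!r}")

    @property
    def gain(self) -> float:
        return math.sin(self.b)


@dataclass
class Orbit:
    """Post-transient trajectory of one of the schemes."""

    states: np.ndarray  # (n, 2)
    h: float
    scheme: str
    transient_discarded: int
    diverged: bool = False
    gain: ControlGain | None = None
    initial: State | None = None

    @property
    def terminal(self) -> State:
        return State(*self.states[-1])


def nsfd_step(state, params: Parameters, h: float) -> State:
    x, y = state
    p = params
    xn = (x + h * (p.sigma + p.rho * x * y / (p.eta + y))) / (1.0 + h * (p.delta + p.mu * y))
    yn = y * (1.0 + h * p.alpha) / (1.0 + h * (x + p.alpha * p.beta * y))
    return State(xn, yn)


def euler_step(state, params: Parameters, h: float) -> State:
    x, y = state
    dx, dy = ode_rhs(state, params)
    return State(x + h * dx, y + h * dy)


def controlled_step(state, params: Parameters, h: float, gain: ControlGain) -> State:
    g = gain.gain
    xn, yn = nsfd_step(state, params, h)
    return State(g * xn + (1.0 - g) * state[0], g * yn + (1.0 - g) * state[1])


def step_function(scheme: str, params: Parameters, h: float,
                  gain: ControlGain | None = None):
    """Bind a scheme to ``state -> next state``."""
    if scheme == "nsfd":
        return lambda s: nsfd_step(s, params, h)
    if scheme == "euler":
        return lambda s: euler_step(s, params, h)
    if scheme == "controlled":
        if gain is None:
            raise ValueError("controlled scheme requires a ControlGain")
        return lambda s: controlled_step(s, params, h, gain)
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def simulate_orbit(scheme: str, initial, params: Parameters, h: float,
                   n_steps: int, n_transient: int = 0,
                   gain: ControlGain | None = None) -> Orbit:
    """Iterate the chosen map, recording states after the transient.

    If any component exceeds the divergence guard (1e12) the orbit is
    returned partially filled with ``diverged=True`` rather than raising.
    """
    if not (n_steps > n_transient >= 0):
        raise ValueError("need n_steps > n_transient >= 0")
    validate_h(h)
    step = step_function(scheme, params, h, gain)
    s = State(*initial)
    recorded: list[State] = []
    diverged = False
    for i in range(n_steps):
        s = step(s)
        if not (abs(s.x) < DIVERGENCE_GUARD and abs(s.y) < DIVERGENCE_GUARD):
            diverged = True
            recorded.append(s)
            break
        if i >= n_transient:
            recorded.append(s)
    return Orbit(
        states=np.asarray(recorded, dtype=float).reshape(-1, 2),
        h=h,
        scheme=scheme,
        transient_discarded=n_transient,
        diverged=diverged,
        gain=gain,
        initial=State(*initial),
    )


@dataclass(frozen=True)
class BoundednessReport:
    """Invariant-box certificate for the NSFD scheme.

    The tumor component always satisfies lim sup y_n <= 1/beta.  When
    rho < delta*(1 + beta*eta) the effector component admits the bound
    sigma*(1 + beta*eta) / (delta*(1 + beta*eta) - rho) and the box is
    forward-invariant; otherwise the x-bound is inapplicable (flag, not an
    error).
    """

    y_bound: float
    x_bound: float | None
    x_bound_applicable: bool
    orbit_checked: bool = False
    orbit_within_bounds: bool | None = None
    violations: int = 0


def boundedness_certificate(params: Parameters, orbit: Orbit | None = None) -> BoundednessReport:
    p = params
    y_bound = 1.0 / p.beta
    denom = p.delta * (1.0 + p.beta * p.eta) - p.rho
    applicable = denom > 0.0
    x_bound = p.sigma * (1.0 + p.beta * p.eta) / denom if applicable else None
    checked = False
    within: bool | None = None
    violations = 0
    if orbit is not None:
        checked = True
        tol = 1e-12
        ybad = int(np.sum(orbit.states[:, 1] > y_bound * (1.0 + tol)))
        xbad = 0
        if applicable:
            xbad = int(np.sum(orbit.states[:, 0] > x_bound * (1.0 + tol)))
        violations = ybad + xbad
        within = violations == 0
    return BoundednessReport(y_bound, x_bound, applicable, checked, within, violations)
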