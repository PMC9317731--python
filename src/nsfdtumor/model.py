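"""Nondimensional effector-cell / tumor-cell interaction model.

The planar ODE

    dx/dt = sigma + rho*x*y/(eta + y) - mu*x*y - delta*x
    dy/dt = alpha*y*(1 - beta*y) - x*y

describes the density ``x`` of cytotoxic effector cells (CTL/NK) attacking an
immunogenic tumor of density ``y``; both are measured in units of 10^6 cells.
Effector cells flow in at constant rate ``sigma``, are recruited by tumor
contact with Michaelis-Menten saturation (``rho``, half-saturation ``eta``),
are inactivated by tumor cells at rate ``mu`` and die at rate ``delta``.  The
tumor grows logistically (rate ``alpha``, inverse carrying capacity ``beta``)
and is killed on contact with effector cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import NamedTuple

__all__ = [
    "Parameters",
    "DimensionalParameters",
    "State",
    "make_params",
    "preset_kuznetsov",
    "ode_rhs",
    "nondimensionalize",
    "dimensionalize",
]


class State(NamedTuple):
    """Effector-cell and tumor-cell densities (units of 10^6 cells)."""

    x: float
    y: float


@dataclass(frozen=True)
class Parameters:
    """The seven positive nondimensional rates of the model.

    Attributes
    ----------
    sigma : effector-cell influx rate.
    rho : maximal immune-recruitment rate.
    eta : recruitment half-saturation (tumor units).
    mu : effector inactivation rate by tumor contact.
    delta : effector natural death rate.
    alpha : tumor intrinsic growth rate.
    beta : inverse tumor carrying capacity (the tumor saturates at 1/beta).
    """

    sigma: float
    rho: float
    eta: float
    mu: float
    delta: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} must be finite, got {v!r}")
            if v <= 0:
                raise ValueError(f"parameter {f.name!r} must be strictly positive, got {v!r}")
            object.__setattr__(self, f.name, float(v))

    def astuple(self) -> tuple[float, ...]:
        return (self.sigma, self.rho, self.eta, self.mu, self.delta, self.alpha, self.beta)

    def replace(self, **kwargs: float) -> "Parameters":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kwargs)
        return Parameters(**d)


@dataclass(frozen=True)
class DimensionalParameters:
    """Dimensional rates of the pre-scaling model plus the scaling populations.

    ``s, p, g, m, d`` are the dimensional analogues of sigma, rho, eta, mu,
    delta; ``a, b`` the dimensional tumor growth rate and inverse carrying
    capacity; ``n`` the tumor-deactivation rate that sets the time scale; and
    ``E0, T0`` the effector/tumor scaling populations (10^6 cells each in the
    standard scaling).
    """

    s: float
    p: float
    g: float
    m: float
    d: float
    a: float
    b: float
    n: float
    E0: float = 1e6
    T0: float = 1e6

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v) or v <= 0:
                raise ValueError(f"dimensional parameter {f.name!r} must be finite and positive")


def make_params(sigma: float, rho: float, eta: float, mu: float,
                delta: float, alpha: float, beta: float) -> Parameters:
    """Validate and build a :class:`Parameters` set."""
    return Parameters(sigma, rho, eta, mu, delta, alpha, beta)


#: Kuznetsov-type parameter estimates shared by all presets.
_PRESET_COMMON = dict(eta=20.19, mu=0.00311, delta=0.3743, alpha=1.636, beta=0.002)

_RHO_VARIANTS = {"continuous": 11.131, "discrete": 1.131}


def preset_kuznetsov(rho_variant: str = "discrete", sigma: float = 0.1181) -> Parameters:
    """Standard parameter preset for the tumor-immune model.

    ``rho_variant='continuous'`` uses the recruitment rate rho = 11.131
    employed for the ODE runs; ``'discrete'`` uses rho = 1.131 as in the
    discrete-map experiments.  ``sigma`` defaults to the value used in the
    numerical experiments and may be overridden.
    """
    try:
        rho = _RHO_VARIANTS[rho_variant]
    except KeyError:
        raise ValueError(
            f"unknown rho_variant {rho_variant!r}; expected one of {sorted(_RHO_VARIANTS)}"
        ) from None
    return Parameters(sigma=sigma, rho=rho, **_PRESET_COMMON)


def ode_rhs(state: State | tuple[float, float], params: Parameters) -> State:
    """Right-hand side of the nondimensional ODE at ``state``."""
    x, y = state
    p = params
    dx = p.sigma + p.rho * x * y / (p.eta + y) - p.mu * x * y - p.delta * x
    dy = p.alpha * y * (1.0 - p.beta * y) - x * y
    return State(dx, dy)


def nondimensionalize(dim: DimensionalParameters) -> tuple[Parameters, float]:
    """Convert dimensional rates to the nondimensional set.

    Time is rescaled by the tumor-deactivation rate, tau = n*T0*t, and the
    populations by E0 and T0.  Returns ``(params, time_scale)`` where
    ``time_scale = n*T0`` is the factor converting dimensional time to tau.
    """
    n, E0, T0 = dim.n, dim.E0, dim.T0
    params = Parameters(
        sigma=dim.s / (n * E0 * T0),
        rho=dim.p / (n * T0),
        eta=dim.g / T0,
        mu=dim.m / n,
        delta=dim.d / (n * T0),
        alpha=dim.a / (n * T0),
        beta=dim.b * T0,
    )
    return params, n * T0


def dimensionalize(params: Parameters, n: float, E0: float = 1e6,
                   T0: float = 1e6) -> DimensionalParameters:
    """Exact inverse of :func:`nondimensionalize` for given scalings."""
    return DimensionalParameters(
        s=params.sigma * n * E0 * T0,
        p=params.rho * n * T0,
        g=params.eta * T0,
        m=params.mu * n,
        d=params.delta * n * T0,
        a=params.alpha * n * T0,
        b=params.beta / T0,
        n=n,
        E0=E0,
        T0=T0,
    )
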