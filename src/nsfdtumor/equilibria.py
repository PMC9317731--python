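"""Fixed points shared by the ODE and its NSFD discretization.

The NSFD scheme preserves equilibria exactly: a state is fixed under the map
for one step size h > 0 iff it is an equilibrium of the vector field, so one
solver serves both.  The boundary (tumor-free) point is (sigma/delta, 0).
Interior points satisfy

    x = alpha * (1 - beta * y)            (tumor balance)
    delta*x + mu*x*y = sigma + rho*x*y/(eta+y)    (effector balance)

which after elimination of x and clearing of (eta + y) is a cubic in y.  All
real roots with 0 < y < 1/beta and x > 0 are admissible; each is polished by
a damped Newton iteration on the full nonlinear residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

from ._derivatives import ode_jacobian_exact
from .model import Parameters, State, ode_rhs

__all__ = [
    "FixedPoint",
    "ExistenceDiagnostics",
    "boundary_fixed_point",
    "interior_fixed_points",
    "existence_conditions",
]

_POLISH_TOL = 1e-12
_MAX_NEWTON = 50


@dataclass(frozen=True)
class FixedPoint:
    """An equilibrium with its kind and the polished residual."""

    location: State
    kind: str  # "boundary" | "interior"
    residual: float
    admissible: bool
    params: Parameters

    def __iter__(self):
        return iter(self.location)


@dataclass(frozen=True)
class ExistenceDiagnostics:
    """The three sign conditions quoted for uniqueness of an interior point.

    Diagnostics only: :func:`interior_fixed_points` is authoritative for
    existence (the conditions are sufficient-style and fail at the standard
    preset even though interior equilibria exist).
    """

    cond_rho_gt_delta: bool
    cond_second: bool
    cond_third: bool

    @property
    def all_satisfied(self) -> bool:
        return self.cond_rho_gt_delta and self.cond_second and self.cond_third


def _residual(x: float, y: float, params: Parameters) -> float:
    dx, dy = ode_rhs((x, y), params)
    return max(abs(dx), abs(dy))


def boundary_fixed_point(params: Parameters) -> FixedPoint:
    """The tumor-free equilibrium (sigma/delta, 0)."""
    x = params.sigma / params.delta
    return FixedPoint(State(x, 0.0), "boundary", _residual(x, 0.0, params), True, params)


def _newton_polish(x: float, y: float, params: Parameters) -> tuple[float, float, float]:
    res = _residual(x, y, params)
    for _ in range(_MAX_NEWTON):
        if res < _POLISH_TOL:
            break
        J = ode_jacobian_exact(x, y, params.astuple())
        f = np.asarray(ode_rhs((x, y), params), dtype=float)
        try:
            step = np.linalg.solve(J, f)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        while lam > 1e-6:
            xn, yn = x - lam * step[0], y - lam * step[1]
            rn = _residual(xn, yn, params)
            if rn < res:
                x, y, res = xn, yn, rn
                break
            lam *= 0.5  # damp on residual increase
        else:
            break
    return x, y, res


def interior_fixed_points(params: Parameters) -> list[FixedPoint]:
    """All admissible interior equilibria, sorted by ascending y.

    Empty list means no interior equilibrium.  More than one admissible root
    is possible (the uniqueness conditions are not always met) and all are
    returned.
    """
    p = params
    # cubic in y: (eta+y)(delta+mu y) x(y) - sigma (eta+y) - rho x(y) y = 0,
    # with x(y) = alpha (1 - beta y); coefficients by polynomial arithmetic
    xpoly = (p.alpha, -p.alpha * p.beta)
    c = npoly.polymul(npoly.polymul((p.eta, 1.0), (p.delta, p.mu)), xpoly)
    c = npoly.polysub(c, (p.sigma * p.eta, p.sigma))
    c = npoly.polysub(c, npoly.polymul((0.0, 1.0), npoly.polymul((p.rho,), xpoly)))
    roots = npoly.polyroots(c)

    out: list[FixedPoint] = []
    ymax = 1.0 / p.beta
    for r in roots:
        if abs(r.imag) > 1e-9 * (1.0 + abs(r.real)):
            continue
        y = float(r.real)
        if not (0.0 < y < ymax):
            continue
        x = p.alpha * (1.0 - p.beta * y)
        if x <= 0.0:
            continue
        x, y, res = _newton_polish(x, y, params)
        if not (0.0 < y < ymax and x > 0.0):
            continue
        if out and abs(y - out[-1].location.y) < 1e-8 * (1.0 + abs(y)):
            continue  # duplicate root after polishing
        out.append(FixedPoint(State(x, y), "interior", res, True, params))
    out.sort(key=lambda fp: fp.location.y)
    return out


def existence_conditions(params: Parameters) -> ExistenceDiagnostics:
    """Evaluate the three quoted sign inequalities (diagnostics only)."""
    p = params
    return ExistenceDiagnostics(
        cond_rho_gt_delta=p.rho > p.delta,
        cond_second=p.sigma + p.alpha * (p.beta * p.eta * p.delta + p.rho)
        < p.eta * p.mu + p.alpha * (1.0 + 2.0 * p.mu),
        cond_third=p.alpha**2 * p.mu * (p.beta * p.eta + 1.0)
        < p.sigma * (p.eta + p.alpha**2 * p.beta),
    )
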