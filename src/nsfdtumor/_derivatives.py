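"""Exact derivatives of the vector field and of the NSFD update map.

The Jacobians and the second/third derivative tensors used by the stability
and normal-form machinery are derived symbolically from the model definitions
once at import time and lambdified to fast numpy callables.  Nothing here is
transcribed from printed closed forms; everything follows mechanically from
the two defining expressions.
"""

from __future__ import annotations

import numpy as np
import sympy as sp

_x, _y, _h = sp.symbols("x y h")
_sigma, _rho, _eta, _mu, _delta, _alpha, _beta = sp.symbols(
    "sigma rho eta mu delta alpha beta"
)
_PARS = (_sigma, _rho, _eta, _mu, _delta, _alpha, _beta)
_V = (_x, _y)

# continuous-time vector field
_F = [
    _sigma + _rho * _x * _y / (_eta + _y) - _mu * _x * _y - _delta * _x,
    _alpha * _y * (1 - _beta * _y) - _x * _y,
]

# NSFD (Mickens) update: stiff loss terms moved into the denominators
_G = [
    (_x + _h * (_sigma + _rho * _x * _y / (_eta + _y))) / (1 + _h * (_delta + _mu * _y)),
    _y * (1 + _h * _alpha) / (1 + _h * (_x + _alpha * _beta * _y)),
]


def _lam(expr_nest, args):
    return sp.lambdify(args, expr_nest, "numpy")


_ode_args = (_x, _y) + _PARS
_map_args = (_x, _y, _h) + _PARS

_ode_jac = _lam([[sp.diff(f, v) for v in _V] for f in _F], _ode_args)
_nsfd_jac = _lam([[sp.diff(g, v) for v in _V] for g in _G], _map_args)
# scalar ("math" module) variants for tight per-step loops
_ode_jac_m = sp.lambdify(_ode_args, [[sp.diff(f, v) for v in _V] for f in _F], "math")
_nsfd_jac_m = sp.lambdify(_map_args, [[sp.diff(g, v) for v in _V] for g in _G], "math")
_nsfd_d2 = _lam(
    [[[sp.diff(g, a, b) for b in _V] for a in _V] for g in _G], _map_args
)
_nsfd_d3 = _lam(
    [[[[sp.diff(g, a, b, c) for c in _V] for b in _V] for a in _V] for g in _G],
    _map_args,
)


def ode_jacobian_exact(x: float, y: float, pars: tuple[float, ...]) -> np.ndarray:
    return np.asarray(_ode_jac(x, y, *pars), dtype=float)


def ode_jacobian_entries(x: float, y: float, pars: tuple[float, ...]):
    """Jacobian of the vector field as a nested list of plain floats."""
    return _ode_jac_m(x, y, *pars)


def nsfd_jacobian_entries(x: float, y: float, h: float, pars: tuple[float, ...]):
    """Jacobian of the NSFD step as a nested list of plain floats."""
    return _nsfd_jac_m(x, y, h, *pars)


def nsfd_jacobian_exact(x: float, y: float, h: float, pars: tuple[float, ...]) -> np.ndarray:
    return np.asarray(_nsfd_jac(x, y, h, *pars), dtype=float)


def nsfd_d2_exact(x: float, y: float, h: float, pars: tuple[float, ...]) -> np.ndarray:
    """Second-derivative tensor D2[i, a, b] = d^2 G_i / dz_a dz_b."""
    return np.asarray(_nsfd_d2(x, y, h, *pars), dtype=float)


def nsfd_d3_exact(x: float, y: float, h: float, pars: tuple[float, ...]) -> np.ndarray:
    """Third-derivative tensor D3[i, a, b, c] = d^3 G_i / dz_a dz_b dz_c."""
    return np.asarray(_nsfd_d3(x, y, h, *pars), dtype=float)


# ---------------------------------------------------------------------------
# small finite-difference helpers (for user-supplied generic planar fields
# and as independent oracles in the test suite)
# ---------------------------------------------------------------------------

def fd_jacobian(func, point, step: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of a planar map/field at ``point``."""
    point = np.asarray(point, dtype=float)
    J = np.empty((2, 2))
    for j in range(2):
        e = np.zeros(2)
        e[j] = step * (1.0 + abs(point[j]))
        fp = np.asarray(func(point + e), dtype=float)
        fm = np.asarray(func(point - e), dtype=float)
        J[:, j] = (fp - fm) / (2 * e[j])
    return J


def fd_partial(func, point, multi_index, step: float = 1e-3):
    """Mixed partial derivative of scalar ``func`` by iterated 4th-order
    central differences; ``multi_index`` is a sequence of axis indices, e.g.
    (0, 0, 1) for d^3/dx^2 dy.  Accurate enough for low-order polynomial-like
    nonlinearities, which is all the normal-form formulas consume."""
    if not multi_index:
        return func(np.asarray(point, dtype=float))
    ax, rest = multi_index[0], multi_index[1:]

    def deriv(pt):
        e = np.zeros(2)
        e[ax] = step
        f1 = fd_partial(func, pt + e, rest, step)
        f2 = fd_partial(func, pt + 2 * e, rest, step)
        f_1 = fd_partial(func, pt - e, rest, step)
        f_2 = fd_partial(func, pt - 2 * e, rest, step)
        return (-f2 + 8 * f1 - 8 * f_1 + f_2) / (12 * step)

    return deriv(np.asarray(point, dtype=float))
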