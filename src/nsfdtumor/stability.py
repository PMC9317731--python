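"""Linear stability: Jacobians, Routh-Hurwitz and Jury classification.

For the planar map with characteristic polynomial C(phi) = phi^2 - T*phi + D
the Jury conditions (assuming C(1) > 0) classify the fixed point:

* sink   iff C(-1) > 0 and D < 1
* source iff C(-1) > 0 and D > 1
* saddle iff C(-1) < 0
* non-hyperbolic complex pair on the unit circle iff T^2 - 4D < 0 and D = 1

The continuous classification uses trace/determinant signs.  Every report is
cross-checked against the eigenvalues directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._derivatives import nsfd_jacobian_exact, ode_jacobian_exact
from .equilibria import FixedPoint
from .maps import ControlGain, validate_h
from .model import Parameters

__all__ = [
    "StabilityReport",
    "ode_jacobian",
    "map_jacobian",
    "classify_continuous",
    "classify_continuous_jacobian",
    "classify_from_jacobian",
    "classify_map_fp",
    "cminus1",
]

_HYP_TOL = 1e-9


@dataclass(frozen=True)
class StabilityReport:
    jacobian: np.ndarray
    trace: float
    det: float
    eigenvalues: tuple[complex, complex]
    char_at_plus1: float
    char_at_minus1: float
    klass: str  # sink | source | saddle | non-hyperbolic
    degenerate: bool = False  # C(1) <= 0 fold-type boundary (maps only)


def ode_jacobian(state, params: Parameters) -> np.ndarray:
    """Exact Jacobian of the vector field at ``state``."""
    x, y = state
    return ode_jacobian_exact(x, y, params.astuple())


def map_jacobian(state, params: Parameters, h: float, scheme: str = "nsfd",
                 gain: ControlGain | None = None) -> np.ndarray:
    """Exact Jacobian of the selected one-step map at ``state``."""
    validate_h(h)
    x, y = state
    if scheme == "nsfd":
        return nsfd_jacobian_exact(x, y, h, params.astuple())
    if scheme == "euler":
        return np.eye(2) + h * ode_jacobian_exact(x, y, params.astuple())
    if scheme == "controlled":
        if gain is None:
            raise ValueError("controlled scheme requires a ControlGain")
        g = gain.gain
        return (1.0 - g) * np.eye(2) + g * nsfd_jacobian_exact(x, y, h, params.astuple())
    raise ValueError(f"unknown scheme {scheme!r}")


def _report(J: np.ndarray, klass: str, degenerate: bool = False) -> StabilityReport:
    T = float(np.trace(J))
    D = float(np.linalg.det(J))
    eig = np.linalg.eigvals(J)
    return StabilityReport(
        jacobian=J,
        trace=T,
        det=D,
        eigenvalues=(complex(eig[0]), complex(eig[1])),
        char_at_plus1=1.0 - T + D,
        char_at_minus1=1.0 + T + D,
        klass=klass,
        degenerate=degenerate,
    )


def classify_continuous(fp: FixedPoint, params: Parameters) -> StabilityReport:
    """Routh-Hurwitz classification of an ODE equilibrium."""
    return classify_continuous_jacobian(ode_jacobian(fp.location, params))


def classify_continuous_jacobian(J: np.ndarray) -> StabilityReport:
    """Routh-Hurwitz classification from a continuous-time Jacobian."""
    T = float(np.trace(J))
    D = float(np.linalg.det(J))
    if abs(D) < _HYP_TOL or (D > 0 and abs(T) < _HYP_TOL):
        klass = "non-hyperbolic"
    elif D < 0:
        klass = "saddle"
    elif T < 0:
        klass = "sink"
    else:
        klass = "source"
    return _report(J, klass)


def classify_from_jacobian(J: np.ndarray) -> StabilityReport:
    """Jury classification of a map fixed point from its Jacobian."""
    T = float(np.trace(J))
    D = float(np.linalg.det(J))
    c1 = 1.0 - T + D
    cm1 = 1.0 + T + D
    if c1 <= _HYP_TOL:
        # Jury table assumes C(1) > 0; C(1) = 0 is a fold-type boundary and
        # C(1) < 0 puts one real eigenvalue beyond +1 — classify by moduli.
        if abs(c1) < _HYP_TOL:
            return _report(J, "non-hyperbolic", degenerate=True)
        mods = sorted(abs(e) for e in np.linalg.eigvals(J))
        if mods[0] < 1.0 - _HYP_TOL:
            klass = "saddle"
        elif mods[0] > 1.0 + _HYP_TOL:
            klass = "source"
        else:
            klass = "non-hyperbolic"
        return _report(J, klass, degenerate=True)
    if T * T - 4.0 * D < 0.0 and abs(D - 1.0) < _HYP_TOL:
        klass = "non-hyperbolic"
    elif abs(cm1) < _HYP_TOL or abs(D - 1.0) < _HYP_TOL:
        klass = "non-hyperbolic"
    elif cm1 < 0.0:
        klass = "saddle"
    elif D < 1.0:
        klass = "sink"
    else:
        klass = "source"
    rep = _report(J, klass)
    # cross-check against eigenvalue moduli
    mods = sorted(abs(e) for e in rep.eigenvalues)
    if klass == "sink":
        assert mods[1] < 1.0 + _HYP_TOL
    elif klass == "source":
        assert mods[0] > 1.0 - _HYP_TOL
    elif klass == "saddle":
        assert mods[0] < 1.0 + _HYP_TOL < mods[1] + 2 * _HYP_TOL
    return rep


def classify_map_fp(fp: FixedPoint, params: Parameters, h: float,
                    scheme: str = "nsfd",
                    gain: ControlGain | None = None) -> StabilityReport:
    """Jury classification of a fixed point of the selected map."""
    J = map_jacobian(fp.location, params, h, scheme, gain)
    return classify_from_jacobian(J)


def cminus1(fp: FixedPoint, params: Parameters, h: float) -> float:
    """C(-1) = 1 + T + D for the NSFD Jacobian at ``fp``.

    Positivity of this quantity for all admissible parameters rules out a
    period-doubling (flip) bifurcation of the NSFD map.
    """
    J = map_jacobian(fp.location, params, h, "nsfd")
    return 1.0 + float(np.trace(J)) + float(np.linalg.det(J))
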