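"""Hopf and Neimark-Sacker analysis, plus the hybrid-control interval.

Continuous side
---------------
:func:`hopf_scan` tracks the interior equilibrium while the influx sigma
varies and root-finds a crossing of the leading eigenvalue real part.  For
the tumor model the interior trace identity T = -sigma/x* - alpha*beta*y* < 0
rules such a crossing out, so the scan reports ``none-found`` there; the
machinery is exercised on synthetic registered planar fields with planted
crossings.  :func:`hopf_l1` evaluates the standard planar first Lyapunov
coefficient after transforming the field to rotation normal form.

Discrete side
-------------
The NSFD map loses stability of the interior fixed point when the complex
Jacobian eigenvalue pair crosses the unit circle, i.e. when det J(h) = 1
with T^2 < 4D.  :func:`ns_critical_h` locates that step size,
:func:`ns_nonresonance` excludes 1st..4th roots of unity, and
:func:`ns_coefficient` computes the normal-form coefficient

    coeff = -Re[(1-2*m)*mbar^2/(1-m) * xi20*xi11] - |xi11|^2/2 - |xi02|^2
            + Re(mbar*xi21)

from the map's exact second/third derivative tensors, where m = lam + i*om
is the critical multiplier.  coeff < 0 means supercritical: an attracting
invariant closed curve exists for h just above the critical value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import brentq

from ._derivatives import (
    fd_jacobian,
    fd_partial,
    nsfd_d2_exact,
    nsfd_d3_exact,
)
from .equilibria import FixedPoint, interior_fixed_points
from .maps import ControlGain
from .model import Parameters, State
from .stability import map_jacobian, ode_jacobian

__all__ = [
    "HopfReport",
    "NSReport",
    "ControlReport",
    "PlanarField",
    "SyntheticHopfField",
    "RadialNormalFormField",
    "hopf_scan",
    "hopf_l1",
    "ns_critical_h",
    "ns_nonresonance",
    "ns_coefficient",
    "ns_normal_form_coefficient",
    "resonance_flags_from_trace",
    "control_stability_interval",
    "delayed_logistic_ns_coefficient",
]


# ---------------------------------------------------------------------------
# Hopf analysis (continuous system)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HopfReport:
    sigma0: float | None
    omega0: float | None
    dre_dsigma: float | None
    L1: float | None
    direction: str  # supercritical | subcritical | degenerate | none-found
    scanned_range: tuple[float, float]
    valid_range: tuple[float, float] | None = None


class PlanarField:
    """A planar vector field with one scalar bifurcation parameter.

    Subclasses implement ``rhs(state, a)``, ``jacobian(state, a)`` and
    ``equilibrium(a)``.  ``jacobian`` defaults to central differences.
    """

    def rhs(self, state, a):  # pragma: no cover - interface
        raise NotImplementedError

    def jacobian(self, state, a):
        return fd_jacobian(lambda s: self.rhs(s, a), state)

    def equilibrium(self, a):  # pragma: no cover - interface
        raise NotImplementedError


class SyntheticHopfField(PlanarField):
    """Registered test field with a planted Hopf crossing at a = a_crit:

        dx/dt = (a - a_crit)*x - omega*y + c*x*(x^2 + y^2)
        dy/dt = omega*x + (a - a_crit)*y + c*y*(x^2 + y^2)

    Equilibrium at the origin; eigenvalues (a - a_crit) +- i*omega, so the
    crossing is exactly at a_crit with frequency omega; the cubic radial term
    makes the bifurcation supercritical for c < 0 (L1 = c).
    """

    def __init__(self, a_crit: float = 0.25, omega: float = 1.0, c: float = -1.0):
        self.a_crit = a_crit
        self.omega = omega
        self.c = c

    def rhs(self, state, a):
        x, y = state
        r2 = x * x + y * y
        mu = a - self.a_crit
        return np.array([mu * x - self.omega * y + self.c * x * r2,
                         self.omega * x + mu * y + self.c * y * r2])

    def jacobian(self, state, a):
        x, y = state
        mu = a - self.a_crit
        c = self.c
        return np.array([
            [mu + c * (3 * x * x + y * y), -self.omega + 2 * c * x * y],
            [self.omega + 2 * c * x * y, mu + c * (x * x + 3 * y * y)],
        ])

    def equilibrium(self, a):
        return np.zeros(2)


class RadialNormalFormField(PlanarField):
    """dx/dt = -y + a*x*(x^2+y^2), dy/dt = x + a*y*(x^2+y^2): r' = a r^3."""

    def rhs(self, state, a):
        x, y = state
        r2 = x * x + y * y
        return np.array([-y + a * x * r2, x + a * y * r2])

    def equilibrium(self, a):
        return np.zeros(2)


class _TumorSigmaField(PlanarField):
    """The tumor model with sigma as bifurcation parameter; the equilibrium
    is tracked by continuation (nearest interior point to the previous one)."""

    def __init__(self, template: Parameters):
        self.template = template
        self._last: np.ndarray | None = None

    def _params(self, sigma: float) -> Parameters:
        return self.template.replace(sigma=sigma)

    def rhs(self, state, sigma):
        from .model import ode_rhs
        return np.asarray(ode_rhs(state, self._params(sigma)), dtype=float)

    def jacobian(self, state, sigma):
        return ode_jacobian(state, self._params(sigma))

    def equilibrium(self, sigma):
        fps = interior_fixed_points(self._params(sigma))
        if not fps:
            raise _EquilibriumLost(sigma)
        pts = np.array([tuple(fp.location) for fp in fps])
        if self._last is None:
            pick = pts[0]
        else:
            pick = pts[np.argmin(np.linalg.norm(pts - self._last, axis=1))]
        self._last = pick
        return pick


class _EquilibriumLost(Exception):
    def __init__(self, a):
        self.a = a


def _first_root(fun, grid, vals) -> float | None:
    """First root of ``fun`` on a scanned grid; exact grid hits are honored."""
    for i in range(len(grid) - 1):
        a, b = float(grid[i]), float(grid[i + 1])
        fa, fb = float(vals[i]), float(vals[i + 1])
        if fa == 0.0:
            return a
        if fa * fb < 0.0:
            return float(brentq(fun, a, b, xtol=1e-14, rtol=8.9e-16))
    if len(grid) and float(vals[-1]) == 0.0:
        return float(grid[-1])
    return None


def _max_re(field: PlanarField, a: float) -> float:
    eq = field.equilibrium(a)
    return float(np.max(np.linalg.eigvals(field.jacobian(eq, a)).real))


def hopf_scan(field: PlanarField | Parameters, sigma_range: tuple[float, float],
              n_scan: int = 101) -> HopfReport:
    """Scan the bifurcation parameter for a Hopf crossing.

    Accepts either a :class:`PlanarField` or a :class:`Parameters` template
    (in which case sigma is the scanned parameter).  Returns ``none-found``
    when the leading real part never changes sign; if the equilibrium
    disappears mid-range the report covers the valid sub-range only.
    """
    if isinstance(field, Parameters):
        field = _TumorSigmaField(field)
    a_lo, a_hi = sigma_range
    grid = np.linspace(a_lo, a_hi, n_scan)
    res = []
    valid_hi = a_hi
    for a in grid:
        try:
            res.append(_max_re(field, float(a)))
        except _EquilibriumLost:
            valid_hi = float(a)
            break
    res = np.asarray(res)
    valid = (a_lo, float(grid[len(res) - 1])) if len(res) else None
    a0 = _first_root(lambda a: _max_re(field, a), grid[: len(res)], res)
    if a0 is None:
        return HopfReport(None, None, None, None, "none-found",
                          (a_lo, a_hi), valid)
    eq = field.equilibrium(a0)
    eig = np.linalg.eigvals(field.jacobian(eq, a0))
    omega0 = float(np.max(np.abs(eig.imag)))
    da = 1e-6 * (1.0 + abs(a0))
    dre = (_max_re(field, a0 + da) - _max_re(field, a0 - da)) / (2 * da)
    l1 = hopf_l1(lambda s: field.rhs(s, a0), eq, omega0,
                 jacobian=field.jacobian(eq, a0))
    if abs(l1) < 1e-10:
        direction = "degenerate"
    else:
        direction = "supercritical" if l1 < 0 else "subcritical"
    return HopfReport(float(a0), omega0, float(dre), float(l1), direction,
                      (a_lo, a_hi), valid)


def hopf_l1(field, equilibrium, omega0: float, jacobian: np.ndarray | None = None,
            fd_step: float = 1e-2) -> float:
    """First Lyapunov coefficient of a planar field at a Hopf point.

    ``field`` maps a state to its rate pair; ``equilibrium`` must carry a
    purely imaginary eigenvalue pair +-i*omega0 (checked).  The field is
    translated to the origin and transformed by the real eigenbasis so its
    linear part is the rotation [[0, -w], [w, 0]]; the coefficient is then
    assembled from second/third partial derivatives (the classical
    1/16 (fxxx + fxyy + gxxy + gyyy) + 1/(16 w) [...] formula), derivatives
    taken by 4th-order central differences.
    """
    eq = np.asarray(equilibrium, dtype=float)
    A = jacobian if jacobian is not None else fd_jacobian(field, eq)
    eigval, eigvec = np.linalg.eig(A)
    k = int(np.argmax(eigval.imag))
    lam = eigval[k]
    if abs(lam.real) > 1e-6 * (1.0 + abs(lam)) or lam.imag <= 0:
        raise ValueError(
            f"equilibrium eigenvalues {eigval} are not a purely imaginary pair"
        )
    w = float(lam.imag)
    q = eigvec[:, k]
    Q = np.column_stack([q.real, -q.imag])  # Q^-1 A Q = [[0,-w],[w,0]]
    Q = Q / math.sqrt(abs(np.linalg.det(Q)))  # unit-determinant normalization
    Qi = np.linalg.inv(Q)

    def f(u):
        return float((Qi @ np.asarray(field(eq + Q @ u), dtype=float))[0])

    def g(u):
        return float((Qi @ np.asarray(field(eq + Q @ u), dtype=float))[1])

    o = np.zeros(2)
    s = fd_step
    fxx = fd_partial(f, o, (0, 0), s)
    fyy = fd_partial(f, o, (1, 1), s)
    fxy = fd_partial(f, o, (0, 1), s)
    gxx = fd_partial(g, o, (0, 0), s)
    gyy = fd_partial(g, o, (1, 1), s)
    gxy = fd_partial(g, o, (0, 1), s)
    fxxx = fd_partial(f, o, (0, 0, 0), s)
    fxyy = fd_partial(f, o, (0, 1, 1), s)
    gxxy = fd_partial(g, o, (0, 0, 1), s)
    gyyy = fd_partial(g, o, (1, 1, 1), s)
    L1 = (fxxx + fxyy + gxxy + gyyy) / 16.0
    L2 = (fxy * (fxx + fyy) - gxy * (gxx + gyy) - fxx * gxx + fyy * gyy) / (16.0 * w)
    return float(L1 + L2)


# ---------------------------------------------------------------------------
# Neimark-Sacker analysis (NSFD map)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NSReport:
    h_crit: float | None
    trace_at_crit: float | None = None
    det_at_crit: float | None = None
    modulus_derivative: float | None = None
    complex_pair: bool | None = None
    resonance_flags: dict | None = None
    coeff: float | None = None
    direction: str | None = None  # supercritical | subcritical | degenerate
    fixed_point: FixedPoint | None = None
    diagnostics: str | None = None


H_BRACKET = (1e-3, 1.0 - 1e-6)  # lower bound excludes the trivial root D(0)=1


def _pick_fp(params: Parameters, fixed_point: FixedPoint | None) -> FixedPoint:
    if fixed_point is not None:
        return fixed_point
    fps = interior_fixed_points(params)
    if not fps:
        raise ValueError("no interior fixed point for these parameters")
    return fps[0]


def _det_minus_1(params: Parameters, fp: FixedPoint):
    loc = fp.location

    def fun(h: float) -> float:
        return float(np.linalg.det(map_jacobian(loc, params, h, "nsfd"))) - 1.0

    return fun


def ns_critical_h(params: Parameters, fixed_point: FixedPoint | None = None,
                  n_scan: int = 256) -> NSReport:
    """Locate the Neimark-Sacker threshold det J(h) = 1 on (0.001, 1).

    Returns a partial report (``h_crit=None`` plus diagnostics) when the
    determinant never crosses unity inside the bracket.
    """
    fp = _pick_fp(params, fixed_point)
    fun = _det_minus_1(params, fp)
    grid = np.linspace(H_BRACKET[0], H_BRACKET[1], n_scan)
    vals = np.array([fun(h) for h in grid])
    h_crit = _first_root(fun, grid, vals)
    if h_crit is None:
        return NSReport(None, fixed_point=fp,
                        diagnostics="det(J(h)) - 1 has no sign change in the bracket")
    J = map_jacobian(fp.location, params, h_crit, "nsfd")
    T = float(np.trace(J))
    D = float(np.linalg.det(J))
    complex_pair = T * T - 4.0 * D < 0.0

    def modulus(h: float) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(
            map_jacobian(fp.location, params, h, "nsfd")))))

    dh = 1e-6 * (1.0 + abs(h_crit))
    dmod = (modulus(h_crit + dh) - modulus(h_crit - dh)) / (2 * dh)
    return NSReport(float(h_crit), trace_at_crit=T, det_at_crit=D,
                    modulus_derivative=float(dmod), complex_pair=complex_pair,
                    fixed_point=fp)


def resonance_flags_from_trace(T: float, tol: float = 1e-9) -> dict:
    """Flags for low-order resonances lam^m = 1, m = 1..4, of a unit-modulus
    complex pair.  With lam = exp(+-i*theta), theta = arccos(T/2), the
    resonances occur at T = 2, -2, -1, 0 respectively."""
    return {
        1: abs(T - 2.0) < tol,
        2: abs(T + 2.0) < tol,
        3: abs(T + 1.0) < tol,
        4: abs(T) < tol,
    }


def ns_nonresonance(params: Parameters, h_crit: float,
                    fixed_point: FixedPoint | None = None,
                    tol: float = 1e-9) -> dict:
    """Low-order resonance flags for the NSFD map at ``h_crit``."""
    fp = _pick_fp(params, fixed_point)
    J = map_jacobian(fp.location, params, h_crit, "nsfd")
    return resonance_flags_from_trace(float(np.trace(J)), tol)


def ns_normal_form_coefficient(J: np.ndarray, D2: np.ndarray, D3: np.ndarray) -> float:
    """Normal-form coefficient for a planar map at a Neimark-Sacker point.

    ``J`` is the Jacobian at the fixed point (det 1, complex pair), ``D2``
    and ``D3`` the second/third derivative tensors of the map there
    (D2[i,a,b] = d^2 G_i / dz_a dz_b and analogously for D3).  The map is
    transformed by the real eigenbasis so its linear part is the rotation
    by theta = arg(m); the quadratic/cubic coefficients xi20, xi11, xi02,
    xi21 are assembled and combined in the standard way.
    """
    T = float(np.trace(J))
    D = float(np.linalg.det(J))
    disc = 4.0 * D - T * T
    if disc <= 0:
        raise ValueError("Jacobian eigenvalues are not a complex pair")
    lam = T / 2.0
    om = math.sqrt(disc) / 2.0
    l11, l12 = float(J[0, 0]), float(J[0, 1])
    if abs(l12) < 1e-14:
        # eigenbasis from the second row instead
        Jf = np.array([[J[1, 1], J[1, 0]], [J[0, 1], J[0, 0]]])
        D2f = D2[::-1][:, ::-1, :][:, :, ::-1]
        D3f = D3[::-1][:, ::-1][:, :, ::-1][:, :, :, ::-1]
        return ns_normal_form_coefficient(Jf, D2f, D3f)
    Tr = np.array([[l12, 0.0], [lam - l11, -om]])
    Ti = np.linalg.inv(Tr)
    H2 = np.einsum("ij,jkl,ka,lb->iab", Ti, D2, Tr, Tr)
    H3 = np.einsum("ij,jklm,ka,lb,mc->iabc", Ti, D3, Tr, Tr, Tr)
    Fuu, Fuv, Fvv = H2[0, 0, 0], H2[0, 0, 1], H2[0, 1, 1]
    Guu, Guv, Gvv = H2[1, 0, 0], H2[1, 0, 1], H2[1, 1, 1]
    Fuuu, Fuuv, Fuvv, Fvvv = H3[0, 0, 0, 0], H3[0, 0, 0, 1], H3[0, 0, 1, 1], H3[0, 1, 1, 1]
    Guuu, Guuv, Guvv, Gvvv = H3[1, 0, 0, 0], H3[1, 0, 0, 1], H3[1, 0, 1, 1], H3[1, 1, 1, 1]
    xi20 = ((Fuu - Fvv + 2 * Guv) + 1j * (Guu - Gvv - 2 * Fuv)) / 8.0
    xi11 = ((Fuu + Fvv) + 1j * (Guu + Gvv)) / 4.0
    xi02 = ((Fuu - Fvv - 2 * Guv) + 1j * (Guu - Gvv + 2 * Fuv)) / 8.0
    xi21 = ((Fuuu + Fuvv + Guuv + Gvvv) + 1j * (Guuu + Guvv - Fuuv - Fvvv)) / 16.0
    m = lam + 1j * om
    mbar = lam - 1j * om
    return float(
        (-((1 - 2 * m) * mbar**2 / (1 - m) * xi20 * xi11).real)
        - 0.5 * abs(xi11) ** 2
        - abs(xi02) ** 2
        + (mbar * xi21).real
    )


def ns_coefficient(params: Parameters, h_crit: float,
                   fixed_point: FixedPoint | None = None) -> NSReport:
    """Full Neimark-Sacker report at ``h_crit`` for the NSFD map."""
    fp = _pick_fp(params, fixed_point)
    flags = ns_nonresonance(params, h_crit, fp)
    if any(flags.values()):
        raise ValueError(f"low-order resonance present at h={h_crit}: {flags}")
    x, y = fp.location
    pars = params.astuple()
    J = map_jacobian(fp.location, params, h_crit, "nsfd")
    coeff = ns_normal_form_coefficient(
        J, nsfd_d2_exact(x, y, h_crit, pars), nsfd_d3_exact(x, y, h_crit, pars)
    )

    def modulus(h: float) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(
            map_jacobian(fp.location, params, h, "nsfd")))))

    dh = 1e-6 * (1.0 + abs(h_crit))
    dmod = (modulus(h_crit + dh) - modulus(h_crit - dh)) / (2 * dh)
    T = float(np.trace(J))
    D = float(np.linalg.det(J))
    if abs(coeff) < 1e-14:
        direction = "degenerate"
    else:
        direction = "supercritical" if coeff < 0 else "subcritical"
    return NSReport(float(h_crit), trace_at_crit=T, det_at_crit=D,
                    modulus_derivative=float(dmod),
                    complex_pair=T * T - 4 * D < 0, resonance_flags=flags,
                    coeff=coeff, direction=direction, fixed_point=fp)


def delayed_logistic_ns_coefficient(r: float = 2.0) -> float:
    """NS coefficient of the registered delayed-logistic test map
    (x, y) -> (y, r*y*(1-x)) at its fixed point; the r = 2 point is the
    classical supercritical example used as an independent check."""
    ystar = 1.0 - 1.0 / r
    J = np.array([[0.0, 1.0], [-r * ystar, r * (1.0 - ystar)]])
    D2 = np.zeros((2, 2, 2))
    D2[1, 0, 1] = D2[1, 1, 0] = -r
    D3 = np.zeros((2, 2, 2, 2))
    return ns_normal_form_coefficient(J, D2, D3)


# ---------------------------------------------------------------------------
# Hybrid bifurcation control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ControlReport:
    h: float
    stable_b_intervals: list
    predicate_samples: list  # (b, jury_ok, spectral_radius)


def control_stability_interval(params: Parameters, h: float, b_grid=None,
                               fixed_point: FixedPoint | None = None) -> ControlReport:
    """Stable gain intervals of the hybrid-controlled map at step size h.

    For each b the controlled Jacobian Jc = (1 - sin b) I + sin b J(h) is
    classified by the full Jury predicate |Tr Jc| < 1 + det Jc < 2, and
    cross-checked against the spectral radius.  Maximal contiguous runs of
    stable grid points are reported as (b_low, b_high) intervals.
    """
    fp = _pick_fp(params, fixed_point)
    if b_grid is None:
        b_grid = np.linspace(1e-3, 1.0, 1000)
    b_grid = np.asarray(b_grid, dtype=float)
    J = map_jacobian(fp.location, params, h, "nsfd")
    samples = []
    stable = np.zeros(len(b_grid), dtype=bool)
    for i, b in enumerate(b_grid):
        g = math.sin(b)
        Jc = (1.0 - g) * np.eye(2) + g * J
        T = float(np.trace(Jc))
        D = float(np.linalg.det(Jc))
        jury = abs(T) < 1.0 + D < 2.0
        rho_c = float(np.max(np.abs(np.linalg.eigvals(Jc))))
        samples.append((float(b), jury, rho_c))
        stable[i] = jury
    intervals = []
    i = 0
    while i < len(b_grid):
        if stable[i]:
            j = i
            while j + 1 < len(b_grid) and stable[j + 1]:
                j += 1
            intervals.append((float(b_grid[i]), float(b_grid[j])))
            i = j + 1
        else:
            i += 1
    return ControlReport(h=float(h), stable_b_intervals=intervals,
                        predicate_samples=samples)
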