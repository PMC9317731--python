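import numpy as np
import pytest

from nsfdtumor import (
    RadialNormalFormField,
    SyntheticHopfField,
    control_stability_interval,
    delayed_logistic_ns_coefficient,
    hopf_l1,
    hopf_scan,
    interior_fixed_points,
    ns_coefficient,
    ns_critical_h,
    ns_nonresonance,
    ns_normal_form_coefficient,
    simulate_orbit,
)
from nsfdtumor.bifurcation import resonance_flags_from_trace


# ---------------------------------------------------------------------------
# Neimark-Sacker threshold
# ---------------------------------------------------------------------------

def test_ns_critical_h_preset(ns_partial):
    rep = ns_partial
    assert 0.487 < rep.h_crit < 0.497
    assert abs(rep.det_at_crit - 1.0) < 1e-10
    assert rep.complex_pair
    assert rep.modulus_derivative > 0  # transversality: pair leaves the disk


def test_ns_critical_h_absent_for_weak_recruitment(discrete_params):
    rep = ns_critical_h(discrete_params.replace(rho=0.2))
    assert rep.h_crit is None
    assert rep.diagnostics is not None


def test_ns_nonresonance_preset(discrete_params, ns_partial):
    flags = ns_nonresonance(discrete_params, ns_partial.h_crit)
    assert not any(flags.values())
    assert ns_partial.trace_at_crit == pytest.approx(1.96255, abs=1e-4)
    theta = np.arccos(ns_partial.trace_at_crit / 2)
    assert theta == pytest.approx(0.1937, abs=1e-3)


@pytest.mark.parametrize("trace, m", [(2.0, 1), (-2.0, 2), (-1.0, 3), (0.0, 4)])
def test_resonance_flags_at_roots_of_unity(trace, m):
    flags = resonance_flags_from_trace(trace)
    assert flags[m]
    assert sum(flags.values()) == 1


def test_ns_coefficient_preset_supercritical(discrete_params, ns_partial):
    rep = ns_coefficient(discrete_params, ns_partial.h_crit, ns_partial.fixed_point)
    assert rep.coeff < 0
    assert rep.direction == "supercritical"
    assert not any(rep.resonance_flags.values())


def test_ns_direction_confirmed_by_simulation(discrete_params, ns_partial):
    """Attracting invariant curve just above h_crit, spiral-in just below."""
    fp = np.asarray(ns_partial.fixed_point.location)
    below = simulate_orbit("nsfd", fp + 1e-3, discrete_params,
                           ns_partial.h_crit - 0.02, 60_000, 59_500)
    dist_below = np.linalg.norm(below.states - fp, axis=1)
    assert dist_below.max() < 1e-6
    above = simulate_orbit("nsfd", fp + 1e-3, discrete_params,
                           ns_partial.h_crit + 0.02, 60_000, 59_500)
    dist_above = np.linalg.norm(above.states - fp, axis=1)
    assert not above.diverged
    assert dist_above.min() > 1e-2  # settled on a closed curve away from the point


def test_delayed_logistic_reference_map():
    coeff = delayed_logistic_ns_coefficient(2.0)
    assert coeff == pytest.approx(-0.5, abs=1e-12)
    # oracle: r slightly above 2 has a bounded attracting curve off the point
    fp = 1.0 - 1.0 / 2.05
    s = np.array([0.51, 0.51])
    step = lambda z: np.array([z[1], 2.05 * z[1] * (1 - z[0])])
    for _ in range(5000):
        s = step(s)
    dists = []
    for _ in range(500):
        s = step(s)
        dists.append(np.hypot(s[0] - fp, s[1] - fp))
    assert 0.01 < min(dists) and max(dists) < 1.0


def test_affine_map_has_zero_coefficient():
    J = np.array([[0.6, -0.8], [0.8, 0.6]])  # rotation, det 1
    zero2 = np.zeros((2, 2, 2))
    zero3 = np.zeros((2, 2, 2, 2))
    assert ns_normal_form_coefficient(J, zero2, zero3) == 0.0


# ---------------------------------------------------------------------------
# Hopf machinery
# ---------------------------------------------------------------------------

def test_hopf_scan_finds_no_crossing_on_tumor_model(discrete_params, continuous_params):
    # interior trace identity T = -sigma/x - alpha*beta*y < 0 for all sigma
    for p in (discrete_params, continuous_params):
        rep = hopf_scan(p, (1e-4, 0.5), n_scan=26)
        assert rep.direction == "none-found"
        assert rep.sigma0 is None


def test_hopf_scan_recovers_planted_crossing():
    field = SyntheticHopfField(a_crit=0.237, omega=1.4, c=-0.8)
    rep = hopf_scan(field, (0.0, 0.5))
    assert rep.sigma0 == pytest.approx(0.237, abs=1e-8)
    assert rep.omega0 == pytest.approx(1.4, abs=1e-8)
    assert rep.dre_dsigma == pytest.approx(1.0, abs=1e-6)
    assert rep.direction == "supercritical"
    sub = hopf_scan(SyntheticHopfField(a_crit=0.1, c=+0.5), (0.0, 0.3))
    assert sub.direction == "subcritical"


@pytest.mark.parametrize("a", [-1.0, 1.0, -0.3])
def test_hopf_l1_radial_normal_form(a):
    field = RadialNormalFormField()
    l1 = hopf_l1(lambda s: field.rhs(s, a), (0.0, 0.0), 1.0)
    assert l1 == pytest.approx(a, abs=1e-9)


def test_hopf_l1_vanishes_for_linear_and_removable_quadratic_fields():
    assert abs(hopf_l1(lambda s: np.array([-s[1], s[0]]), (0, 0), 1.0)) < 1e-10
    # quadratic-only perturbation with no radial mean drift
    quad = lambda s: np.array([-s[1] + s[0] ** 2, s[0]])
    assert abs(hopf_l1(quad, (0, 0), 1.0)) < 1e-8


def test_hopf_l1_requires_imaginary_pair():
    with pytest.raises(ValueError, match="imaginary"):
        hopf_l1(lambda s: np.array([-0.5 * s[0] - s[1], s[0] - 0.5 * s[1]]), (0, 0), 1.0)


# ---------------------------------------------------------------------------
# hybrid control
# ---------------------------------------------------------------------------

def test_control_interval_nonempty_at_unstable_step(discrete_params):
    rep = control_stability_interval(discrete_params, 0.6)
    assert rep.stable_b_intervals
    lo, hi = rep.stable_b_intervals[0]
    assert 0.0 < lo < hi <= 1.0
    # Jury predicate must agree exactly with the spectral radius oracle
    for b, jury, rho_c in rep.predicate_samples:
        if abs(rho_c - 1.0) > 1e-9:
            assert jury == (rho_c < 1.0), (b, jury, rho_c)


def test_control_all_gains_stable_below_critical_step(discrete_params):
    rep = control_stability_interval(discrete_params, 0.3, np.linspace(0.01, 1.0, 100))
    assert all(j for _, j, _ in rep.predicate_samples)
    assert rep.stable_b_intervals == [(pytest.approx(0.01), pytest.approx(1.0))]
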