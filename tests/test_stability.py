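import numpy as np
import pytest

from nsfdtumor import (
    boundary_fixed_point,
    classify_continuous,
    classify_map_fp,
    cminus1,
    interior_fixed_points,
    map_jacobian,
    ode_jacobian,
    sample_admissible_params,
)
from nsfdtumor.maps import ControlGain, controlled_step, euler_step, nsfd_step
from nsfdtumor.stability import classify_continuous_jacobian, classify_from_jacobian
from nsfdtumor._derivatives import fd_jacobian


def test_ode_jacobian_matches_finite_differences(discrete_params, rng):
    for _ in range(100):
        s = rng.uniform(0.01, 10.0, size=2)
        J = ode_jacobian(s, discrete_params)
        from nsfdtumor import ode_rhs

        Jfd = fd_jacobian(lambda z: np.asarray(ode_rhs(z, discrete_params)), s)
        assert np.max(np.abs(J - Jfd)) < 1e-6


def test_ode_jacobian_special_points(discrete_params, interior_fp):
    p = discrete_params
    J0 = ode_jacobian((0.0, 0.0), p)
    assert np.allclose(J0, [[-p.delta, 0.0], [0.0, p.alpha]])
    x, y = interior_fp.location
    J = ode_jacobian(interior_fp.location, p)
    # interior identities: J11 = -sigma/x*, J22 = -alpha*beta*y*
    assert J[0, 0] == pytest.approx(-p.sigma / x, abs=1e-10)
    assert J[1, 1] == pytest.approx(-p.alpha * p.beta * y, abs=1e-10)
    assert np.trace(J) == pytest.approx(-0.100187, abs=1e-6)


@pytest.mark.parametrize("scheme", ["nsfd", "euler", "controlled"])
def test_map_jacobian_h0_is_identity(discrete_params, scheme):
    gain = ControlGain(0.7) if scheme == "controlled" else None
    J = map_jacobian((1.2, 3.4), discrete_params, 0.0, scheme, gain)
    assert np.allclose(J, np.eye(2))


@pytest.mark.parametrize("scheme, stepper", [
    ("nsfd", nsfd_step),
    ("euler", euler_step),
    ("controlled", None),
])
def test_map_jacobian_matches_finite_differences(discrete_params, rng, scheme, stepper):
    gain = ControlGain(0.8) if scheme == "controlled" else None
    for _ in range(100):
        s = rng.uniform(0.01, 10.0, size=2)
        h = rng.uniform(0.01, 0.99)
        J = map_jacobian(s, discrete_params, h, scheme, gain)
        if scheme == "controlled":
            f = lambda z: np.asarray(controlled_step(z, discrete_params, h, gain))
        else:
            f = lambda z: np.asarray(stepper(z, discrete_params, h))
        assert np.max(np.abs(J - fd_jacobian(f, s))) < 1e-6


def test_nsfd_interior_determinant_near_unity_at_printed_step(discrete_params, interior_fp):
    J = map_jacobian(interior_fp.location, discrete_params, 0.4917268, "nsfd")
    assert abs(np.linalg.det(J) - 1.0) < 5e-4


def test_classify_continuous(discrete_params, interior_fp):
    rep = classify_continuous(interior_fp, discrete_params)
    assert rep.klass == "sink"
    assert rep.trace == pytest.approx(-0.1002, abs=1e-4)
    assert rep.det == pytest.approx(0.3346, abs=1e-4)
    b = classify_continuous(boundary_fixed_point(discrete_params), discrete_params)
    assert b.klass == "saddle"
    # eigenvalues -delta and alpha - sigma/delta of opposite sign
    eig = sorted(e.real for e in b.eigenvalues)
    assert eig[0] == pytest.approx(-0.3743) and eig[1] == pytest.approx(1.32048, abs=1e-5)
    assert classify_continuous_jacobian(np.diag([-1.0, -2.0])).klass == "sink"


def test_classify_boundary_map_point(discrete_params):
    rep = classify_map_fp(boundary_fixed_point(discrete_params), discrete_params, 0.5)
    assert rep.klass == "saddle"
    mods = sorted(abs(e) for e in rep.eigenvalues)
    # closed-form boundary multipliers 1/(1+h*delta) and delta(1+h*alpha)/(delta+h*sigma)
    assert mods[0] == pytest.approx(0.842354, abs=1e-6)
    assert mods[1] == pytest.approx(1.570272, abs=1e-6)


def test_boundary_point_is_sink_when_growth_below_influx(discrete_params):
    # alpha*delta < sigma: both multipliers inside the unit circle
    p = discrete_params.replace(sigma=1.0)
    rep = classify_map_fp(boundary_fixed_point(p), p, 0.5)
    assert rep.klass == "sink"


@pytest.mark.parametrize("h, expected", [(0.30, "sink"), (0.60, "source")])
def test_classify_interior_map_point(discrete_params, interior_fp, h, expected):
    rep = classify_map_fp(interior_fp, discrete_params, h)
    assert rep.klass == expected
    assert rep.char_at_plus1 == pytest.approx(1 - rep.trace + rep.det, abs=1e-12)
    assert rep.char_at_minus1 == pytest.approx(1 + rep.trace + rep.det, abs=1e-12)


def test_cminus1_values(discrete_params, interior_fp, ns_partial):
    assert cminus1(interior_fp, discrete_params, 0.0) == pytest.approx(4.0, abs=1e-14)
    assert cminus1(interior_fp, discrete_params, ns_partial.h_crit) == pytest.approx(
        3.9626, abs=1e-3
    )


def test_no_flip_bifurcation_over_random_draws():
    draws = sample_admissible_params(seed=13, n=100, constraints=["interior_exists"])
    hs = np.linspace(0.02, 0.98, 20)
    for p in draws:
        fp = interior_fixed_points(p)[0]
        for h in hs:
            assert cminus1(fp, p, float(h)) > 0.0


def test_interior_trace_identity_over_random_draws():
    draws = sample_admissible_params(seed=17, n=100, constraints=["interior_exists"])
    for p in draws:
        for fp in interior_fixed_points(p):
            x, y = fp.location
            J = ode_jacobian(fp.location, p)
            assert abs(np.trace(J) + p.sigma / x + p.alpha * p.beta * y) < 1e-10
            assert np.trace(J) < 0.0


def test_jury_agrees_with_eigenvalue_moduli(rng):
    draws = sample_admissible_params(seed=19, n=30, constraints=["interior_exists"])
    for p in draws:
        fp = interior_fixed_points(p)[0]
        for h in rng.uniform(0.02, 0.98, size=5):
            rep = classify_map_fp(fp, p, float(h))
            mods = sorted(abs(e) for e in rep.eigenvalues)
            if rep.klass == "sink":
                assert mods[1] < 1 + 1e-9
            elif rep.klass == "source":
                assert mods[0] > 1 - 1e-9
            elif rep.klass == "saddle":
                assert mods[0] < 1 + 1e-9 < mods[1] + 2e-9


def test_map_trace_det_at_h0(discrete_params, interior_fp):
    J = map_jacobian(interior_fp.location, discrete_params, 0.0)
    assert np.trace(J) == 2.0 and np.linalg.det(J) == 1.0
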