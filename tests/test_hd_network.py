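"""HD ring attractor: kernel structure, dynamics, bump readout."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thetasweep.errors import NumericalDivergenceError, \
    UndefinedDirectionError
from thetasweep.fixtures import make_bump_field
from thetasweep.hd_network import (
    HDNetState,
    HDParams,
    build_ring_kernel,
    divisive_rates,
    hd_input,
    internal_direction,
    preferred_directions,
    ring_distance,
    run_hd,
    step_hd,
    theta_gain_hd,
)
from thetasweep.trajectory import make_rotation, make_straight_run, \
    wrap_angle


@pytest.mark.parametrize("a,b,expected", [
    (0.0, np.pi, np.pi),
    (0.1, 2 * np.pi - 0.1, 0.2),
    (1.234, 1.234, 0.0),
    (-3.0, 3.0, 2 * np.pi - 6.0),
])
def test_ring_distance(a, b, expected):
    np.testing.assert_allclose(ring_distance(a, b), expected, atol=1e-12)
    np.testing.assert_allclose(ring_distance(b, a), expected, atol=1e-12)


def test_ring_kernel_structure():
    params = HDParams(n=64)
    j = build_ring_kernel(params)
    np.testing.assert_allclose(j, j.T, atol=1e-14)
    assert np.all(np.diag(j) == j.max(axis=1))
    # translation invariance on the uniform ring: equal row sums
    np.testing.assert_allclose(j.sum(axis=1), j.sum(axis=1)[0], rtol=1e-12)
    np.testing.assert_allclose(
        j.max(), params.j0 / (2 * np.pi * params.b ** 2))


def test_ring_kernel_noise_is_seeded():
    p = HDParams(conn_noise_sd=0.1, conn_noise_seed=3)
    a, b = build_ring_kernel(p), build_ring_kernel(p)
    np.testing.assert_array_equal(a, b)
    assert not np.allclose(a, build_ring_kernel(HDParams()))


def test_theta_gain_limits():
    p = HDParams()
    assert theta_gain_hd(0.0, 0.123, p) == 1.0       # immobile
    assert theta_gain_hd(0.7, 0.0, p) == 1.0          # sin(0) = 0
    p0 = HDParams(abar=0.0)                           # septal inactivation
    t = np.linspace(0, 1, 100)
    np.testing.assert_array_equal(theta_gain_hd(0.8, t, p0), 1.0)


def test_hd_input_peak_and_symmetries():
    p = HDParams()
    x = preferred_directions(p.n)
    theta = 1.1
    inp = hd_input(theta, 0.3, 0.0, p, x)
    assert np.argmax(inp) == np.argmin(ring_distance(x, theta))
    np.testing.assert_allclose(inp, hd_input(theta + 2 * np.pi, 0.3, 0.0,
                                             p, x), atol=1e-12)
    doubled = hd_input(theta, 0.3, 0.0, p.with_(a_input=2 * p.a_input), x)
    np.testing.assert_allclose(doubled, 2 * inp, rtol=1e-12)


def test_divisive_rates_closed_forms():
    np.testing.assert_array_equal(divisive_rates(np.zeros(5), 1.0),
                                  np.zeros(5))
    h = np.array([1.0, -2.0, 0.5])
    np.testing.assert_allclose(divisive_rates(h, 0.0), h ** 2)
    c = 3.0
    single = np.array([0.0, c, 0.0])
    np.testing.assert_allclose(divisive_rates(single, 1.0)[1],
                               c ** 2 / (1 + c ** 2))
    with pytest.raises(ValueError):
        divisive_rates(h, -0.1)


def test_step_hd_fixed_points_and_adaptation():
    p = HDParams(m=0.0)
    kernel = build_ring_kernel(p)
    state = HDNetState.zeros(p)
    zero = np.zeros(p.n)
    out = step_hd(state, zero, 1e-3, p, kernel)
    np.testing.assert_array_equal(out.h, 0.0)     # all-zero fixed point
    np.testing.assert_array_equal(out.a, 0.0)     # m=0 keeps adaptation 0
    with pytest.raises(ValueError, match="dt"):
        step_hd(state, zero, 1.0, p, kernel)
    state.h[0] = np.nan
    with pytest.raises(NumericalDivergenceError, match="'h'"):
        step_hd(state, zero, 1e-3, p, kernel)


def test_bump_settles_on_input_peak_without_adaptation():
    p = HDParams(m=0.0, abar=0.0)
    kernel = build_ring_kernel(p)
    state = HDNetState.zeros(p)
    theta = 2.0
    inp = hd_input(theta, 0.0, 0.0, p, state.x)
    for _ in range(1000):  # 100 tau
        state = step_hd(state, inp, 1e-3, p, kernel)
    center = internal_direction(state.r, state.x)
    assert ring_distance(center, theta) < 2 * np.pi / p.n


def test_internal_direction_readout():
    x = preferred_directions(100)
    bump = make_bump_field(1.0, 0.4, 100, "ring")
    np.testing.assert_allclose(internal_direction(bump, x), 1.0, atol=1e-6)
    # bump straddling the pi/-pi seam
    seam = make_bump_field(np.pi - 0.02, 0.4, 100, "ring")
    np.testing.assert_allclose(
        np.exp(1j * internal_direction(seam, x)),
        np.exp(1j * (np.pi - 0.02)), atol=1e-5)
    with pytest.raises(UndefinedDirectionError):
        internal_direction(np.ones(100), x)       # uniform: zero resultant
    with pytest.raises(UndefinedDirectionError):
        internal_direction(np.zeros(100), x)


def test_tracking_limit_without_adaptation_or_theta():
    """No adaptation, no theta: internal direction locks to the HD."""
    p = HDParams(m=0.0, abar=0.0)
    traj = make_rotation(np.pi / 2, 0.0, 2.0, linear_speed=0.3)
    run = run_hd(traj, p, warmup=0.5)
    ang, ok = run.internal_direction_trace()
    assert ok.all()
    err = np.abs(wrap_angle(ang - traj.theta_hd))
    assert err.max() < p.b          # within one bump half-width


def test_anticipatory_lead_scales_with_rotation_speed():
    """With adaptation, the bump leads rotation, more so when faster."""
    p = HDParams(abar=0.0)
    leads = []
    for omega in (np.pi / 4, np.pi / 2, np.pi):
        traj = make_rotation(omega, 0.0, 3.0, linear_speed=0.3)
        run = run_hd(traj, p, warmup=0.5)
        ang, ok = run.internal_direction_trace()
        off = wrap_angle(ang - traj.theta_hd)[run.t > 1.0]
        leads.append(np.mean(off))
    assert all(lead > 0 for lead in leads)        # lead has rotation sign
    assert leads[0] < leads[1] < leads[2]         # monotone in speed
    # clockwise rotation leads the other way
    traj = make_rotation(-np.pi / 2, 0.0, 3.0, linear_speed=0.3)
    run = run_hd(traj, p, warmup=0.5)
    ang, _ = run.internal_direction_trace()
    assert np.mean(wrap_angle(ang - traj.theta_hd)[run.t > 1.0]) < 0


def test_rates_nonnegative_and_bounded(hd_run_default):
    rates = hd_run_default.rates
    assert np.all(rates >= 0)
    assert np.all(np.isfinite(rates))
    # divisive normalization caps the total rate
    assert rates.sum(axis=1).max() < 2.0 / hd_run_default.params.k


def test_straight_run_sweeps_alternate(hd_run_default, straight_traj):
    """Default params: per-cycle peak offsets alternate sides, mean ~0."""
    run, traj = hd_run_default, straight_traj
    ang, ok = run.internal_direction_trace()
    off = wrap_angle(ang - traj.theta_hd)
    pop = run.pop_rate()
    om = run.params.omega_theta
    cyc = np.floor(om * run.t / (2 * np.pi)).astype(int)
    first = int(cyc[run.t >= 2.0].min())          # discard settling
    peaks = []
    for c in range(first, cyc.max()):
        idx = np.flatnonzero(cyc == c)
        peaks.append(off[idx[np.argmax(pop[idx])]])
    peaks = np.array(peaks)
    assert peaks.size >= 4
    assert np.all(np.abs(peaks) > np.deg2rad(5))
    assert np.all(np.sign(peaks[1:]) != np.sign(peaks[:-1]))
    assert abs(np.mean(off[run.t > 2.0])) < np.deg2rad(3)


def test_euler_step_halving_convergence():
    """Bump-centre trace changes by <1% of a cycle when dt halves.

    Uses a smoothly pinned regime (subcritical adaptation) where the
    trace is not a free-running limit cycle, so the pointwise
    comparison is meaningful.
    """
    p = HDParams(m=0.4)
    traj1 = make_rotation(np.pi / 2, 0.0, 2.0, dt=1e-3, linear_speed=0.4)
    traj2 = make_rotation(np.pi / 2, 0.0, 2.0, dt=5e-4, linear_speed=0.4)
    a1, _ = run_hd(traj1, p, warmup=0.5).internal_direction_trace()
    a2, _ = run_hd(traj2, p, warmup=0.5).internal_direction_trace()
    diff = np.abs(wrap_angle(a1 - a2[::2]))
    assert np.max(diff) < 0.01 * 2 * np.pi


@settings(deadline=None, max_examples=25, derandomize=True)
@given(phi=st.floats(-10, 10), psi=st.floats(-10, 10))
def test_ring_distance_is_a_metric_on_the_circle(phi, psi):
    d = ring_distance(phi, psi)
    assert 0 <= d <= np.pi + 1e-12
    assert np.isclose(ring_distance(phi, phi), 0.0)
    if not np.isclose(np.exp(1j * phi), np.exp(1j * psi)).all():
        assert d > 0


def test_hd_params_validation():
    with pytest.raises(ValueError):
        HDParams(tau_a=0.005)         # adaptation faster than rates
    with pytest.raises(ValueError):
        HDParams(n=4)
    with pytest.raises(ValueError):
        HDParams(b=-0.1)
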