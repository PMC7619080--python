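"""Grid torus attractor: phase map, kernel/convolution, conj input."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thetasweep.fixtures import make_bump_field
from thetasweep.grid_network import (
    GridNetState,
    GridParams,
    W_TRANS,
    build_torus_kernel,
    conj_input,
    kernel_convolve,
    phase_lattice,
    phase_map,
    speed_gain,
    step_grid,
    theta_gain_grid,
    torus_distance,
)
from thetasweep.hd_network import preferred_directions


def test_phase_map_origin_and_lattice_points():
    lam = 0.6
    np.testing.assert_allclose(phase_map((0.0, 0.0), lam), 0.0, atol=1e-12)
    np.testing.assert_allclose(phase_map((lam, 0.0), lam) % (2 * np.pi),
                               0.0, atol=1e-9)
    np.testing.assert_allclose(
        phase_map((lam / 2, lam * np.sqrt(3) / 2), lam) % (2 * np.pi),
        0.0, atol=1e-9)


def test_phase_map_hexagonal_lattice_invariance():
    rng = np.random.default_rng(0)
    lam = 0.45
    z = rng.uniform(-3, 3, size=(1000, 2))
    e1 = lam * np.array([1.0, 0.0])
    e2 = lam * np.array([0.5, np.sqrt(3) / 2])
    for e in (e1, e2):
        d = phase_map(z + e, lam) - phase_map(z, lam)
        err = np.abs(np.exp(1j * d) - 1.0)
        assert err.max() < 1e-9


@pytest.mark.parametrize("a,b,expected", [
    ((0.0, 0.0), (0.0, 0.0), 0.0),
    ((0.0, 0.0), (2 * np.pi - 0.1, 0.0), 0.1),
    ((0.2, 6.0), (6.0, 0.2), np.hypot(
        np.angle(np.exp(1j * (0.2 - 6.0))), np.angle(np.exp(1j * (6.0 - 0.2))))),
])
def test_torus_distance(a, b, expected):
    np.testing.assert_allclose(torus_distance(np.array(a), np.array(b)),
                               expected, atol=1e-12)
    np.testing.assert_allclose(torus_distance(np.array(b), np.array(a)),
                               expected, atol=1e-12)


def test_torus_kernel_peak_and_delta_convolution():
    p = GridParams(n_side=16)
    kern = build_torus_kernel(p)
    assert kern[0, 0] == kern.max()
    delta = np.zeros((16, 16))
    delta[3, 11] = 1.0
    conv = kernel_convolve(np.fft.rfft2(kern), delta)
    np.testing.assert_allclose(conv, np.roll(kern, (3, 11), axis=(0, 1)),
                               atol=1e-12)


def test_fft_convolution_matches_dense_matrix_oracle():
    """Circular FFT recurrence == brute-force dense weights, 16x16."""
    p = GridParams(n_side=16)
    kern = build_torus_kernel(p)
    n = p.n_side
    lx, ly = phase_lattice(n)
    coords = np.column_stack((lx.ravel(), ly.ravel()))
    d = torus_distance(coords[:, None, :], coords[None, :, :])
    dense = p.j0 / (2 * np.pi * p.b ** 2) * np.exp(-d ** 2 /
                                                   (4 * p.b ** 2))
    rng = np.random.default_rng(1)
    field = rng.random((n, n))
    via_fft = kernel_convolve(np.fft.rfft2(kern), field)
    via_dense = (dense @ field.ravel()).reshape(n, n)
    assert np.max(np.abs(via_fft - via_dense)) < 1e-10


def test_speed_gain_is_affine():
    p = GridParams()
    assert speed_gain(0.0, p) == p.a_input
    v = 0.37
    np.testing.assert_allclose(speed_gain(2 * v, p) - speed_gain(v, p),
                               p.t0 * v, rtol=1e-12)


def test_theta_gain_grid_limits():
    p = GridParams()
    assert theta_gain_grid(0.0, 0.5, p) == 1.0
    assert theta_gain_grid(0.5, 0.0, p) == 1.0


def test_conj_input_delta_hd_rate_geometry():
    """A single active HD cell shifts the input bump along its direction."""
    p = GridParams(n_side=32)
    lat = phase_lattice(p.n_side)
    x_hd = preferred_directions(8)
    z = np.array([0.13, 0.07])
    psi = phase_map(z, p.lambda_)
    j = 2                                    # only this HD cell fires
    r_h = np.zeros(8)
    r_h[j] = 1.0

    # w0 = 0: field peaks exactly at psi(z)
    p0 = p.with_(w0=0.0)
    field = conj_input(r_h, x_hd, z, 0.5, 0.0, p0, lat)
    i, k = np.unravel_index(np.argmax(field), field.shape)
    peak = np.array([lat[0][i, k], lat[1][i, k]])
    assert torus_distance(peak, psi) <= 2 * np.pi / p.n_side

    # w0 > 0: peak displaced by w0*2pi along the cell's direction
    field = conj_input(r_h, x_hd, z, 0.5, 0.0, p, lat)
    i, k = np.unravel_index(np.argmax(field), field.shape)
    peak = np.array([lat[0][i, k], lat[1][i, k]])
    expected = psi + p.w0 * 2 * np.pi * np.array([np.cos(x_hd[j]),
                                                  np.sin(x_hd[j])])
    assert torus_distance(peak, np.mod(expected, 2 * np.pi)) \
        <= 2 * 2 * np.pi / p.n_side


def test_conj_input_vanishes_when_drive_is_off():
    p = GridParams(a_input=0.0, n_side=16)
    x_hd = preferred_directions(8)
    field = conj_input(np.ones(8), x_hd, (0.0, 0.0), 0.0, 0.0, p)
    np.testing.assert_allclose(field, 0.0, atol=1e-12)   # v=0, A_g=0
    field = conj_input(np.zeros(8), x_hd, (0.0, 0.0), 0.5, 0.0, p)
    np.testing.assert_array_equal(field, 0.0)            # silent HD layer


def test_step_grid_fixed_point_and_static_tracking():
    p = GridParams(n_side=24, m=0.0, abar=0.0)
    kern_fft = np.fft.rfft2(build_torus_kernel(p))
    state = GridNetState.zeros(p)
    zero = np.zeros((p.n_side, p.n_side))
    out = step_grid(state, zero, 1e-3, p, kern_fft)
    np.testing.assert_array_equal(out.g, 0.0)

    # static centred input -> stationary bump at the input peak
    center = (np.pi, np.pi)
    inp = 5.0 * make_bump_field(center, p.b, p.n_side, "torus")
    for _ in range(1000):
        state = step_grid(state, inp, 1e-3, p, kern_fft)
    i, k = np.unravel_index(np.argmax(state.r), state.r.shape)
    lat = phase_lattice(p.n_side)
    peak = np.array([lat[0][i, k], lat[1][i, k]])
    assert torus_distance(peak, np.array(center)) <= 2 * np.pi / p.n_side


def test_coupled_run_rates_stay_finite_and_nonnegative(coupled_small):
    mod = coupled_small.modules[0]
    assert np.all(np.isfinite(mod.pop_rate))
    assert np.all(mod.pop_rate >= 0)
    assert mod.coherent.mean() > 0.9


def test_grid_params_validation():
    with pytest.raises(ValueError):
        GridParams(lambda_=0.0)
    with pytest.raises(ValueError):
        GridParams(n_side=8)
    with pytest.raises(ValueError):
        GridParams(m=-0.5)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(x=st.floats(-2, 2), y=st.floats(-2, 2))
def test_phase_map_output_range_property(x, y):
    phi = phase_map((x, y), 0.5)
    assert np.all(phi >= 0) and np.all(phi < 2 * np.pi)


def _gridness(rate_map):
    """Sixfold-symmetry score of a spatial rate map's autocorrelogram.

    Correlates the spatial autocorrelogram with itself rotated by 60
    and 120 degrees (expected high for a hexagonal pattern) versus 30,
    90 and 150 degrees (expected low); positive score = grid-like.
    """
    from scipy.ndimage import rotate

    m = np.nan_to_num(rate_map - np.nanmean(rate_map))
    ac = np.fft.fftshift(np.fft.irfft2(
        np.abs(np.fft.rfft2(m)) ** 2, s=m.shape))
    n = ac.shape[0]
    yy, xx = np.indices(ac.shape)
    rad = np.hypot(yy - n // 2, xx - n // 2)
    annulus = (rad > n * 0.08) & (rad < n * 0.45)

    def corr_at(angle):
        rot = rotate(ac, angle, reshape=False, order=1, mode="nearest")
        a, b = ac[annulus], rot[annulus]
        return np.corrcoef(a, b)[0, 1]

    return min(corr_at(60), corr_at(120)) - max(
        corr_at(30), corr_at(90), corr_at(150))


def test_single_cell_rate_map_is_hexagonal():
    """A grid cell's spatial rate map shows sixfold symmetry (smoke)."""
    from thetasweep.hd_network import HDParams, run_hd
    from thetasweep.trajectory import make_random_walk

    traj = make_random_walk(40.0, dt=1e-3, speed_stats=(0.35, 0.1),
                            turn_stats=(0.0, 3.0), arena_size=1.0,
                            seed=5)
    hd = run_hd(traj, HDParams(), warmup=0.5)
    gp = GridParams(n_side=32, lambda_=0.3)
    mod = run_grid_with_probe(traj, hd, gp)
    rates = mod.cell_rates[:, 0]

    bins = np.linspace(0, 1.0, 26)
    occ = np.histogram2d(traj.z[:, 0], traj.z[:, 1], bins=bins)[0]
    amp = np.histogram2d(traj.z[:, 0], traj.z[:, 1], bins=bins,
                         weights=rates)[0]
    with np.errstate(invalid="ignore"):
        rate_map = np.where(occ > 0, amp / np.maximum(occ, 1), np.nan)
    assert _gridness(rate_map) > 0


def run_grid_with_probe(traj, hd, gp):
    from thetasweep.grid_network import run_grid

    return run_grid(traj, hd, gp, warmup=0.5, probe_cells=[(7, 21)])
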