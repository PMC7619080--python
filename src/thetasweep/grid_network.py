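"""Grid-cell torus attractor driven by conjunctive grid x direction input.

Grid cells of one module form a continuous attractor on a twisted
torus: ``n_side x n_side`` units indexed by a phase pair
``(phi_x, phi_y)`` in [0, 2pi)^2.  Physical position maps onto the
torus through a 60-degree shear followed by a modulo over the grid
spacing ``lambda`` (hexagonal periodicity), so a single activity bump
on the torus manifests as hexagonally arranged firing fields in space.

The feedforward drive is the closed-form sum over conjunctive
grid x direction cells: each HD cell with preferred direction ``beta``
contributes a Gaussian bump of input centred at the animal's phase
position *shifted by* ``w0`` along ``beta``, weighted by that HD
cell's firing rate.  The HD internal-direction sweep therefore steers
where the grid bump is pushed, and grid-cell adaptation amplifies the
resulting location sweep.  Recurrence is evaluated as FFT circular
convolution (the kernel is translation-invariant on the torus).

Dynamics mirror the HD ring (explicit Euler):

    tau   dg/dt = -g + J * r - a + I_conj(phi; z, r_h, v, t)
    tau_a da/dt = -a + m r
    r           = g^2 / (1 + k sum g^2)
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import NumericalDivergenceError
from .hd_network import COHERENCE_THRESHOLD, HDParams, HDRun, run_hd
from .trajectory import Trajectory

__all__ = [
    "GridParams",
    "GridNetState",
    "GridModuleRun",
    "CoupledRun",
    "W_TRANS",
    "phase_map",
    "torus_distance",
    "phase_lattice",
    "build_torus_kernel",
    "kernel_convolve",
    "speed_gain",
    "theta_gain_grid",
    "conj_input",
    "step_grid",
    "run_grid",
    "run_coupled",
]

_TWO_PI = 2.0 * np.pi

#: Shear matrix projecting position onto two axes 60 degrees apart,
#: giving the hexagonal (twisted-torus) periodicity of grid fields.
W_TRANS = np.array([[1.0, -1.0 / np.sqrt(3.0)],
                    [0.0, 2.0 / np.sqrt(3.0)]])


@dataclass(frozen=True)
class GridParams:
    """Parameters of one grid module.

    ``lambda_`` is the grid spacing in metres; ``b`` and ``w0`` are in
    phase units (``w0`` as a fraction of the 2pi torus period, shifted
    input offset from the conjunctive cells).  ``t0`` and ``a_input``
    set the speed gain ``T(v) = t0 v + a_input`` of the conjunctive
    drive.  ``m`` is the adaptation strength: around 0.7 for the most
    dorsal modules and up to 1.8 for the most ventral.  Calibrated
    defaults are discussed in the methods note.
    """

    n_side: int = 48        # cells per torus dimension (headline runs: 100)
    tau: float = 0.010      # rate time constant (s)
    b: float = 0.8          # Gaussian kernel width (phase units)
    j0: float = 0.5         # recurrent connection strength
    k: float = 5e-4         # divisive global-inhibition strength
    lambda_: float = 0.4    # grid spacing (m)
    w0: float = 1.0 / 9.0   # conj phase offset (fraction of 2pi)
    t0: float = 0.06        # speed gain of conjunctive input (per m/s)
    a_input: float = 0.002  # baseline conjunctive input strength
    abar: float = 0.25      # theta-modulation speed scaling (per m/s)
    m: float = 0.7          # adaptation strength (0.7 dorsal - 1.8 ventral)
    tau_a: float = 0.100    # adaptation time constant (s)
    theta_freq: float = 7.5   # shared with the HD network (Hz)
    conn_noise_sd: float = 0.0
    conn_noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("grid spacing lambda_ must be positive")
        if self.m < 0:
            raise ValueError("adaptation strength m must be nonnegative")
        if self.n_side < 16:
            raise ValueError("need at least 16 cells per torus dimension")
        if self.tau <= 0 or self.tau_a <= 0:
            raise ValueError("time constants must be positive")

    @property
    def omega_theta(self) -> float:
        return _TWO_PI * self.theta_freq

    def with_(self, **kwargs) -> "GridParams":
        return replace(self, **kwargs)


def phase_map(z, lambda_: float) -> np.ndarray:
    """Map physical position(s) to torus phase(s) in [0, 2pi)^2.

    ``phi = 2 pi mod(W_trans z, lambda) / lambda``; the map is
    invariant under the hexagonal lattice translations
    ``z -> z + lambda (1, 0)`` and ``z -> z + lambda (1/2, sqrt(3)/2)``.
    """
    z = np.asarray(z, dtype=float)
    sheared = z @ W_TRANS.T
    phi = _TWO_PI * np.mod(sheared / lambda_, 1.0)
    # guard: mod of a tiny negative can land exactly on the period
    return np.where(phi >= _TWO_PI, 0.0, phi)


def torus_distance(phi_a, phi_b) -> np.ndarray:
    """Euclidean norm of the componentwise circular phase differences."""
    d = np.mod(np.asarray(phi_a) - np.asarray(phi_b) + np.pi, _TWO_PI) - np.pi
    return np.sqrt(np.sum(d * d, axis=-1))


def phase_lattice(n_side: int):
    """Preferred phases of the grid: two (n_side, n_side) arrays."""
    phis = _TWO_PI * np.arange(n_side) / n_side
    return np.meshgrid(phis, phis, indexing="ij")


def build_torus_kernel(params: GridParams) -> np.ndarray:
    """Circular 2D Gaussian kernel with its peak at index (0, 0).

    ``J(d) = j0/(2 pi b^2) exp(-d^2/(4 b^2))`` with ``d`` the toroidal
    distance between phase displacements; applied by circular
    convolution, never materialised as an N_g x N_g matrix.  Optional
    multiplicative jitter (seeded) perturbs the kernel weights.
    """
    n = params.n_side
    dphi = _TWO_PI * np.arange(n) / n
    dphi = np.mod(dphi + np.pi, _TWO_PI) - np.pi
    dsq = dphi[:, None] ** 2 + dphi[None, :] ** 2
    kern = params.j0 / (_TWO_PI * params.b ** 2) * np.exp(
        -dsq / (4.0 * params.b ** 2))
    if params.conn_noise_sd > 0:
        rng = np.random.default_rng(params.conn_noise_seed)
        kern = kern * (1.0 + params.conn_noise_sd
                       * rng.standard_normal(kern.shape))
    return kern


def kernel_convolve(kernel_fft: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Circular convolution of a (pre-FFT'd) kernel with a rate field."""
    return np.fft.irfft2(kernel_fft * np.fft.rfft2(field),
                         s=field.shape)


def speed_gain(v: float, params: GridParams) -> float:
    """Linear speed modulation ``T(v) = t0 v + a_input`` of the drive."""
    return params.t0 * v + params.a_input


def theta_gain_grid(v, t, params: GridParams):
    """Septal theta gain ``alpha_g = 1 + abar * v * sin(omega_theta t)``."""
    return 1.0 + params.abar * v * np.sin(params.omega_theta * np.asarray(t))


@dataclass
class GridNetState:
    """Instantaneous grid-module state on the phase lattice."""

    g: np.ndarray     # synaptic input field (n_side, n_side)
    a: np.ndarray     # adaptation field
    r: np.ndarray     # rate field (image of g)

    @classmethod
    def zeros(cls, params: GridParams) -> "GridNetState":
        z = np.zeros((params.n_side, params.n_side))
        return cls(g=z.copy(), a=z.copy(), r=z.copy())


def _divisive_field(g: np.ndarray, k: float) -> np.ndarray:
    gsq = np.square(g)
    return gsq / (1.0 + k * gsq.sum())


def conj_input(r_h: np.ndarray, x_hd: np.ndarray, z, v: float, t: float,
               params: GridParams, lattice=None) -> np.ndarray:
    """Shifted phase input from the conjunctive grid x direction cells.

    Closed-form feedforward field (the conjunctive layer is not
    simulated as dynamics): a sum over HD cells ``j`` of Gaussian
    bumps centred at ``psi(z) + w0 * 2pi * (cos x_j, sin x_j)`` on the
    torus, weighted by the HD rates, scaled by the speed gain ``T(v)``
    and the grid theta gain ``alpha_g``.
    """
    if lattice is None:
        lattice = phase_lattice(params.n_side)
    lx, ly = lattice
    psi = phase_map(np.asarray(z, dtype=float), params.lambda_)
    r_h = np.asarray(r_h, dtype=float)
    if not np.any(r_h):
        return np.zeros((params.n_side, params.n_side))
    off = params.w0 * _TWO_PI
    cx = psi[0] + off * np.cos(x_hd)          # (n_h,) bump centres
    cy = psi[1] + off * np.sin(x_hd)
    dx = np.mod(lx[None] - cx[:, None, None] + np.pi, _TWO_PI) - np.pi
    dy = np.mod(ly[None] - cy[:, None, None] + np.pi, _TWO_PI) - np.pi
    bumps = np.exp(-(dx * dx + dy * dy) / (4.0 * params.b ** 2))
    gain = theta_gain_grid(v, t, params) * speed_gain(v, params)
    return gain * np.einsum("j,jkl->kl", r_h, bumps)


def step_grid(state: GridNetState, inp: np.ndarray, dt: float,
              params: GridParams, kernel_fft: np.ndarray) -> GridNetState:
    """One explicit-Euler step of the torus-attractor dynamics."""
    if dt > params.tau / 5.0:
        raise ValueError("dt must satisfy dt <= tau/5 for stable Euler "
                         "integration")
    rec = kernel_convolve(kernel_fft, state.r)
    g = state.g + dt / params.tau * (-state.g + rec - state.a + inp)
    a = state.a + dt / params.tau_a * (-state.a + params.m * state.r)
    if not np.all(np.isfinite(g)):
        raise NumericalDivergenceError("non-finite values in state "
                                       "variable 'g'")
    if not np.all(np.isfinite(a)):
        raise NumericalDivergenceError("non-finite values in state "
                                       "variable 'a_g'")
    return GridNetState(g=g, a=a, r=_divisive_field(g, params.k))


def _field_center(field: np.ndarray, lattice):
    """Population-vector phase centre of a rate field.

    Returns ``(phi_x, phi_y, coherent)`` where ``coherent`` requires
    both circular resultants to exceed the shared threshold.
    """
    lx, ly = lattice
    total = field.sum()
    if total <= 0:
        return np.nan, np.nan, False
    vx = np.sum(field * np.exp(1j * lx))
    vy = np.sum(field * np.exp(1j * ly))
    if min(np.abs(vx), np.abs(vy)) / total < COHERENCE_THRESHOLD:
        return np.nan, np.nan, False
    return (np.mod(np.angle(vx), _TWO_PI),
            np.mod(np.angle(vy), _TWO_PI), True)


@dataclass
class GridModuleRun:
    """Recorded simulation of one grid module.

    Stores the decoded bump-centre phase trace and population rate per
    sample (the full rate-field history is too large to keep); rate
    traces of individually probed cells can be recorded on request.
    """

    t: np.ndarray                 # (T,)
    phase_center: np.ndarray      # (T, 2) torus bump centre, [0, 2pi)
    coherent: np.ndarray          # (T,) bool
    pop_rate: np.ndarray          # (T,)
    params: GridParams
    probe_cells: np.ndarray | None = None   # (p, 2) lattice indices
    cell_rates: np.ndarray | None = None    # (T, p)
    final_state: GridNetState | None = None


@dataclass
class CoupledRun:
    """HD run plus one or more grid-module runs on a shared clock."""

    traj: Trajectory
    hd: HDRun
    modules: list


def run_grid(traj: Trajectory, hd_run: HDRun, params: GridParams,
             warmup: float = 0.5, probe_cells=None,
             keep_final_state: bool = False) -> GridModuleRun:
    """Drive one grid module with recorded HD rates along a trajectory.

    Warmup mirrors :func:`thetasweep.hd_network.run_hd`: the module
    settles on the first sample's drive with theta gain frozen at 1
    before the recorded portion starts.
    """
    if warmup < 0:
        raise ValueError("warmup must be nonnegative")
    dt = traj.dt
    lattice = phase_lattice(params.n_side)
    kernel_fft = np.fft.rfft2(build_torus_kernel(params))
    state = GridNetState.zeros(params)

    frozen = params.with_(abar=0.0)
    inp0 = conj_input(hd_run.rates[0], hd_run.x, traj.z[0], traj.v[0],
                      0.0, frozen, lattice)
    for _ in range(int(round(warmup / dt))):
        state = step_grid(state, inp0, dt, params, kernel_fft)

    n_t = len(traj)
    centers = np.empty((n_t, 2))
    coherent = np.empty(n_t, dtype=bool)
    pop = np.empty(n_t)
    if probe_cells is not None:
        probe_cells = np.asarray(probe_cells, dtype=int)
        cell_rates = np.empty((n_t, probe_cells.shape[0]))
    else:
        cell_rates = None
    for i in range(n_t):
        inp = conj_input(hd_run.rates[i], hd_run.x, traj.z[i], traj.v[i],
                         traj.t[i], params, lattice)
        state = step_grid(state, inp, dt, params, kernel_fft)
        cx, cy, ok = _field_center(state.r, lattice)
        centers[i] = (cx, cy)
        coherent[i] = ok
        pop[i] = state.r.sum()
        if cell_rates is not None:
            cell_rates[i] = state.r[probe_cells[:, 0], probe_cells[:, 1]]
    return GridModuleRun(
        t=traj.t.copy(), phase_center=centers, coherent=coherent,
        pop_rate=pop, params=params, probe_cells=probe_cells,
        cell_rates=cell_rates,
        final_state=state if keep_final_state else None)


def run_coupled(traj: Trajectory, hd_params: HDParams,
                grid_params_list, warmup: float = 0.5,
                probe_cells=None) -> CoupledRun:
    """One HD simulation driving several independent grid modules.

    All modules must share the trajectory time step and the theta
    frequency of the HD network (the septal drive is the common clock).
    """
    grid_params_list = list(grid_params_list)
    for gp in grid_params_list:
        if gp.theta_freq != hd_params.theta_freq:
            raise ValueError("all modules must share the HD theta_freq")
    hd_run = run_hd(traj, hd_params, warmup=warmup)
    modules = [run_grid(traj, hd_run, gp, warmup=warmup,
                        probe_cells=probe_cells)
               for gp in grid_params_list]
    return CoupledRun(traj=traj, hd=hd_run, modules=modules)
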