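"""Head-direction (HD) ring attractor with adaptation and theta drive.

The network is a continuous attractor on the ring: ``n`` rate units with
preferred directions equally spaced over (-pi, pi], Gaussian recurrent
connectivity, divisive global inhibition, slow firing-rate adaptation
and a head-direction-tuned feedforward input whose gain oscillates at
the septal theta frequency with a depth proportional to running speed.

Dynamics (explicit Euler, step ``dt``):

    tau   dh/dt  = -h + J r - a + I(theta_hd, v, t)
    tau_a da/dt  = -a + m r
    r_j          = h_j^2 / (1 + k sum_j h_j^2)

The population-vector centre of ``r`` is the *internal direction*: with
adaptation it can leave the actual head direction, sweeping side to
side once per theta cycle (theta sweeps) or leading during turns
(anticipatory firing).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import NumericalDivergenceError, UndefinedDirectionError
from .trajectory import Trajectory, wrap_angle

__all__ = [
    "HDParams",
    "HDNetState",
    "HDRun",
    "preferred_directions",
    "ring_distance",
    "build_ring_kernel",
    "theta_gain_hd",
    "hd_input",
    "divisive_rates",
    "step_hd",
    "run_hd",
    "internal_direction",
]

#: Minimum population-vector resultant (fraction of total rate) for the
#: bump centre to count as defined; shared with the torus decoder.
COHERENCE_THRESHOLD = 0.1


@dataclass(frozen=True)
class HDParams:
    """Parameters of the HD ring attractor.

    ``tau``, ``tau_a`` are in seconds, ``b`` in radians, ``abar`` in
    1/(m/s) (theta-modulation depth per unit running speed) and
    ``theta_freq`` in Hz.  ``j0``, ``k``, ``a_input``, ``abar`` and
    ``m`` are calibrated defaults (see the methods note); the remainder
    follow standard rate-model practice.
    """

    n: int = 100            # number of HD cells on the ring
    tau: float = 0.010      # rate time constant (s)
    b: float = 0.4          # Gaussian width of kernel and input (rad)
    j0: float = 0.075       # recurrent connection strength
    k: float = 5e-4         # divisive global-inhibition strength
    a_input: float = 40.0   # baseline sensory-input strength
    abar: float = 0.25      # theta-modulation speed scaling (per m/s)
    m: float = 0.85         # adaptation strength
    tau_a: float = 0.100    # adaptation time constant (s)
    theta_freq: float = 7.5   # septal theta frequency (Hz)
    conn_noise_sd: float = 0.0   # multiplicative kernel jitter SD
    conn_noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.tau_a <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_a <= self.tau:
            raise ValueError("adaptation must be slower than the rate "
                             "dynamics (tau_a > tau)")
        if self.n < 8:
            raise ValueError("need at least 8 cells on the ring")
        if self.b <= 0:
            raise ValueError("kernel width b must be positive")

    @property
    def omega_theta(self) -> float:
        """Theta angular frequency (rad/s)."""
        return 2.0 * np.pi * self.theta_freq

    def with_(self, **kwargs) -> "HDParams":
        return replace(self, **kwargs)


@dataclass
class HDNetState:
    """Instantaneous network state: inputs, adaptation, rates."""

    h: np.ndarray     # synaptic input, length n
    a: np.ndarray     # adaptation variable, length n
    r: np.ndarray     # firing rates, length n (image of h)
    x: np.ndarray     # preferred directions, fixed over a run

    @classmethod
    def zeros(cls, params: HDParams) -> "HDNetState":
        x = preferred_directions(params.n)
        z = np.zeros(params.n)
        return cls(h=z.copy(), a=z.copy(), r=z.copy(), x=x)


def preferred_directions(n: int) -> np.ndarray:
    """``n`` equally spaced preferred directions in (-pi, pi]."""
    return wrap_angle(-np.pi + 2.0 * np.pi * (np.arange(n) + 1) / n)


def ring_distance(phi_i, phi_j):
    """Circular distance on the ring, in [0, pi]."""
    return np.abs(wrap_angle(np.asarray(phi_i) - np.asarray(phi_j)))


def build_ring_kernel(params: HDParams) -> np.ndarray:
    """Gaussian recurrent connectivity matrix J (n x n).

    ``J_ij = j0/(2 pi b^2) exp(-d(x_i, x_j)^2 / (4 b^2))`` with ``d``
    the circular distance; translation-invariant on the uniform ring.
    With ``conn_noise_sd > 0`` each weight receives i.i.d.
    multiplicative Gaussian jitter (seeded), which breaks the
    homogeneity of the connectivity.
    """
    x = preferred_directions(params.n)
    d = ring_distance(x[:, None], x[None, :])
    j = params.j0 / (2.0 * np.pi * params.b ** 2) * np.exp(
        -d ** 2 / (4.0 * params.b ** 2))
    if params.conn_noise_sd > 0:
        rng = np.random.default_rng(params.conn_noise_seed)
        j = j * (1.0 + params.conn_noise_sd * rng.standard_normal(j.shape))
    return j


def theta_gain_hd(v, t, params: HDParams):
    """Septal theta gain ``alpha_h = 1 + abar * v * sin(omega_theta t)``."""
    return 1.0 + params.abar * v * np.sin(params.omega_theta * np.asarray(t))


def hd_input(theta_hd: float, v: float, t: float,
             params: HDParams, x: np.ndarray | None = None) -> np.ndarray:
    """Head-direction-tuned sensory input with theta-modulated gain.

    ``I_i = A alpha_h exp(-d(x_i, theta_hd)^2 / (4 b^2))``, peaked at
    the cell whose preferred direction is nearest the actual HD.
    """
    if x is None:
        x = preferred_directions(params.n)
    d = ring_distance(x, theta_hd)
    gain = params.a_input * theta_gain_hd(v, t, params)
    return gain * np.exp(-d ** 2 / (4.0 * params.b ** 2))


def divisive_rates(h: np.ndarray, k: float) -> np.ndarray:
    """Divisive (global-inhibition) nonlinearity ``h^2/(1 + k sum h^2)``."""
    if k < 0:
        raise ValueError("inhibition strength k must be nonnegative")
    hsq = np.square(h)
    return hsq / (1.0 + k * hsq.sum())


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise NumericalDivergenceError(
            f"non-finite values in state variable {name!r}")


def step_hd(state: HDNetState, inp: np.ndarray, dt: float,
            params: HDParams, kernel: np.ndarray) -> HDNetState:
    """One explicit-Euler step of the ring-attractor dynamics."""
    if dt > params.tau / 5.0:
        raise ValueError("dt must satisfy dt <= tau/5 for stable Euler "
                         "integration")
    rec = kernel @ state.r
    h = state.h + dt / params.tau * (-state.h + rec - state.a + inp)
    a = state.a + dt / params.tau_a * (-state.a + params.m * state.r)
    _check_finite(h, "h")
    _check_finite(a, "a_h")
    return HDNetState(h=h, a=a, r=divisive_rates(h, params.k), x=state.x)


@dataclass
class HDRun:
    """Recorded HD-network simulation: rates at every trajectory sample."""

    t: np.ndarray          # (T,) time in s, aligned with the trajectory
    rates: np.ndarray      # (T, n) firing rates
    x: np.ndarray          # (n,) preferred directions
    params: HDParams

    def pop_rate(self) -> np.ndarray:
        """Total population rate per sample."""
        return self.rates.sum(axis=1)

    def internal_direction_trace(self):
        """Population-vector bump centre per sample.

        Returns ``(angles, coherent)``; samples with an incoherent
        bump have ``coherent=False`` and NaN angle instead of raising.
        """
        vec = self.rates @ np.exp(1j * self.x)
        total = self.rates.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = np.abs(vec) / total
        coherent = (total > 0) & (res >= COHERENCE_THRESHOLD)
        ang = np.full(self.t.shape, np.nan)
        ang[coherent] = np.angle(vec[coherent])
        return wrap_angle(ang), coherent


def run_hd(traj: Trajectory, params: HDParams,
           warmup: float = 0.5) -> HDRun:
    """Drive the ring attractor along a trajectory.

    The network starts from the zero state and is warmed up on the
    first trajectory sample for ``warmup`` seconds with the theta gain
    frozen at 1 (adaptation enabled), so a settled bump exists before
    measurement starts and no theta-phase bias is introduced.  The run
    is deterministic given its inputs.
    """
    if warmup < 0:
        raise ValueError("warmup must be nonnegative")
    dt = traj.dt
    kernel = build_ring_kernel(params)
    state = HDNetState.zeros(params)
    x = state.x

    frozen = params.with_(abar=0.0)
    inp0 = hd_input(traj.theta_hd[0], traj.v[0], 0.0, frozen, x)
    for _ in range(int(round(warmup / dt))):
        state = step_hd(state, inp0, dt, params, kernel)

    n_t = len(traj)
    rates = np.empty((n_t, params.n))
    for i in range(n_t):
        inp = hd_input(traj.theta_hd[i], traj.v[i], traj.t[i], params, x)
        state = step_hd(state, inp, dt, params, kernel)
        rates[i] = state.r
    return HDRun(t=traj.t.copy(), rates=rates, x=x, params=params)


def internal_direction(r: np.ndarray, x: np.ndarray,
                       tol: float = COHERENCE_THRESHOLD) -> float:
    """Circular population-vector mean: angle of ``sum_j r_j e^{i x_j}``.

    Raises :class:`UndefinedDirectionError` when rates are all zero or
    the resultant length is below ``tol`` times the total rate (no
    coherent bump, e.g. a uniform rate vector).
    """
    r = np.asarray(r, dtype=float)
    total = r.sum()
    if total <= 0:
        raise UndefinedDirectionError("all-zero rate vector")
    vec = np.sum(r * np.exp(1j * np.asarray(x)))
    if np.abs(vec) / total < tol:
        raise UndefinedDirectionError(
            f"population vector resultant {np.abs(vec) / total:.3g} below "
            f"coherence threshold {tol}")
    return wrap_angle(np.angle(vec))
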