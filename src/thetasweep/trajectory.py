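"""Synthetic behavioural trajectories that drive the attractor networks.

A :class:`Trajectory` is a uniformly sampled time series of 2D position,
head direction and speeds.  Generators build trajectories from per-step
increments, so the kinematic invariants (``omega`` equals the wrapped
finite difference of ``theta_hd``; ``v`` equals the step displacement
divided by ``dt``) hold exactly by construction.

Angles are radians wrapped to (-pi, pi]; positions are metres; the
mathematical convention is used throughout (counterclockwise positive),
so a clockwise head turn has negative angular speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "wrap_angle",
    "make_straight_run",
    "make_rotation",
    "make_segments",
    "make_random_walk",
]

_TWO_PI = 2.0 * np.pi


def wrap_angle(a):
    """Wrap angle(s) to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = np.pi - np.mod(np.pi - a, _TWO_PI)
    return out if out.ndim else float(out)


@dataclass
class Trajectory:
    """Uniformly sampled behavioural input stream.

    Attributes
    ----------
    t : (n,) array
        Time in seconds, strictly increasing with constant step ``dt``.
    z : (n, 2) array
        Position (x, y) in metres.
    theta_hd : (n,) array
        Head direction in radians, wrapped to (-pi, pi].
    v : (n,) array
        Linear speed in m/s (nonnegative).
    omega : (n,) array
        Signed angular head speed in rad/s.
    """

    t: np.ndarray
    z: np.ndarray
    theta_hd: np.ndarray
    v: np.ndarray
    omega: np.ndarray
    dt: float = field(init=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.theta_hd = np.asarray(self.theta_hd, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        n = self.t.size
        if not (self.z.shape == (n, 2) and self.theta_hd.size == n
                and self.v.size == n and self.omega.size == n):
            raise ValueError("all trajectory arrays must have equal length")
        if n < 2:
            raise ValueError("a trajectory needs at least two samples")
        steps = np.diff(self.t)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("t must be strictly increasing with constant dt")
        if np.any(self.v < 0):
            raise ValueError("linear speed v must be nonnegative")
        self.dt = float(steps[0])

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "x": self.z[:, 0], "y": self.z[:, 1],
            "theta_hd": self.theta_hd, "v": self.v, "omega": self.omega,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(
            t=df["t"].to_numpy(),
            z=df[["x", "y"]].to_numpy(),
            theta_hd=df["theta_hd"].to_numpy(),
            v=df["v"].to_numpy(),
            omega=df["omega"].to_numpy(),
        )

    def to_npz(self, path) -> None:
        np.savez(path, t=self.t, z=self.z, theta_hd=self.theta_hd,
                 v=self.v, omega=self.omega)

    @classmethod
    def from_npz(cls, path) -> "Trajectory":
        d = np.load(path)
        return cls(t=d["t"], z=d["z"], theta_hd=d["theta_hd"],
                   v=d["v"], omega=d["omega"])


def _check_positive(name: str, value) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value!r}")


def _from_increments(z0, theta0, speeds, dthetas, dt, t0=0.0) -> Trajectory:
    """Assemble a trajectory from per-step speed and heading increments.

    ``speeds`` and ``dthetas`` hold one entry per integration step; the
    result has ``n_steps + 1`` samples.  Step ``i`` first applies the
    heading increment, then moves along the updated heading, so ``v``
    and ``omega`` match the forward finite differences of ``z`` and
    ``theta_hd`` exactly (the final sample repeats the last increment).
    """
    speeds = np.asarray(speeds, dtype=float)
    dthetas = np.asarray(dthetas, dtype=float)
    n = speeds.size
    theta = np.empty(n + 1)
    theta[0] = wrap_angle(theta0)
    for i in range(n):  # wrapped sample-by-sample so omega stays exact
        theta[i + 1] = wrap_angle(theta[i] + dthetas[i])
    step_vec = (speeds * dt)[:, None] * np.column_stack(
        (np.cos(theta[1:]), np.sin(theta[1:])))
    z = np.vstack((np.zeros(2), np.cumsum(step_vec, axis=0))) + np.asarray(
        z0, dtype=float)
    v = np.append(speeds, speeds[-1])
    omega = np.append(dthetas, dthetas[-1]) / dt
    t = t0 + dt * np.arange(n + 1)
    return Trajectory(t=t, z=z, theta_hd=theta, v=v, omega=omega)


def make_straight_run(speed: float, heading: float, duration: float,
                      dt: float = 1e-3, start=(0.0, 0.0)) -> Trajectory:
    """Straight run at constant speed with a fixed head direction."""
    if speed < 0:
        raise ValueError("speed must be nonnegative")
    _check_positive("duration", duration)
    _check_positive("dt", dt)
    n = int(round(duration / dt))
    _check_positive("number of steps", n)
    return _from_increments(start, heading, np.full(n, float(speed)),
                            np.zeros(n), dt)


def make_rotation(angular_speed: float, initial_heading: float,
                  duration: float, dt: float = 1e-3,
                  linear_speed: float = 0.0, start=(0.0, 0.0)) -> Trajectory:
    """Constant-rate head turn, optionally while translating.

    Positive ``angular_speed`` is counterclockwise; a clockwise turn
    (to the right) therefore has ``angular_speed < 0``.
    """
    _check_positive("duration", duration)
    _check_positive("dt", dt)
    if linear_speed < 0:
        raise ValueError("linear_speed must be nonnegative")
    n = int(round(duration / dt))
    _check_positive("number of steps", n)
    return _from_increments(start, initial_heading,
                            np.full(n, float(linear_speed)),
                            np.full(n, float(angular_speed) * dt), dt)


def make_segments(segments, dt: float = 1e-3, start=(0.0, 0.0),
                  heading: float = 0.0) -> Trajectory:
    """Chain straight runs, constant-rate turns and immobile periods.

    Each segment is ``(kind, params)`` with kind one of ``"straight"``
    (params: speed, duration, optional heading), ``"turn"`` (params:
    angular_speed, duration, optional speed) or ``"still"`` (params:
    duration).  Position and head direction chain continuously: turns
    are constant-omega arcs, and a ``straight`` segment may restate the
    current heading but requesting a different one is a discontinuity
    and raises ``ValueError``.
    """
    if not segments:
        raise ValueError("segments must be nonempty")
    _check_positive("dt", dt)
    speeds, dthetas = [], []
    cur_heading = float(heading)
    start_heading = None
    for kind, params in segments:
        dur = params["duration"]
        _check_positive("duration", dur)
        n = int(round(dur / dt))
        _check_positive("number of steps", n)
        if kind == "straight":
            if "heading" in params:
                req = float(params["heading"])
                if start_heading is None:
                    cur_heading = req
                elif abs(wrap_angle(req - cur_heading)) > 1e-9:
                    raise ValueError(
                        "discontinuous heading at segment join: "
                        f"requested {req!r}, current {cur_heading!r}")
            speeds.append(np.full(n, float(params["speed"])))
            dthetas.append(np.zeros(n))
        elif kind == "turn":
            w = float(params["angular_speed"])
            speeds.append(np.full(n, float(params.get("speed", 0.0))))
            dthetas.append(np.full(n, w * dt))
            cur_heading = wrap_angle(cur_heading + w * n * dt)
        elif kind == "still":
            speeds.append(np.zeros(n))
            dthetas.append(np.zeros(n))
        else:
            raise ValueError(f"unknown segment kind {kind!r}")
        if start_heading is None:
            start_heading = cur_heading
    return _from_increments(start, start_heading,
                            np.concatenate(speeds), np.concatenate(dthetas),
                            dt)


def make_random_walk(duration: float, dt: float = 1e-3,
                     speed_stats=(0.25, 0.1), turn_stats=(0.0, 2.0),
                     arena_size: float = 1.5, seed: int = 0,
                     start=None, heading: float = 0.0) -> Trajectory:
    """Random foraging-like walk confined to a square arena.

    Speed follows a mean-reverting random walk clipped at zero
    (``speed_stats = (mean, sd)`` in m/s, reversion time scale 0.5 s);
    heading performs a random walk with angular-velocity SD
    ``turn_stats[1]`` rad/s around drift ``turn_stats[0]``.  The walk
    is confined to ``[0, arena_size]^2`` by reflective turning at the
    walls.  Deterministic given ``seed``.
    """
    _check_positive("duration", duration)
    _check_positive("dt", dt)
    if arena_size <= 0:
        raise ValueError("arena_size must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    _check_positive("number of steps", n)
    if start is None:
        start = (arena_size / 2.0, arena_size / 2.0)
    sp_mean, sp_sd = speed_stats
    turn_mean, turn_sd = turn_stats

    rev = dt / 0.5  # speed mean-reversion rate per step
    noise_s = rng.standard_normal(n)
    noise_w = rng.standard_normal(n)
    speeds = np.empty(n)
    dthetas = np.empty(n)
    s = max(float(sp_mean), 0.0)
    th = wrap_angle(heading)
    z = np.asarray(start, dtype=float).copy()
    sqrt_dt = np.sqrt(dt)
    for i in range(n):
        s += rev * (sp_mean - s) + sp_sd * np.sqrt(2.0 * rev) * noise_s[i]
        s = max(s, 0.0)
        th_new = th + turn_mean * dt + turn_sd * sqrt_dt * noise_w[i]
        # reflective turning: bounce the heading off a wall on contact
        step = s * dt
        if not 0.0 <= z[0] + step * np.cos(th_new) <= arena_size:
            th_new = np.pi - th_new
        if not 0.0 <= z[1] + step * np.sin(th_new) <= arena_size:
            th_new = -th_new
        speeds[i] = s
        dthetas[i] = wrap_angle(th_new - th)
        th = wrap_angle(th)
        th = wrap_angle(th + dthetas[i])
        z += step * np.array([np.cos(th), np.sin(th)])
    return _from_increments(start, heading, speeds, dthetas, dt)
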