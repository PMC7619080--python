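"""Small deterministic fixtures with closed-form ground truth.

These constructions let every decoder and metric be exercised without
running the full simulator: wrapped-Gaussian bump fields whose centre
is known by construction, sweep-angle sequences with hand-computable
alternation scores, and autocorrelograms generated directly from the
theta-skipping model so the fit can be checked by parameter recovery.
Everything is a pure function of its arguments (and seed).
"""

from __future__ import annotations

import numpy as np

from .hd_network import preferred_directions
from .grid_network import phase_lattice
from .spike_metrics import ACG_BIN, ACG_WINDOW, Autocorrelogram, \
    skipping_model
from .trajectory import wrap_angle

__all__ = [
    "make_bump_field",
    "make_sweep_sequence",
    "make_acg_from_model",
]

_TWO_PI = 2.0 * np.pi


def make_bump_field(center, width: float, n: int, kind: str = "ring"):
    """Wrapped Gaussian rate bump on the ring or the torus.

    ``center`` is an angle (ring) or a phase pair (torus); ``width``
    is the Gaussian SD in the same angular units.  The decoder oracle
    for the returned field is ``center`` itself.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if kind == "ring":
        x = preferred_directions(n)
        d = np.abs(wrap_angle(x - float(np.asarray(center))))
        return np.exp(-0.5 * (d / width) ** 2)
    if kind == "torus":
        cx, cy = np.asarray(center, dtype=float)
        lx, ly = phase_lattice(n)
        dx = np.mod(lx - cx + np.pi, _TWO_PI) - np.pi
        dy = np.mod(ly - cy + np.pi, _TWO_PI) - np.pi
        return np.exp(-0.5 * (dx * dx + dy * dy) / width ** 2)
    raise ValueError(f"unknown field kind {kind!r}")


def make_sweep_sequence(pattern: str, amplitude: float, n: int = 11,
                        custom=None) -> np.ndarray:
    """Deterministic sweep-angle sequences with known alternation score.

    ``"alternating"`` gives +A, -A, +A, ... (score exactly 1);
    ``"constant"`` gives A, A, ... (score exactly 0); ``"custom"``
    passes ``custom`` through (wrapped to (-pi, pi]).
    """
    if pattern == "custom":
        if custom is None:
            raise ValueError("custom pattern needs the custom= angles")
        return wrap_angle(np.asarray(custom, dtype=float))
    if n < 3:
        raise ValueError("need at least 3 sweeps")
    if pattern == "alternating":
        return amplitude * (-1.0) ** np.arange(n)
    if pattern == "constant":
        return np.full(n, float(amplitude))
    raise ValueError(f"unknown pattern {pattern!r}")


def make_acg_from_model(a1: float, a2: float, b: float, c: float,
                        omega: float, tau1: float, tau2: float,
                        noise_sd: float = 0.0,
                        seed: int = 0) -> Autocorrelogram:
    """Forward-evaluate the skipping model on the standard ACG lag grid.

    Optional additive Gaussian noise (seeded).  With ``noise_sd = 0``
    the generating parameters are the exact ground truth for
    :func:`thetasweep.spike_metrics.fit_skipping_model`.
    """
    n_bins = int(round(2 * ACG_WINDOW / ACG_BIN)) + 1
    lags = -ACG_WINDOW + ACG_BIN * np.arange(n_bins)
    values = skipping_model(lags, a1, a2, b, c, omega, tau1, tau2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + noise_sd * rng.standard_normal(values.shape)
    return Autocorrelogram(lags=lags, values=values)
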