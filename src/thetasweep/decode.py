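"""Read out internal direction and internal location from network state.

The grid bump lives on a torus, so its phase centre maps to physical
space one-to-many (every hexagonal lattice translate is a preimage).
The inverse used here anchors the first sample at the lattice preimage
nearest a known physical location (normally the animal's position at
simulation start) and then continues greedily to the nearest preimage
of each subsequent sample.  Because theta sweeps are short compared to
the grid period, this resolves the ambiguity and may legitimately
place the decoded location outside the arena.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AmbiguityError, UndefinedDirectionError
from .grid_network import W_TRANS, phase_lattice, _field_center
from .trajectory import wrap_angle

__all__ = [
    "DecodedTrack",
    "bump_center_torus",
    "phase_to_physical",
    "decode_module",
]

_TWO_PI = 2.0 * np.pi
_W_INV = np.linalg.inv(W_TRANS)


def bump_center_torus(r_g: np.ndarray, lattice=None):
    """Per-dimension circular mean of the phase lattice weighted by rates.

    ``r_g`` is an (n, n) rate field.  Raises
    :class:`UndefinedDirectionError` for an all-zero or incoherent
    field (circular resultant below the shared coherence threshold in
    either dimension).
    """
    r_g = np.asarray(r_g, dtype=float)
    if lattice is None:
        lattice = phase_lattice(r_g.shape[0])
    cx, cy, ok = _field_center(r_g, lattice)
    if not ok:
        raise UndefinedDirectionError(
            "rate field has no coherent bump centre")
    return np.array([cx, cy])


def phase_to_physical(phase_trace: np.ndarray, lambda_: float,
                      anchor_z) -> np.ndarray:
    """Invert the torus phase trace to a continuous physical path.

    The first sample is mapped to the hexagonal-lattice preimage
    nearest ``anchor_z``; later samples follow by continuous unwrapping
    (the preimage nearest the previous decoded point).  A per-step
    phase jump of half a period or more in either component is
    ambiguous and raises :class:`AmbiguityError` naming the step.
    """
    phase_trace = np.atleast_2d(np.asarray(phase_trace, dtype=float))
    anchor_z = np.asarray(anchor_z, dtype=float)
    steps = np.diff(phase_trace, axis=0)
    wrapped = np.mod(steps + np.pi, _TWO_PI) - np.pi
    bad = np.max(np.abs(wrapped), axis=1, initial=0.0) >= np.pi * (1 - 1e-12)
    if np.any(bad):
        raise AmbiguityError(
            f"phase jump of >= half a period at step {int(np.argmax(bad))}")
    unwrapped = np.vstack((phase_trace[0],
                           phase_trace[0] + np.cumsum(wrapped, axis=0)))
    # sheared coordinates in metres, still missing the lattice offset
    u = unwrapped * lambda_ / _TWO_PI
    # integer lattice offset bringing the first point nearest the anchor
    anchor_u = anchor_z @ W_TRANS.T
    k0 = np.round((anchor_u - u[0]) / lambda_)
    best, best_d = None, np.inf
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            k = k0 + (di, dj)
            z0 = (u[0] + lambda_ * k) @ _W_INV.T
            d = np.hypot(*(z0 - anchor_z))
            if d < best_d:
                best, best_d = k, d
    return (u + lambda_ * best) @ _W_INV.T


@dataclass
class DecodedTrack:
    """Joint decoded readout of the coupled simulation.

    ``internal_loc`` is continuous (sub-period steps) and may exit the
    arena; ``phase_loc`` is its image on the torus.  Samples with an
    incoherent grid or HD bump are flagged, not interpolated.
    """

    t: np.ndarray              # (T,)
    internal_dir: np.ndarray   # (T,) rad, NaN where HD bump incoherent
    internal_loc: np.ndarray   # (T, 2) metres
    phase_loc: np.ndarray      # (T, 2) [0, 2pi)
    coherent: np.ndarray       # (T,) bool: both networks coherent
    anchor: np.ndarray         # (2,) physical anchor of the inverse map

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t,
            "internal_dir": self.internal_dir,
            "loc_x": self.internal_loc[:, 0],
            "loc_y": self.internal_loc[:, 1],
            "phase_x": self.phase_loc[:, 0],
            "phase_y": self.phase_loc[:, 1],
            "coherent_flag": self.coherent.astype(int),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def decode_module(coupled, module_index: int = 0,
                  anchor_z=None) -> DecodedTrack:
    """Build a :class:`DecodedTrack` from a coupled simulation.

    ``anchor_z`` defaults to the animal's position at the first sample.
    Incoherent phase samples are carried through by holding the last
    coherent phase (flagged) so the physical unwrap stays defined.
    """
    mod = coupled.modules[module_index]
    traj = coupled.traj
    if anchor_z is None:
        anchor_z = traj.z[0]
    internal_dir, dir_ok = coupled.hd.internal_direction_trace()

    phase = mod.phase_center.copy()
    ok = mod.coherent.copy()
    # hold last coherent phase across flagged samples (kept flagged)
    last = None
    for i in range(phase.shape[0]):
        if ok[i]:
            last = phase[i]
        elif last is not None:
            phase[i] = last
    if last is None:
        raise UndefinedDirectionError("no coherent grid bump in the run")
    first_ok = int(np.argmax(ok))
    phase[:first_ok] = phase[first_ok]

    loc = phase_to_physical(phase, mod.params.lambda_, anchor_z)
    return DecodedTrack(
        t=mod.t.copy(),
        internal_dir=wrap_angle(internal_dir),
        internal_loc=loc,
        phase_loc=phase,
        coherent=ok & dir_ok,
        anchor=np.asarray(anchor_z, dtype=float),
    )
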