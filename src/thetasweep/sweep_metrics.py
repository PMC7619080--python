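"""Per-theta-cycle sweep segmentation and sweep statistics.

A *sweep* is the excursion of the decoded internal location (or
direction) away from the animal within one theta cycle.  Theta phase
is defined from the septal drive itself, ``omega_theta * t mod 2pi``,
with cycle boundaries at phase zero.  The sweep tip is the sample of
maximum displacement from the concurrent animal position within the
cycle (sweeps return toward the animal before the cycle ends, so the
end-of-cycle sample would underestimate them).

The alternation score of a sweep-angle sequence is, for each interior
triplet, ``s_i = |a_i - b_i| / (2 max(|a_i|, |b_i|))`` with
``a_i = alpha_i - alpha_{i-1}`` and ``b_i = alpha_{i+1} - alpha_i``
(plain differences of angles expressed in (-pi, pi]), averaged over
triplets.  It is 1 for perfect left-right alternation and 0 for a
constant sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .trajectory import Trajectory, wrap_angle

__all__ = [
    "SweepRecord",
    "segment_sweeps",
    "sweeps_from_run",
    "alternation_score",
    "sweep_stats",
    "records_to_frame",
]

_TWO_PI = 2.0 * np.pi

#: Cycles whose mean running speed is below this (m/s) are excluded:
#: sweeps are measured relative to the movement direction, which is
#: undefined during immobility.
MIN_SPEED = 0.02

#: |alpha| below this (rad) classifies a sweep as "forward".
FORWARD_THRESHOLD = np.deg2rad(10.0)

#: Sweeps shorter than this (m) have an undefined direction.
MIN_LENGTH = 1e-6


@dataclass
class SweepRecord:
    """One theta cycle's decoded sweep."""

    cycle_index: int
    t_tip: float              # time of maximum displacement (s)
    alpha: float              # sweep angle rel. movement dir, rad, left > 0
    length: float             # metres
    length_phase: float       # same excursion in torus phase units
    peak_dir_offset: float    # HD offset at the population-rate peak (rad)
    side: str                 # "left" | "right" | "forward"
    valid: bool


def _movement_direction(traj: Trajectory, i: int) -> float:
    """Heading of the velocity vector around sample ``i``."""
    lo = max(i - 1, 0)
    hi = min(i + 1, len(traj) - 1)
    d = traj.z[hi] - traj.z[lo]
    if np.hypot(*d) < 1e-12:
        return float(traj.theta_hd[i])
    return float(np.arctan2(d[1], d[0]))


def segment_sweeps(track, traj: Trajectory, theta_phase: np.ndarray,
                   hd_pop_rate: np.ndarray | None = None,
                   min_speed: float = MIN_SPEED) -> list:
    """Cut a decoded track into per-theta-cycle sweep records.

    ``track`` is a :class:`~thetasweep.decode.DecodedTrack` aligned
    with ``traj``; ``theta_phase`` is the septal phase per sample.
    Cycles containing flagged (incoherent) samples, immobile cycles
    and zero-length sweeps are marked invalid and excluded from
    aggregates.  ``hd_pop_rate`` locates the within-cycle HD
    population-rate peak for the direction peak offset; without it the
    sample of maximum absolute direction offset is used.
    """
    theta_phase = np.asarray(theta_phase, dtype=float)
    n = len(traj)
    if theta_phase.size != n or track.t.size != n:
        raise ValueError("track, trajectory and theta phase must align")
    cycles = np.floor(np.unwrap(theta_phase) / _TWO_PI).astype(int)
    records: list[SweepRecord] = []
    first, last = cycles.min(), cycles.max()
    if last - first < 2:
        raise ValueError("need at least 2 full theta cycles")
    for c in range(first + 1, last):   # interior (complete) cycles only
        idx = np.where(cycles == c)[0]
        if idx.size == 0:
            continue
        disp = track.internal_loc[idx] - traj.z[idx]
        norms = np.hypot(disp[:, 0], disp[:, 1])
        j_rel = int(np.argmax(norms))
        j = idx[j_rel]
        length = float(norms[j_rel])
        valid = bool(np.all(track.coherent[idx])) \
            and float(traj.v[idx].mean()) >= min_speed \
            and length >= MIN_LENGTH
        move_dir = _movement_direction(traj, j)
        alpha = wrap_angle(np.arctan2(disp[j_rel, 1], disp[j_rel, 0])
                           - move_dir) if length >= MIN_LENGTH else np.nan
        if hd_pop_rate is not None:
            jp = idx[int(np.argmax(np.asarray(hd_pop_rate)[idx]))]
        else:
            off = wrap_angle(track.internal_dir[idx] - traj.theta_hd[idx])
            off = np.where(np.isnan(off), -np.inf, np.abs(off))
            jp = idx[int(np.argmax(off))]
        peak_off = wrap_angle(track.internal_dir[jp] - traj.theta_hd[jp])
        if not np.isfinite(peak_off):
            valid = False
        if not np.isfinite(alpha):
            side = "forward"
        elif alpha > FORWARD_THRESHOLD:
            side = "left"
        elif alpha < -FORWARD_THRESHOLD:
            side = "right"
        else:
            side = "forward"
        records.append(SweepRecord(
            cycle_index=int(c), t_tip=float(track.t[j]),
            alpha=float(alpha) if np.isfinite(alpha) else np.nan,
            length=length,
            length_phase=np.nan,  # filled in by sweeps_from_run
            peak_dir_offset=float(peak_off) if np.isfinite(peak_off)
            else np.nan,
            side=side, valid=valid))
    return records


def sweeps_from_run(coupled, module_index: int = 0,
                    track=None, min_speed: float = MIN_SPEED) -> list:
    """Segment sweeps directly from a coupled simulation."""
    from .decode import decode_module

    if track is None:
        track = decode_module(coupled, module_index)
    lam = coupled.modules[module_index].params.lambda_
    omega = coupled.hd.params.omega_theta
    phase = np.mod(omega * coupled.hd.t, _TWO_PI)
    recs = segment_sweeps(track, coupled.traj, phase,
                          hd_pop_rate=coupled.hd.pop_rate(),
                          min_speed=min_speed)
    for r in recs:
        r.length_phase = r.length * _TWO_PI / lam
    return recs


def alternation_score(alphas) -> float:
    """Mean triplet alternation score of a sweep-angle sequence.

    For each interior index the score is
    ``|a - b| / (2 max(|a|, |b|))`` with ``a``, ``b`` the two
    consecutive plain differences; a degenerate triplet of three
    identical angles scores 0.  The result lies in [0, 1].

    Angles are expected in (-pi, pi] and are used as given (plain,
    non-wrapped differences); the ratio is invariant to the angular
    unit, so degree inputs give the same score.
    """
    alphas = np.asarray(alphas, dtype=float)
    if alphas.size < 3:
        raise InsufficientDataError("alternation score needs >= 3 sweeps")
    a = alphas[1:-1] - alphas[:-2]
    b = alphas[2:] - alphas[1:-1]
    denom = 2.0 * np.maximum(np.abs(a), np.abs(b))
    s = np.where(denom > 0, np.abs(a - b) / np.where(denom > 0, denom, 1.0),
                 0.0)
    return float(np.mean(s))


def sweep_stats(records) -> dict:
    """Aggregate statistics over the valid sweep records.

    Returns mean unsigned sweep angle (rad), circular variance of the
    signed angle, mean length (m), mean unsigned direction peak offset
    (rad) and the alternation score of the angle sequence.
    """
    valid = [r for r in records if r.valid]
    if len(valid) < 3:
        raise InsufficientDataError(
            f"need >= 3 valid sweep records, got {len(valid)}")
    alphas = np.array([r.alpha for r in valid])
    lengths = np.array([r.length for r in valid])
    offsets = np.array([r.peak_dir_offset for r in valid])
    return {
        "n_sweeps": len(valid),
        "mean_abs_alpha": float(np.mean(np.abs(alphas))),
        "circ_var_alpha": float(1.0 - np.abs(np.mean(np.exp(1j * alphas)))),
        "mean_length": float(np.mean(lengths)),
        "mean_abs_peak_dir_offset": float(np.mean(np.abs(offsets))),
        "alternation_score": alternation_score(alphas),
    }


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([{
        "cycle_index": r.cycle_index, "t_tip": r.t_tip, "alpha": r.alpha,
        "length": r.length, "length_phase": r.length_phase,
        "peak_dir_offset": r.peak_dir_offset, "side": r.side,
        "valid": r.valid} for r in records])
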