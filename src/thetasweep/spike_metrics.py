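"""Single-cell temporal statistics on model-generated spike trains.

Spikes are drawn from the rate model by inhomogeneous Poisson thinning
(the rate model's units are arbitrary, so a global ``rate_scale``
calibration constant converts model rate to Hz).  On the spike trains
this module computes:

* the spike-time autocorrelogram (ACG): +-500 ms, 5 ms bins,
  normalized by its peak between 50 and 250 ms and clipped at 1;
* the theta-cycle-skipping fit — a cosine at the theta frequency plus
  an interfering cosine at half that frequency under an exponential
  envelope, with a narrow Gaussian accounting for the zero-lag peak:

      y(x) = [a1 (cos(w x) + 1) + a2 (cos(w x / 2) + 1) + b]
             * exp(-|x| / tau1) + c exp(-x^2 / (2 tau2^2))

  and the theta-skipping index ``TS = (p2 - p1)/max(p1, p2)`` where
  ``p1 = y(2 pi / w)`` (one theta period) and ``p2 = y(4 pi / w)``
  (two periods), positive when the cell fires on alternate cycles;
* occupancy-normalized directional tuning curves with a
  full-width-at-half-maximum (FWHM) width estimate;
* the circular-linear correlation between spike theta phase and a
  covariate (theta phase precession).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .errors import (
    FitError,
    InsufficientDataError,
    NormalizationError,
    UndefinedValueError,
)
from .trajectory import Trajectory, wrap_angle

__all__ = [
    "SpikeTrain",
    "Autocorrelogram",
    "SkippingFit",
    "TuningCurve",
    "poisson_spikes",
    "spikes_from_hd_run",
    "autocorrelogram",
    "skipping_model",
    "fit_skipping_model",
    "theta_skipping_index",
    "tuning_curve",
    "phase_precession_corr",
    "skipping_vs_offset",
]

_TWO_PI = 2.0 * np.pi

ACG_WINDOW = 0.500      # s, lag range of the autocorrelogram
ACG_BIN = 0.005         # s, bin width (201 bins over +-window)

#: Bounds of the skipping-model parameters, in fit order
#: (a1, a2, b, c, omega, tau1, tau2).  The theta frequency is searched
#: over [10 pi, 18 pi] rad/s, i.e. the 5-9 Hz theta band.
SKIP_BOUNDS_LO = np.array([0.0, 0.0, 0.0, -1.0, 10.0 * np.pi, 1e-3, 1e-4])
SKIP_BOUNDS_HI = np.array([1.0, 1.0, 1.0, 1.0, 18.0 * np.pi, 5.0, 5e-3])


@dataclass
class SpikeTrain:
    """Sorted spike times with covariates sampled at spike times."""

    times: np.ndarray               # (n,) s, nondecreasing
    cell_id: int = 0
    theta_phase: np.ndarray | None = None   # (n,) rad at spike times
    hd: np.ndarray | None = None            # (n,) rad at spike times

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be nondecreasing")

    def __len__(self) -> int:
        return self.times.size


def poisson_spikes(rates: np.ndarray, dt: float, seed: int,
                   t0: float = 0.0) -> np.ndarray:
    """Inhomogeneous Poisson thinning of a rate series (Hz) per bin.

    Each time bin emits at most one spike (at the bin time) with
    probability ``rate * dt``; reproducible given ``seed``.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    p = rates * dt
    if np.any(p > 1):
        raise ValueError("rate * dt exceeds 1; reduce dt or the rate scale")
    rng = np.random.default_rng(seed)
    hits = rng.random(rates.size) < p
    return t0 + dt * np.flatnonzero(hits)


def spikes_from_hd_run(run, traj: Trajectory, cells, rate_scale: float,
                       seed: int = 0) -> list:
    """Generate spike trains for selected HD cells of a recorded run.

    ``rate_scale`` converts model rate units to Hz (global calibration
    constant).  Theta phase (``omega_theta t mod 2pi``) and head
    direction are attached at spike times.  Cell ``i`` uses child seed
    ``seed + i`` so trains are independent but reproducible.
    """
    trains = []
    phase = np.mod(run.params.omega_theta * run.t, _TWO_PI)
    for i in np.atleast_1d(cells):
        times = poisson_spikes(rate_scale * run.rates[:, i], traj.dt,
                               seed=seed + int(i), t0=run.t[0])
        idx = np.clip(np.searchsorted(run.t, times), 0, run.t.size - 1)
        trains.append(SpikeTrain(times=times, cell_id=int(i),
                                 theta_phase=phase[idx],
                                 hd=traj.theta_hd[idx]))
    return trains


def save_spike_trains(trains, path) -> None:
    """Write spike trains as a two-column CSV (t, cell_id)."""
    import pandas as pd

    rows = [(t, train.cell_id) for train in trains for t in train.times]
    pd.DataFrame(rows, columns=["t", "cell_id"]).to_csv(path, index=False)


def load_spike_trains(path) -> list:
    """Read spike trains written by :func:`save_spike_trains`."""
    import pandas as pd

    df = pd.read_csv(path)
    return [SpikeTrain(times=np.sort(g["t"].to_numpy()),
                       cell_id=int(cid))
            for cid, g in df.groupby("cell_id")]


@dataclass
class Autocorrelogram:
    """Normalized spike-time autocorrelogram on a fixed lag grid."""

    lags: np.ndarray     # (201,) bin centres in s, -0.5 .. 0.5
    values: np.ndarray   # (201,) normalized counts, clipped to <= 1


def autocorrelogram(train) -> Autocorrelogram:
    """Spike-time ACG over +-500 ms in 5 ms bins.

    Counts all ordered spike pairs (zero-lag self-pairs excluded),
    normalizes by the peak bin between 50 and 250 ms lag, then clips
    values above 1 (the zero-lag bin).  Symmetric by construction.
    """
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(
        train, dtype=float)
    if times.size < 2:
        raise InsufficientDataError("autocorrelogram needs >= 2 spikes")
    n_bins = int(round(2 * ACG_WINDOW / ACG_BIN)) + 1          # 201
    edges = -ACG_WINDOW - ACG_BIN / 2 + ACG_BIN * np.arange(n_bins + 1)
    lags = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(n_bins)
    # positive-lag pairs via a sliding window on the sorted train
    hi = np.searchsorted(times, times + edges[-1], side="right")
    for i in range(times.size):
        d = times[i + 1:hi[i]] - times[i]
        if d.size:
            counts += np.histogram(d, bins=edges)[0]
    # mirror: ACG(-tau) = ACG(tau); zero-lag pairs counted both ways
    counts = counts + counts[::-1]
    centers = np.abs(lags)
    ref = (centers >= 0.050) & (centers <= 0.250)
    peak = counts[ref].max()
    if peak <= 0:
        raise NormalizationError(
            "no spike pairs in the 50-250 ms normalization window")
    values = np.minimum(counts / peak, 1.0)
    return Autocorrelogram(lags=lags, values=values)


def skipping_model(x, a1, a2, b, c, omega, tau1, tau2):
    """Theta-skipping ACG model: dual cosine under exponential decay."""
    x = np.asarray(x, dtype=float)
    env = (a1 * (np.cos(omega * x) + 1.0)
           + a2 * (np.cos(0.5 * omega * x) + 1.0) + b)
    return env * np.exp(-np.abs(x) / tau1) + c * np.exp(
        -x * x / (2.0 * tau2 ** 2))


@dataclass
class SkippingFit:
    """Fitted skipping-model parameters and the derived TS index."""

    a1: float
    a2: float
    b: float
    c: float
    omega: float
    tau1: float
    tau2: float
    p1: float
    p2: float
    ts: float
    fit_rss: float


def fit_skipping_model(acg: Autocorrelogram) -> SkippingFit:
    """Bounded least-squares fit of the skipping model to an ACG.

    Deterministic multi-start (8 theta-frequency starts x 2 amplitude
    configurations, best residual kept) avoids the local minima of the
    dual-cosine model.  ``p1``/``p2`` are the model values at one and
    two theta periods; ``ts`` their normalized difference.
    """
    x, y = acg.lags, acg.values
    starts = []
    for om in np.linspace(10.5 * np.pi, 17.5 * np.pi, 8):
        for a1, a2 in ((0.5, 0.05), (0.05, 0.5)):
            starts.append([a1, a2, 0.1, 0.5, om, 0.5, 2e-3])
    best = None
    best_rss = np.inf
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    skipping_model, x, y, p0=p0,
                    bounds=(SKIP_BOUNDS_LO, SKIP_BOUNDS_HI),
                    maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((skipping_model(x, *popt) - y) ** 2))
        if rss < best_rss:
            best, best_rss = popt, rss
    if best is None:
        raise FitError("skipping-model fit failed at every start point")
    a1, a2, b, c, omega, tau1, tau2 = best
    p1 = float(skipping_model(2.0 * np.pi / omega, *best))
    p2 = float(skipping_model(4.0 * np.pi / omega, *best))
    return SkippingFit(a1=a1, a2=a2, b=b, c=c, omega=omega, tau1=tau1,
                       tau2=tau2, p1=p1, p2=p2,
                       ts=theta_skipping_index(p1, p2), fit_rss=best_rss)


def theta_skipping_index(p1: float, p2: float) -> float:
    """``TS = (p2 - p1) / max(p1, p2)``, in [-1, 1].

    ``p1`` and ``p2`` are the ACG-model values at one and two theta
    periods; TS > 0 means the two-period peak dominates (the cell
    skips alternate theta cycles).
    """
    if max(p1, p2) <= 0:
        raise UndefinedValueError("TS undefined for p1 = p2 = 0")
    return float((p2 - p1) / max(p1, p2))


@dataclass
class TuningCurve:
    """Occupancy-normalized directional tuning curve."""

    bin_centers: np.ndarray   # (n_bins,) rad in (-pi, pi]
    rate: np.ndarray          # raw rate per bin (Hz), NaN if unoccupied
    smoothed: np.ndarray      # circularly smoothed rate
    width_deg: float          # FWHM in degrees; NaN if undefined


def _circular_smooth(values: np.ndarray, bin_width: float,
                     sd: float) -> np.ndarray:
    """Smooth a circular signal with a wrapped Gaussian kernel."""
    n = values.size
    offs = (np.arange(n) + n // 2) % n - n // 2
    kern = np.exp(-0.5 * (offs * bin_width / sd) ** 2)
    kern /= kern.sum()
    # NaN-aware circular convolution
    filled = np.where(np.isnan(values), 0.0, values)
    mask = (~np.isnan(values)).astype(float)
    num = np.real(np.fft.ifft(np.fft.fft(filled) * np.fft.fft(kern)))
    den = np.real(np.fft.ifft(np.fft.fft(mask) * np.fft.fft(kern)))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _fwhm_deg(smoothed: np.ndarray, bin_width: float) -> float:
    """Full width at half maximum of a circular curve, in degrees."""
    n = smoothed.size
    if not np.all(np.isfinite(smoothed)):
        return np.nan
    peak = int(np.argmax(smoothed))
    half = smoothed[peak] / 2.0
    if smoothed[peak] <= 0 or np.min(smoothed) > half:
        return np.nan   # flat or nowhere below half max

    def _walk(direction: int) -> float:
        prev = smoothed[peak]
        for step in range(1, n):
            cur = smoothed[(peak + direction * step) % n]
            if cur < half:
                frac = (prev - half) / (prev - cur)
                return step - 1 + frac
            prev = cur
        return np.nan

    right, left = _walk(+1), _walk(-1)
    if np.isnan(right) or np.isnan(left):
        return np.nan
    return float(np.rad2deg((right + left) * bin_width))


def tuning_curve(train: SpikeTrain, traj: Trajectory, n_bins: int = 60,
                 smooth_sd_deg: float = 10.0) -> TuningCurve:
    """Directional tuning curve and FWHM width of one spike train.

    Occupancy (time per 6-degree head-direction bin by default) is
    computed from the trajectory; spike counts use the head direction
    attached to the train (or looked up at spike times).  Unoccupied
    bins are masked with a warning.  The curve is smoothed with a
    wrapped Gaussian (SD ``smooth_sd_deg``) before the FWHM estimate.
    """
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occ = np.histogram(wrap_angle(traj.theta_hd), bins=edges)[0] * traj.dt
    if train.hd is not None:
        spike_hd = train.hd
    else:
        idx = np.clip(np.searchsorted(traj.t, train.times), 0,
                      len(traj) - 1)
        spike_hd = traj.theta_hd[idx]
    counts = np.histogram(wrap_angle(spike_hd), bins=edges)[0]
    empty = occ <= 0
    if np.any(empty):
        warnings.warn(f"{int(empty.sum())} direction bins unoccupied; "
                      "masked", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(empty, np.nan, counts / np.where(empty, 1.0, occ))
    bin_width = _TWO_PI / n_bins
    smoothed = _circular_smooth(rate, bin_width, np.deg2rad(smooth_sd_deg))
    return TuningCurve(bin_centers=centers, rate=rate, smoothed=smoothed,
                       width_deg=_fwhm_deg(smoothed, bin_width))


def phase_precession_corr(phases, covariate, slope_bounds=(-3.0, 3.0)):
    """Circular-linear correlation of spike theta phase vs a covariate.

    Fits the slope ``a`` (cycles per covariate unit) maximizing the
    resultant of ``phases - 2 pi a x``, then returns the magnitude of
    the circular-circular correlation between the phases and the
    fitted linear phase, together with the signed slope:
    ``(rho in [0, 1], slope)``.
    """
    phases = np.asarray(phases, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if phases.size < 10:
        raise InsufficientDataError("phase precession needs >= 10 spikes")
    if np.ptp(x) <= 0:
        raise ValueError("degenerate covariate (zero range)")

    def neg_resultant(a: float) -> float:
        return -np.abs(np.mean(np.exp(1j * (phases - _TWO_PI * a * x))))

    grid = np.linspace(slope_bounds[0], slope_bounds[1], 512)
    a0 = grid[int(np.argmin([neg_resultant(a) for a in grid]))]
    span = (slope_bounds[1] - slope_bounds[0]) / 511
    res = minimize_scalar(neg_resultant,
                          bounds=(a0 - 2 * span, a0 + 2 * span),
                          method="bounded")
    slope = float(res.x)

    fitted = np.mod(_TWO_PI * slope * x, _TWO_PI)
    pm = np.angle(np.mean(np.exp(1j * phases)))
    fm = np.angle(np.mean(np.exp(1j * fitted)))
    sp, sf = np.sin(phases - pm), np.sin(fitted - fm)
    denom = np.sqrt(np.sum(sp ** 2) * np.sum(sf ** 2))
    if denom <= 0:
        return 0.0, slope
    rho = float(np.abs(np.sum(sp * sf) / denom))
    return rho, slope


def skipping_vs_offset(trains, traj: Trajectory, preferred_dirs,
                       n_bins: int = 6, min_spikes: int = 100):
    """Theta-skipping index as a function of |HD - preferred direction|.

    For a fixed-HD simulation, each cell's offset is the circular
    distance between its preferred direction and the (constant) head
    direction.  Returns ``(bin_centers, ts_mean, counts)`` over offset
    bins in [0, pi]; bins whose cells have too few spikes are masked
    (NaN).
    """
    preferred_dirs = np.asarray(preferred_dirs, dtype=float)
    hd0 = float(traj.theta_hd[0])
    offsets = np.abs(wrap_angle(preferred_dirs - hd0))
    edges = np.linspace(0.0, np.pi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ts_sum = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for train, off in zip(trains, offsets):
        if len(train) < min_spikes:
            continue
        try:
            fit = fit_skipping_model(autocorrelogram(train))
        except (InsufficientDataError, NormalizationError, FitError):
            continue
        b = min(int(np.searchsorted(edges, off, side="right")) - 1,
                n_bins - 1)
        ts_sum[b] += fit.ts
        counts[b] += 1
    with np.errstate(invalid="ignore"):
        ts_mean = np.where(counts > 0, ts_sum / np.maximum(counts, 1),
                           np.nan)
    return centers, ts_mean, counts
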