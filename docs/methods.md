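# Model and methods

## The model

`thetasweep` simulates two coupled continuous attractor networks
(CANs) with firing-rate adaptation and a speed-scaled septal theta
drive.

**Head-direction (HD) ring.** `n = 100` rate units with preferred
directions `x_i` equally spaced on the circle evolve as

    tau   dh/dt = -h + J r - a + I(theta_hd, v, t)
    tau_a da/dt = -a + m_h r
    r_j         = h_j^2 / (1 + k sum_j h_j^2)

with Gaussian recurrent weights
`J_ij = j0/(2 pi b^2) exp(-d(x_i,x_j)^2 / (4 b^2))` (`d` = circular
distance), divisive global inhibition, and an HD-tuned input
`I_i = A [1 + abar_h v sin(omega_theta t)] exp(-d(x_i,theta)^2/(4 b^2))`.
The population-vector angle of `r` is the *internal direction*.

**Grid-cell torus.** One module is an `n_side x n_side` sheet of
units indexed by a phase pair on `[0, 2pi)^2` with the same dynamics,
a translation-invariant torus kernel applied by FFT circular
convolution, and a feedforward drive standing in for conjunctive
grid x direction cells: a sum over HD cells of Gaussian bumps centred
at `psi(z) + w0 * 2pi * (cos x_j, sin x_j)`, weighted by the HD rates
and scaled by `T(v) = t0 v + a_g` and the grid theta gain.  Physical
position enters through the hexagonal phase map
`psi(z) = 2 pi mod(W z, lambda)/lambda` with the 60-degree shear
`W = [[1, -1/sqrt(3)], [0, 2/sqrt(3)]]`; the decoded phase is mapped
back to physical space by anchoring the first sample at the lattice
preimage nearest the animal and continuing to the nearest preimage
thereafter (sweeps are sub-period, so this greedy continuation is
exact).

Integration is explicit Euler at `dt = 1 ms` (time constants are
10 ms; a step-halving check in the test suite bounds the
discretization error of the bump-centre trace below 1% of a cycle).
Runs begin with a 0.5 s warmup on the first trajectory sample with
the theta gain frozen at 1, so a settled bump exists at t = 0 with no
theta-phase bias.  Theta phase is defined as `omega_theta t mod 2pi`
— the septal drive is the model's clock.

## How the sweeps arise

With the sensory input pinning the bump and adaptation pushing it
away, the pinned state has a damped *position* mode: displacing the
bump and releasing it produces a decaying oscillation around the
input peak.  At the calibrated operating point this mode sits near
3.7 Hz and just above its instability threshold.  The theta gain
oscillation at 7.5 Hz modulates the pinning strength at twice the
mode frequency and therefore entrains it subharmonically
(period-doubling): the bump swings left of the head axis on one theta
cycle and right on the next, giving left-right alternation with
alternation score near 1 on a fast straight run.  During head turns
the adaptation asymmetry instead pushes the bump ahead of the actual
HD (anticipatory firing), linearly in angular speed over the tested
range.

The grid bump inherits the alternation: the conjunctive drive is
centred ahead of the animal's phase position *along the internal
direction*, so the HD sweep steers it left and right while grid-cell
adaptation lets the bump overshoot the drive's centre, making the
location sweep angle exceed the direction sweep angle at every tested
grid adaptation strength.

## Parameters

Printed constants are used as printed: `n = 100` HD cells,
`n_side^2` grid cells per module (headline resolution 100^2, default
48^2 here — see below), `tau = 10 ms`, `tau_a = 100 ms`, `b_h = 0.4`
rad, `b_g = 0.8` phase units, `w0 = 1/9` of the torus period, grid
adaptation between 0.7 (dorsal) and 1.8 (ventral).  Exponent signs in
the Gaussian kernels/inputs are negative throughout, and the phase
map divides by `lambda` before scaling to phase units, so that the
map is dimensionless and `lambda`-periodic.

The remaining strengths are not printed anywhere and were calibrated
once, jointly, so that the model reproduces its headline statistics
(direction peak offset ~17 deg with alternation ~1; location sweep
angle ~24.6 deg; tuning widths near 115/116/121 deg):

| parameter | HD ring | grid module | note |
|---|---|---|---|
| `j0` recurrent strength     | 0.075 | 0.06  | self-sustained bump, input a small fraction of drive |
| `k` divisive inhibition     | 5e-4  | 2e-4  | sets rate scale and saturation |
| input strength              | `A = 40` | `T(v) = t0 v + a_g` | grid values in the config defaults |
| theta scaling `abar` (1/(m/s)) | 0.25 | see defaults | modulation depth `abar*v` stays below 1 |
| adaptation `m`              | 0.85  | 0.7-1.8 | HD value just above the position-mode instability |
| theta frequency             | 7.5 Hz | shared | see below |

Theta defaults to 7.5 Hz rather than the nominal 10 Hz often quoted
for rodent theta: the theta-skipping autocorrelogram model is fitted
with its frequency bounded to 5-9 Hz, so the simulated rhythm must
itself lie in that band to be fittable, and 7.5 Hz additionally sits
at twice the bump position-mode frequency, which is what locks the
left-right alternation.  All parameters are overridable through
`RunConfig` / the CLI.

Grid modules default to a geometric series of spacings (0.40, 0.56,
0.78, 1.10 m) paired with linearly increasing adaptation strength —
the dorsal-to-ventral arrangement.  Sweep length in metres is then
proportional to spacing (the phase-space excursion is nearly
module-invariant).

## Measurement conventions

* **Sweep segmentation.** One record per theta cycle; the sweep tip
  is the sample of maximum displacement of the decoded location from
  the concurrent animal position (sweeps return within the cycle, so
  the cycle-end sample would underestimate them); the sweep angle is
  measured against the heading of the velocity; cycles with mean
  speed below 2 cm/s or any incoherent decoded sample are excluded.
  The direction peak offset is the internal-direction offset at the
  within-cycle maximum of the HD population rate.
* **Alternation score.** For each interior triplet of sweep angles,
  `|a - b| / (2 max(|a|, |b|))` with `a`, `b` the consecutive plain
  differences; degenerate triplets score 0; the run's score is the
  triplet mean.
* **Spikes.** Inhomogeneous Poisson thinning per 1 ms bin with a
  global rate scale of 0.6 Hz per model rate unit (model rates are in
  arbitrary units; 0.6 puts peak rates near 60 Hz).
* **Autocorrelogram and skipping.** +-500 ms, 5 ms bins, normalized
  by the 50-250 ms peak and clipped at 1.  The dual-cosine fit uses
  deterministic multi-start (8 frequency starts x 2 amplitude
  configurations) bounded least squares; `TS = (p2 - p1)/max(p1,p2)`
  with `p1`, `p2` the model values at one and two theta periods.
* **Tuning width.** Occupancy-normalized rate in 6-degree HD bins,
  wrapped-Gaussian smoothing with 10-degree SD, width = full width at
  half maximum.  FWHM was chosen because the width estimator used for
  the reference values is not published; widths therefore depend on
  the (fixed) smoothing bandwidth, roughly +1 degree per degree of
  SD near the default.
* **Width protocol.** The three cell classes (classic = adaptation
  only; non-skipping = theta only; skipping = both) are measured on
  foraging-like random walks whose heading diffuses with
  angular-velocity SD 6.5 rad/s at mean speed 0.25 m/s; each regime
  averages 20 probed cells over three independent 40 s walks (a
  single walk leaves several degrees of trajectory-level noise in the
  mean width).
  Under vigorous turning the finite tracking speed of the bump smears
  the spike-triggered head-direction distribution, which is what
  brings the widths from the static bump's ~76 deg up to the
  ~115-120 deg range.
* **Circular-linear (phase precession) correlation.** Slope fitted by
  maximizing the resultant of `phase - 2 pi a x` over a bounded slope
  range, then the magnitude of the circular-circular correlation
  between the phases and the fitted linear phase is reported with the
  signed slope.

## Problem sizes

Default torus resolution is 48 x 48 (the conjunctive-input evaluation
dominates run time, scaling with `n_h * n_side^2` per step); the
trend checks in the test suite run at 32 x 32, where all qualitative
results are unchanged; 100 x 100 reproduces the same statistics and
is the resolution the headline cell counts refer to.  Straight-run
statistics discard the first 2 s while the period-doubled sweep cycle
locks in.

## Synthetic data vs real data

The trajectory generator produces constant-speed straight runs,
constant-rate turns, chained segments and a reflective random walk.
It does not emulate real rodent kinematics (speed-heading coupling,
wall-following, grooming pauses), real tracking noise, or real spike
trains' non-Poisson features (refractoriness, bursting).  Passing
tests therefore show that the *model* has the claimed dynamics under
clean conditions, not that the pipeline is robust to the artefacts of
recorded data.  The spike metrics (ACG, skipping fit, tuning width,
precession) accept any `SpikeTrain`, so externally recorded spike
times with HD tracking can be analysed, but no loader for any
specific acquisition format is provided.

## Numerical choices and degenerate inputs

Divisive normalization makes all rates nonnegative and bounds the
population rate by `~1/k`.  Bump centres are population-vector means;
a resultant below 0.1 of the total rate is flagged incoherent (the
sample is excluded from sweep aggregates, never interpolated).  The
torus-to-physical inverse raises an error if the phase trace jumps by
half a period in one step.  Degenerate alternation triplets (three
equal angles) score 0 by definition.  Connection-noise experiments
jitter the HD weight matrix elementwise; for the grid network the
jitter is applied to the shared circular kernel (an elementwise
`N_g x N_g` jitter is incompatible with the FFT evaluation), i.e. it
perturbs the interaction profile identically for all cells rather
than breaking translation invariance per synapse.

## Known limitations

* Sweep length *decreases* mildly with running speed in this
  implementation (about -15% from 0.2 to 0.8 m/s), where the
  reference phenomenology has it increasing.  The decoded grid bump
  tracks the conjunctive drive with a lag proportional to running
  speed, and across every drive parameterization explored
  (speed-dominant, baseline-dominant and drive-limited conjunctive
  gain; shallow and deep grid theta modulation) that lag growth
  exceeds the speed-driven growth of the within-cycle excursion.  The
  corresponding trend test asserts the increasing direction and
  fails; the other speed trend (alternation score rising with speed)
  and the spacing-proportionality of sweep length are reproduced.
* The tuning-width *ordering* observed in the reference data
  (skipping broader than both non-sweeping classes, which are
  equal) is not reproduced, although the three values themselves fall
  in the expected range.  In this implementation adaptation
  accelerates tracking (anticipative compensation of the bump's
  tracking lag), which *narrows* tuning under vigorous turning, and
  at the calibrated theta depth this narrowing is larger than the
  extra broadening the theta sweeps contribute; the no-adaptation
  (non-skipping) class therefore comes out broadest.  The effect is
  documented rather than hidden: the corresponding test asserts the
  expected ordering and fails.
* Theta phase precession against turning angle is present but weak
  for model skipping cells (significant against a shuffle null only
  with a permissive slope range); its slope sign is
  convention-dependent and is not asserted.
* Theta frequency is constant; real theta frequency shifts with
  running speed.
* The conjunctive cell layer is a closed-form drive, not a simulated
  population, so no conjunctive spike statistics are available.
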