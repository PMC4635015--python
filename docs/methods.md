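# Methods

## The behavioral model

The agent is a point with position (x, y) and a compass bearing θ
(0 = +y, clockwise positive) inside a rigid 2-D arena. Time advances in
ticks of dt = 0.1 s; each tick the agent moves speed·dt = 1 sim-unit
along its bearing. The spatial scale is fixed at 14/3 sim-units per mm,
the unique scale consistent with all of the modelled containers
(30×60 mm rectangle ↔ 140×280 units; 90-mm dish ↔ radius 210; donut
30/45 mm ↔ 140/210; 60-mm dish ↔ 140; the 200-mm dish is modelled at
the same scale, radius 466.67).

Two stochastic elements drive everything:

- **Wigwag angle** ξ ~ Normal(angle_mean, angle_sd), radians. Applied
  instantaneously to the bearing when a wigwag fires.
- **Wigwag interval** k ~ LogNormal(interval_logmean, interval_logsd),
  seconds, with the location and scale in log space (so the median
  interval is exp(interval_logmean)). The alternative convention — the
  stated location being the median itself — was rejected because it
  would give headless animals *shorter* pauses than intact ones,
  contradicting their observed behavior.

Both draws are rounded to two decimals, reproducing the original
procedure; the effect is negligible against the distribution scales.

Intervals are realized by an integer countdown i: a tick with i ≠ 0
decrements it; a tick with i = 0 applies ξ and resets i to
max(1, round(10·k)). The max(1, ·) floor makes the countdown well
defined when 10·k rounds to 0 (sub-0.1-s intervals cannot be
represented on the tick grid). Because the i = 0 tick itself both turns
and moves, two successive wigwags are i+1 ticks apart; intervals
recovered from trajectories therefore carry a constant +0.1 s offset
relative to the sampled k. This is a property of the countdown rule,
not of the extraction.

### Wall contact

If the proposed move leaves the arena, the position is clamped to the
nearest point on the wall and the bearing is set to the wall tangent
direction (for circles, the tangent of the circle at the clamped
point) whose angular difference from the incoming bearing is smaller —
full realignment, preserving the along-wall sign of the motion. The
observed behavior this encodes: animals reaching a wall continue along
it regardless of incidence angle. Exact ties (perfectly head-on
incidence) are broken by the simulation's random stream. At a
rectangle corner the realignment edge is the one angularly closer to
the incoming bearing, with the same tie rule. A partial "relaxation
toward the tangent" variant would be an alternative reading of the
collision rule; full alignment is adopted because the resulting
reflection angles are tangential at every incidence, which is what the
tracked animals show.

A clamped agent sits exactly on the boundary (to ≤ 1e-9 sim-units);
arena membership tests carry the same tolerance so a sliding agent is
never classified outside.

### Initial conditions

Starts are at the arena center — (175, 0) for the donut, between the
walls — with a bearing uniform on [0, 2π) and an initial countdown
drawn from the interval distribution (neither is specified by the
original procedure; both choices avoid privileging any direction or
phase). All randomness flows from one numpy Generator, so identical
(parameters, arena, seed) reproduce trajectories bit-exactly.

### What the simulator deliberately omits

No quiescence/stopping (real animals stop after ~10 min; assays here
are ≤ 600–1200 s of continuous motion), no speed variation between
wall and center (none was observed), no sensory responses, and no
biomechanics — the model is exactly the two spontaneous behaviors.

## Group presets

| group | ξ mean ± SD (rad) | k log-loc, log-scale | n angles / animals |
|---|---|---|---|
| intact | −0.01 ± 0.34 | 0.14, 0.48 | 196 / 15 |
| head_fragment | −0.07 ± 0.36 | 0.45, 0.40 | 69 / 11 |
| headless | 0.01 ± 0.32 | 1.0, 0.59 | 101 / 14 |

These are the measured wigwag statistics of the three experimental
groups and are the synthetic-data generator's defaults.

## Regions and dwell accounting

The wall region is the band within 5 mm of the wall; the central region
is the concentric similar figure scaled to the same area (for the
30×60 mm rectangle: a 20×40 mm rectangle; for a dish of radius R with
margin m: a disk of radius √(R² − (R−m)²)). The donut is split at
r = √((r_in² + r_out²)/2) into equal-area convex (inner-wall) and
concave (outer-wall) halves. Membership is closed on the wall side of
the band boundary and closed on the central figure, so a wall-sliding
agent always counts as in the wall region.

Dwell times are computed by sample counting at the 0.1-s grid (no
sub-tick interpolation): T_region = (samples in region)·dt and
T = n_samples·dt. Under this convention the zero-wigwag agent in the
90-mm dish — which runs straight from the center and reaches the band
at t = 18.7 s, then never leaves — scores a wall index of 5814/6001 =
0.96884, within 6·10⁻⁶ of the idealized closed form 1 − 18.7/600.

Wall episodes open at the first sample inside the band and close at the
first sample back outside (dwell = t_detach − t_contact); an episode
still running at assay end is reported open with the remaining time as
its dwell and is included in mean-dwell summaries, since animals often
end the assay at the wall. "Detachment" is defined as leaving the 5-mm
band (the original criterion is unstated; a band exit is the only
definition expressible from positions alone).

Incidence and reflection angles are measured from the headings one tick
before and one tick after the contact tick, against the wall tangent
nearest the incoming heading (the measurement window of the original
analysis is unstated; one tick is the finest available).

## Wigwag extraction and fitting

`extract_wigwag` differentiates positions into per-tick bearings and
flags any tick whose bearing change exceeds 0.005 rad (half the 0.01
rounding quantum) as a turn event. On noise-free simulated open-field
tracks this reproduces the simulator's event log exactly, except that
wigwags whose angle rounds to 0.00 rad (≈1.2% of draws at SD 0.34) are
invisible in the positions; their intervals merge into the neighboring
events'. The resulting upward bias on a fitted angle SD is ≈0.6%, an
order of magnitude below the sampling error at the event counts
involved (a few hundred per 600-s track).

Fits are maximum likelihood proper: normal location = sample mean,
scale = 1/n standard deviation; lognormal parameters are the normal
MLE of the log sample. Standard errors are σ̂/√n for the location and
σ̂/√(2n) for the scale.

## Occupancy KDE

The occupancy map is an isotropic bivariate Gaussian KDE evaluated on
1-mm cells, masked to the arena and renormalized to unit mass. The
bandwidth minimizes the least-squares cross-validation score (closed
form for Gaussian kernels) by bounded golden-section search on log h
over ±1 decade around the 2-D Scott pilot σ̂·n^(−1/6); when no interior
minimum exists the pilot is used and a warning issued. Heavily
autocorrelated inputs — e.g. a single trajectory sampled at 0.1 s,
which is effectively a curve of near-duplicate points — routinely have
no interior LSCV minimum; this is expected, not an error. Pairwise
sums use an order-invariant deterministic subsample of at most 1500
points, so the map does not depend on trajectory ordering.

## Test and acceptance problem sizes

Ensemble checks of the qualitative laws (wall index decreasing in
angle SD over {0.1, 0.3, 1.0, 3.0} rad; increasing in interval
log-location over {ln 0.1, 0.14, ln 10}; donut concave > convex; 60-mm
dish > 200-mm dish) use 50 replicates of 600-s runs per condition —
enough that the ensemble means are separated by many standard errors.
Interval locations below ~0.1 s are not separable at the 0.1-s tick
(the countdown floors at one tick), which is why the low end of the
interval grid is 0.1 s. Parameter-recovery checks pool 8 replicate
seeds and require the pooled estimate within 3 standard errors at the
pooled sample size.

## What passing on synthetic data does and does not show

The generator emulates tracked trajectories of the model itself (plus
optional isotropic per-frame Gaussian tracking jitter), so recovery
tests validate the pipeline's internal consistency: geometry, dwell
accounting, event extraction, and fitting are mutually correct, and
the emergent wall preference follows from the modelled behaviors. They
do not validate the model against animals: real planarians stop
moving, vary speed and turn statistics between individuals (the
presets are pooled estimates), and produce tracker noise that is
neither isotropic nor frame-independent. Animal-to-animal parameter
variability is not modelled because it was not quantified.
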