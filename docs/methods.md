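# Methods

This note records the models implemented in `nettdcs`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
fixtures do and do not establish.

## Electrode geometry

Electrode positions are generated on an ideal unit sphere from the
combinatorial 10–20/10–10 construction: Cz at the vertex, the outer ring
(Fpz … Oz) at 72° inclination, midline electrodes every 18° along the
nasion–inion arc, and intermediate electrodes at equal fractions along
great-circle arcs from the midline electrode of each row to its ring
electrode. This yields exact left/right mirror symmetry and is fully
reproducible without an MRI-derived scalp. The `"10-20"` table is the
classic 21 sites plus the interleaved 10-10 sites that 32-channel
stimulation caps expose (AF3/AF4, FC5/FC6, …) — several of which the
12-electrode appetite-network montage uses — for 43 labels in total;
`"10-10"` returns the full grid. Real caps deviate from ideal-sphere
angles by a few degrees; nothing downstream depends on that accuracy.

Label matching is case-insensitive throughout (montage tables in the
wild mix spellings like "FP2" and "Fp1").

## Montage representation and constraints

A montage maps labels to currents in µA; positive is current driven
into the scalp. Invariants enforced: currents sum to zero (tolerance
1e-6 µA), per-electrode magnitude within ±2.0 mA, and total injected
(sum of positive) current within 4.0 mA — the safety envelope of
multichannel protocols at this intensity. "Total injected" is defined
as the positive-side sum; the reference 12-electrode montage saturates
it exactly (positives sum to 4000 µA). Current density is
current/area with a π cm² contact (Pistim-style Ag/AgCl electrode) by
default. Polarity inversion negates every current and provably
preserves validity because the constraint set is sign-symmetric.

Session timing (25 min, 15 s ramp-up, 60 s ramp-down, sham = ramps
only) is carried as data (`StimProtocol`); no hardware control is
attempted.

## Head model and lead field

The forward model is a four-layer concentric-sphere head: radii 7.9,
8.1, 8.5, 9.2 cm and conductivities 0.33 (brain), 1.79 (CSF), 0.008
(skull), 0.33 (scalp) S/m — standard literature values. For a point
current source on the scalp, the potential in each shell is a Legendre
series; per-degree 2×2 transfer matrices propagate the coefficients
across interfaces (continuity of potential and radial current density)
and the outer Neumann condition fixes the scale. Radii are normalized
by the scalp radius so the series is numerically stable to degree
several hundred. The degree-0 term is omitted: it is the only
non-charge-conserving mode and cancels in any zero-sum montage, which
is also why lead-field columns are defined only up to a common-mode
("gauge") shift that montage fields are invariant to.

Truncation defaults to degree 60; doubling it changes no entry of the
default lead field by more than 1e-4 V/m (the low-conductivity skull
strongly damps high harmonics). Electrodes are point contacts — a good
approximation for π cm² pads on a 9 cm sphere and it keeps the series
exact.

Sign convention: pyramidal-cell excitability increases when the field
points *into* the cortex, so the normal field is reported as
E_n = −(outward radial component); E_n is positive beneath an anode.
This is asserted by a unit test against the single-layer analytic
solution.

Cortical samples are a Fibonacci lattice on the brain-layer sphere
restricted to the upper hemisphere plus an anterior band below the
equator (orbital/medial-frontal cortex), subsampled with an even stride
so any requested count stays quasi-uniform; default 2000 points.

The sphere model is a deliberate desk-scale substitute for
template-head FEM solvers: its fields are qualitatively correct
(magnitudes ~0.1–1 V/m for 4 mA montages) but numerically different
from any realistic-geometry solution, so optimized currents are not
expected to reproduce any published montage table entry-by-entry.

## From connectivity to target

The target specification assigns each cortical sample a desired normal
field t_v ∈ {−E0, 0, +E0} and a weight. For the excitatory ("anodal")
protocol, t = +E0 where seed FC exceeds the deadband, −E0 below the
negative deadband, 0 inside it; the inhibitory protocol negates t and
keeps the weights. Weights follow the affine connectivity-strength map
w(r): 4 below r = −0.09, 10 above r = 0.225, linear between — "scaled
linearly" admits only the affine reading between those anchor points.
Weights apply over the whole sampled cortex, not only the masked
network.

Open choices resolved here: E0 is not identified by the problem (it
rescales the objective, and with saturated current caps mostly rescales
the residual); default 0.25 V/m, a typical multichannel optimization
magnitude. The deadband defaults to 0.005 to match the ±0.005 network
mask thresholds; deadband samples keep their weight so they act as
"stay quiet here" pressure rather than being unconstrained.

## Current optimization

The objective is the weighted sum of squared differences between the
induced and target normal fields. Constraints: Kirchhoff (Σc = 0),
per-electrode cap ±2 mA, and the total-current cap written
symmetrically as Σ|c| ≤ 2·4 mA — equivalent, given Σc = 0, to the
positive side being ≤ 4 mA, and the form that preserves exact
anodal/cathodal duality (optimizing against −t returns −c).

The convex program is solved as a quadratic program on split variables
c = p − n (making the L1 cap linear) with scipy's SLSQP, warm-started
where a parent solution exists, then polished by solving the
equality-constrained KKT system on the detected active set exactly.
The polish recovers interior and bound-active solutions to near machine
precision (closed-form two-electrode cases match to <1e-12); a
trust-region fallback with the exact Hessian guards rare non-
convergence. Currents below 1 µA are snapped to zero and the montage
re-balanced on the largest same-sign electrode.

Channel selection is greedy backward elimination: starting from the
all-candidates solution, repeatedly drop the electrode whose removal
(after re-solving) raises the objective least, ties broken to the
lexicographically first label, until the budget (default 12) is met,
then re-solve. Backward elimination is myopic, so the surviving set can
include a channel whose re-optimized current is exactly zero; a
completion pass then swaps such dead channels for the eliminated
candidate whose re-admission lowers the objective most, stopping when
every budgeted channel carries current or no swap strictly helps.

A structural caveat: when the total-current cap binds (as it does in
the reference protocol), the L1 constraint acts like a lasso penalty
and the optimum is naturally sparse — on some random lead fields the
true budget-12 optimum drives only 11 electrodes, and no single swap
improves it (verified by exhaustive 1-exchange search). Whether all
budgeted channels end up active is therefore a property of the
instance, not of the algorithm.

## Seed functional connectivity

Voxel membership in the spherical seed is by voxel-center Euclidean
distance, boundary inclusive, with a RAS affine mapping indices to mm;
on a 2 mm grid the default 4 mm hypothalamus sphere contains 33 voxels.
Preprocessing: per-voxel demeaning, ordinary-least-squares nuisance
regression (residuals kept; collinear columns dropped with a warning),
then a second-order Butterworth 0.01–0.08 Hz band-pass applied
forward–backward (zero phase). Regression precedes filtering, the
conventional ordering. The FC map correlates each voxel with the mean
seed series; zero-variance voxels are returned as NaN and flagged, not
silently zeroed. Network masks threshold at r > +0.005 / r < −0.005
and average Fisher-z values over the combined mask (positive/negative
submask averages are also available — the combined average is the
default reading of "binarized, combined and used as a mask").

Partial correlation residualizes both variables on [intercept,
covariate] and correlates the residuals; p comes from
t = r·√((n−3)/(1−r²)) on n−3 df. A variable collinear with the
covariate has no residual variance and returns r = 0 with a warning; a
constant covariate degrades to the plain Pearson correlation. The
implementation is cross-checked against pingouin's `partial_corr`.

Head-motion screening (2.0 mm / 2.0°) is a validation check on
supplied motion traces; realignment, spatial normalization and
smoothing are out of scope.

## Stop-signal task and SSRT

The schedule is one go-only practice block (16 trials) plus five test
blocks of 64 trials with exactly 16 stop trials each (25%) at random
positions and arrow directions balanced within one per block. The
simulation agent races an ex-Gaussian go process (defaults µ = 440,
σ = 60, τ = 80 ms; chosen to put SSRTs in the low-200 ms range typical
of middle-aged adults) against a Gaussian stop process (µ = 200,
σ = 30 ms) with 1% go omissions; a stop succeeds iff
SSD + stop latency < go RT. The staircase moves the SSD 50 ms up after
each success and down after each failure within [50, 1150] ms, starting
at 250 ms — a one-up/one-down rule whose equilibrium is the 50%
inhibition point (simulated long-run success rate 50.0 ± 0.5% over
10,000 stop trials). Staircase parameters are configurable; the
published task's exact values are proprietary, so numerical equality
with its scores is not claimed.

Two SSRT estimators are provided. The *mean method* (mean go RT − mean
SSD) matches the verbal description of tracking-based scoring but
inherits an upward bias equal to the go distribution's mean−median gap
(~+7 ms at default skew). The *integration method* (p-th go-RT
quantile, omissions replaced by the maximum RT, minus mean SSD; linear
interpolation quantiles) is robust to skew and recovers the true stop
latency to within ~3–5 ms at session size (80 stop trials); a small
negative bias remains because the staircase's stationary SSD
distribution sits slightly above the exact 50% point when the
go−stop difference is right-skewed. Both estimators discard a
configurable burn-in (default 8 stop trials) while the staircase
approaches equilibrium, and warn when the session's stop-success rate
falls outside [0.35, 0.65].

## Synthetic fixtures

The fixture generator emulates the study's inputs so every workflow is
exercisable without restricted data:

- an FC field built from smooth Gaussian clusters — positive
  medial-frontal/orbital (peak ≈ +0.3, centered near the frontal pole
  so the cortical surface passes through its core) and negative
  dorsolateral/striatal (≈ −0.2) — plus low-amplitude smooth background
  so values straddle the ±0.005 mask thresholds and all three weight
  regimes occur; evaluated on a voxel grid and at lead-field sample
  points;
- 4D series (length 200 at TR 1.18 s, reduced spatial grid) with a
  seed-correlated cluster at r = 0.6 whose components are band-limited
  to the analysis band, so the planted correlation survives
  preprocessing (recovered to ±0.1 over 20 replicates);
- a 3-condition × N-subject stop-signal crossover with a −15 ms anodal
  shift of the true stop latency, a plausible facilitation magnitude;
- a seeded smooth synthetic lead field over the standard electrode
  table with physically plausible magnitudes (|entries| ≤ 0.5 V/m per
  mA).

All randomness flows through explicit integer seeds; equal seeds give
bit-identical bundles. What passing tests show: the pipeline's
arithmetic, constraints, estimators and recovery behavior are correct
under known ground truth. What they do not show: anything about real
scanner noise, physiological confounds, realistic head geometry, or
human behavioral variability — the fixtures are statistical stand-ins,
not simulations of the scanner or the participant.

## Known limitations

- Sphere-model fields cannot be compared numerically to FEM-based
  montage tables; only structural properties (constraint saturation,
  channel counts, sign patterns) transfer.
- Greedy-plus-completion channel selection is not globally optimal
  subset selection; it is deterministic and oracle-checkable instead.
- The SSRT estimators assume an independent race; violations
  (proactive slowing, context dependence) are not modeled.
- Group-level inference (mixed-effects modeling of condition effects)
  is out of scope; the fixture study is analyzed only descriptively in
  tests.
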