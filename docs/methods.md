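# Methods

## Dose accumulation model

The package simulates single- and multi-arc VMAT delivery to a rigidly
moving geometry by temporal discretization.  An arc (gantry range
285°→75° through 0°, i.e. a 150° span, by default) is cut into
`n = round(span / Δα)` equal-width angle intervals; the rounding rule
reproduces treatment-planning arc splitting, where a 150° arc yields 65
segments at the finest practical interval of 2.3°, 30 at 5°, 15 at 10° and
a single segment at 150°.  Gantry speed and dose rate are constant by
default (the 50 s beam-on time gives a 3°/s mean speed), so segment time
windows and MU weights are uniform; a per-segment MU table switches both to
a modulated profile.  Angles are handled internally as cumulative degrees
from the arc start, which makes the 360°/0° wrap a non-event.

Each segment's time window is sub-sampled at the trajectory resolution
(`dt = 0.04 s` by default) with midpoint samples, every sub-step carrying an
equal share of the segment MU — i.e. a uniform intra-segment dose rate.
The motion-affected dose is the sum over sub-steps of the segment dose
evaluated at the displaced voxel position `x + s(t)` by trilinear
interpolation, zero outside the grid.  The displaced-lookup is implemented
as a corner-weighted sum of integer-shifted array views: exact trilinear
interpolation for a pure translation, at a fraction of the cost of a
general-purpose resampler (the equivalence is asserted in the test suite).
Sub-steps with identical displacement are merged before interpolation, so
static and piecewise-constant motion reproduce the corresponding shifted
sums bit-exactly.  The fraction of integral dose displaced off-grid is
tracked and reported as *leakage*; a few percent is normal for a
detector-sized grid, and large values signal a mis-sized grid.

No energy- or mass-transfer model is applied to the mapped dose: for small
voxels and rigid motion the dose-cloud lookup is an adequate approximation,
and the single-segment (Δα = span) case degenerates, as it should, to
moving the geometry inside the planned dose cloud.

Course-level accumulation sums fractions and arcs, with per-fraction
starting-phase offsets either fixed or drawn uniformly over one mean
breathing period from a mandatory seed.  The expected value of the mean
fraction dose is the static dose convolved with the displacement occupancy
histogram; the package ships this blurred-static construction as an
independent reference, and the test suite verifies that the fraction mean
converges toward it as fractions accumulate.

## Breathing trajectories

Trajectories are uniformly sampled 3D rigid displacements (SI, AP, LR; mm)
with `t = 0` at beam-on.  Generated scenarios use a **sine** phase
convention, `d_k(t) = (A_k/2)·sin(2πt/T)`, so `t = 0` is the
mid-respiration state that also serves as the static reference position —
matching how phantom measurements are synchronized with the beam-on signal.
Positive SI is the inhale direction.

The scenario registry covers five sinusoids (periods 3.1/4.5/5.8 s,
peak-to-peak amplitudes up to 20 mm SI, 10 mm AP, 10 mm LR) and two
cycle-jittered patterns standing in for regular and irregular patient
traces: per-cycle peak-to-peak amplitude and period are drawn from normal
distributions (regular: 12.8 ± 3.3 mm SI, 9.4 ± 3.3 mm AP, 4.8 ± 0.8 s;
irregular: 13.0 ± 5.2 mm SI, 13.6 ± 5.5 mm AP, 4.4 ± 1.0 s), truncated at
the stated maximum amplitudes and at a 0.5 s minimum period.  The
cycle-wise model (rather than an autoregressive process) was chosen because
the target statistics are exactly per-cycle means ± SDs; axes are assumed
in phase, since the phase relation of real traces is not specified.
Starting-phase offsets re-interpolate the sampled curve; sweep experiments
therefore generate trajectories with enough margin past the delivery time.

## Synthetic phantom and stand-in dose engine

The phantom is a solid-water body (110 mm cube by default) holding a
low-density lung box (ρ = 0.30 g/cm³), a 30 mm water-equivalent tumor cube
whose center defines the 2×2×2 cm CTV, and a bone rod (ρ = 1.85 g/cm³).
Densities are nominal material values; insert dimensions other than the CTV
are package defaults, declared here rather than derived.  Rasterization
anti-aliases boundaries by averaging 2³ sub-voxel samples, which makes
insert volumes resolution-consistent (< 2% change when halving a 4 mm
grid).

The segment dose engine is deliberately simple — the scientific content of
the package is the accumulation and comparison machinery, not absolute
dosimetry.  For each angular sample: density is resampled into a
beam-aligned frame, radiological depth is the cumulative density along the
beam axis (parallel-ray depth; divergence enters the fluence and
inverse-square terms), and dose is
`output · MU · exp(−μ_w·d_rad) · F_u · F_v · (SAD/r)²` with an
erf-smoothed rectangular aperture (3 mm penumbra sigma),
`μ_w = 0.0046 /mm` and `SAD = 1000 mm`.  There is no build-up region and no
scatter kernel, so depth dose is monotone.  A segment's dose integrates its
angle interval at a fixed 1° resolution; because every discretization level
of the same arc integrates the same angular samples, segment-dose sets sum
consistently to the undivided full-arc dose.

To emulate a modulated SBRT plan, the lateral aperture window narrows to
`(1 − m)` of the ITV-conformal field and its center sweeps sinusoidally
across the field as a function of the *arc fraction* (default `m = 0.7`,
3 sweeps).  Defining modulation on the arc fraction rather than per segment
keeps the summation consistency above exact.  Without modulation the
accumulated dose is nearly phase- and discretization-insensitive (pure
blurring), which would make the discretization and starting-phase
experiments vacuous; with it, interplay magnitudes fall in the range
reported for modulated clinical plans.  The aperture is sized to the ITV
(CTV plus half the per-axis peak-to-peak motion, using maximum amplitudes
for jittered scenarios) plus a 5 mm margin.

An alternative dose-source path imports externally computed segment doses
(the package's headered ASCII matrix, or DICOM RT Dose with grid scaling
applied), resampling onto a common frame where needed; the engine-variant
study also offers a per-phase mode that re-rasterizes the phantom displaced
by each segment's mean displacement, the closest-breathing-phase analogue
of choosing different planning CTs.

## γ evaluation and SDD

Plane comparison follows array-QA conventions, with the conventions the QA
literature leaves implicit made explicit here:

- the coronal ROI (11×11 cm at 2.5 mm by default) is extracted by bilinear
  resampling, centered on the reference point in the detector plane;
- setup shifts are corrected by an exhaustive ±5 mm / 0.5 mm translation
  search minimizing the summed squared difference, with parabolic sub-step
  refinement; a boundary optimum triggers a warning;
- the γ-index uses **local** normalization by the *reference* pixel dose
  (the reference is the ground-truth distribution), and the 20% low-dose
  threshold is taken on the *reference* maximum;
- the evaluated distribution is searched on a bilinear comb of step
  `dist/10` within a radius `3·dist`; pixels whose minimum sits on the
  search boundary are flagged, since the true minimum could lie outside;
- passing rates are `100 · #(γ ≤ 1)/#evaluated` per ROI (total / ITV /
  CTV, the structures' axis-aligned coronal projections), printed as
  integer percents with full precision retained;
- **SDD** is the mean pixel-wise squared dose difference (Gy²) over the
  evaluated mask — the aggregation rule (mean, masked) is a package
  convention and is stated wherever SDD is reported.

A detector-array emulation averages dose over 2.3 mm chamber footprints on
a two-pitch layout (2.5 mm inner 5.5×5.5 cm, 5 mm outer) and re-grids the
readings to the uniform 2.5 mm comparison grid.  The exact chamber count of
real arrays is not derivable from the pitch specification; the uniform-grid
path is primary and the emulation approximate.

The vectorized γ implementation is validated against an exhaustive
per-pixel brute-force oracle (naive loops, hand-written bilinear
interpolation) to 10⁻⁶ on small planes, along with identity,
uniform-offset, criterion-monotonicity and threshold-invariance properties.

## Experiments

*Discretization study*: for each scenario and Δα level, the accumulated
plane is compared (a) to the static plan — the simulated motion effect —
and (b) to a designated ground-truth dynamic plane.  Ground truth is
explicit in the configuration: an imported measurement when available,
otherwise the finest-level simulation.  *Phase sweep*: the trajectory is
offset by Δt ∈ [0, 10] s in 0.25 s steps; the ITV rate against the static
plan tracks predicted interplay, the SDD against the Δt = 0 reference
tracks synchronization error.  *Engine variants*: pairwise γ between
accumulated doses from different segment-dose sources.  All experiments are
deterministic under a fixed config: scenario seeds derive from the config
seed, and reports carry Δα, Δt and seed metadata.

## Problem sizes and numerical choices

Default study grids are 2.5 mm isotropic over the phantom (45³ voxels) —
small enough for interpolation-based accumulation to be accurate and for a
full discretization study to run in about a minute; the test suite and the
acceptance script use 4 mm (and a 10×10 cm ROI) for the heavier sweeps,
which the dt-halving and refinement checks show to be well inside the
model's insensitivity bands.  Sub-stepping at dt = 0.04 s matches the
trajectory resolution; halving it changes the accumulated dose by ≲ 0.02%
of the maximum.  Ties in the alignment search resolve to the first minimum;
degenerate (featureless) planes return a zero shift with a warning; empty γ
masks, out-of-range planes and under-covered detectors raise.

## What the synthetic conditions do and do not show

The generator reproduces the *structure* of a motion-phantom study —
scenario amplitudes/periods, arc geometry and timing, detector-plane
comparison — but not the dosimetric detail of a clinical TPS plan: the
stand-in engine has no build-up, scatter or leaf-sequence model, its
modulation is a smooth analytic sweep, and measurement noise, detector
angular response and day-to-day setup variability are absent.  Passing
tests therefore validate the accumulation, discretization and comparison
machinery and their qualitative behaviour (finer discretization tracks
interplay better; starting-phase synchronization matters; fractionation
averages interplay), not absolute agreement with any physical measurement.
Deformable motion is out of scope: the model is rigid by construction.
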