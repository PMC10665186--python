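# Methods

## Geometric model

The thick filament is treated as a straight cylinder.  Its axis is either
given (canonical +z) or fitted by total least squares: the principal axis of
the centred covariance of a point cloud, with the sign chosen so the
direction points Z-ward (away from the M band, which sits at z = 0
throughout the package).  A cloud whose first-to-second singular-value ratio
is below 1.5 has no trustworthy axis; the fit still returns, but carries a
warning.  A per-segment tangent frame from a filament trace can substitute
for the global axis when a filament is visibly curved.

Each IHM is reduced to the triangle of three landmarks: the ATP-binding site
of the free head, the same site of the blocked head, and the head–tail
junction.  Which atoms define those sites is configuration, not code: the
selection layer (`select_atoms`) extracts whatever landmark atoms the user
names, and the synthetic generator places ideal triangles directly.

At the triangle centroid a local orthonormal frame is erected — x tangential
to the cylinder, y radial outward, z axial — and the pose is the rotation
from that frame to the triangle's own frame.  Both frames need conventions
that the underlying measurement idea does not fix, so they are fixed here
once:

* triangle frame: e1 from the centroid toward the free-head landmark,
  e3 the unit normal of (p_free − c) × (p_blocked − c), e2 = e3 × e1;
* Euler order: intrinsic Z-Y-X, so β is the rotation about the radial axis;
  with these sign choices, tilting the head pair outward (away from the
  filament surface) drives β negative, matching the qualitative usage of a
  strongly positive β for canonical crown-2 heads versus negative for
  projected ones;
* angles in degrees, normalized to (−180, 180]; poses within 0.1° of the
  β = ±90° singularity report the α+γ combination in α, set γ = 0, and are
  flagged `gimbal`.

Cylindrical coordinates of the centroid supply azimuth φ (measured from a
deterministic reference perpendicular, the projection of global x onto the
axis-normal plane), radial distance r and height z.  Rise and twist of the
crown lattice are per-class successive differences after sorting by z and
grouping crowns into layers (z within 1 Å by default).  Because Cn symmetry
mates share a layer, the twist step matches each crown to the
nearest-azimuth crown of the next layer; under C3 this deliberately reports
the minimal equivalent twist (a 120° twist is indistinguishable from 0° in a
C3 lattice — single-strand input is required to resolve it).

## Sinuosity

The coiled-coil midline is the polyline through midpoints of α-carbon
couples, paired by sequence index with an optional constant offset; heptad
register estimation is out of scope.  Arc length is the raw polyline sum —
no spline — so the statistic is exactly S = C/L and SCP = (S − 1) × 100 on
the traced points.  The default scope of one SCP value is a whole tail;
`scp_profile` provides sliding arc-length windows (final window anchored at
the curve end so coverage is complete).  Curvature uses Menger circles on a
curve resampled at the smoothing length, which acts as the only smoothing
parameter; maxima are found by prominence.  Windows with end-to-end distance
below 1 Å are rejected since S diverges as L → 0.

## Synthetic generator

The generator builds the study conditions rather than arbitrary scenes: a
C3 filament with a 430 Å repeat containing three crown classes
(layers P1–P3 then A1–A28, 31 layers → 93 IHMs), 0° twist between repeats,
three full-length titin-α chains plus three titin-β chains that terminate at
crown A1 (hence six chains across a C-zone section, three across a P-zone
section), nine cMyBP-C stripes anchored at crown-2 layers spaced 430 Å
(27 anchors under C3), hexagonal thin-filament interstices, and links every
430 Å whose angles are drawn from a normal distribution (default
mean 40°, sd 10° — the published distribution is reported only as a plot, so
the defaults are a plausible mid-range choice) with 3–4 domain points each.
Crown-class pose presets (radii 128–135 Å, β from −10° to +30°, ~100 Å
triangle edges) are illustrative, chosen only to make classes
distinguishable at roughly the right scale; they are not measured values.

Layer heights are computed as (j · repeat)/crowns_per_repeat so that
multiples of the repeat stay exact in floating point; the noise-free rise
check is therefore exact rather than approximate.  Forward pose math is
written as explicit Rz·Ry·Rx matrices, sharing no code with the analysis
path, so pose-recovery tests are genuine round trips.  All randomness flows
from one seed through named substreams (seed, filament index, half), making
scenes bit-reproducible; noise settings default to zero.  Angular noise
perturbs the recorded ground truth itself (the realized pose is the truth),
and positional noise shifts each triangle rigidly with the realized
cylindrical coordinates recomputed.

The mirror half of a full sarcomere is generated as a filament whose axis
direction is −z: poses are identical in its own Z-ward frame, which is how a
bipolar filament actually relates its halves (rotation, not reflection —
chirality is preserved).

What the generator does **not** emulate: atomic-detail myosin, realistic
tomographic noise or missing-wedge effects, lattice disorder beyond
isotropic Gaussian jitter, or per-layer pose individuality (e.g. the
outlier layers seen near the filament tip in real data).  Tests passing on
synthetic scenes therefore validate the geometry pipeline, not the
biological variability of real filaments.

## Bookkeeping operations

Resampling walks a trace at fixed arc spacing with linear interpolation;
tangent-derived orientations carry tilt/ψ with the in-plane spin (rot)
NaN-flagged.  Axial shifts move records along their trace by arc length
(not chord), M-ward/Z-ward resolved through the trace's polarity flag;
records that exit the trace are dropped and counted — reports are mandatory,
silent loss is a bug by design.  Duplicate removal is greedy by descending
score (input order as tie-break), which is deterministic and reproduces the
obvious brute-force reference; the default threshold of half the resampling
spacing is configurable since no canonical value exists.  Symmetry expansion
composes orientations with the symmetry rotation; an undefined in-plane spin
is taken as zero before composition.

## Spectra and calibration

Impulse positions are binned at ≤2 Å, mean-subtracted and Fourier
transformed with zero padding (default 8×); the dominant period comes from
the largest peak excluding DC and periods above half the box, refined by
three-point parabolic interpolation in log power.  Pixel-size calibration is
the exact quotient reference_period / measured_period; the library's own
spectrum closes the loop in tests (profile in px → period in px → Å/px).

## Problem sizes

Tests and the acceptance script run at desk scale: single filaments
(93 crowns), scenes up to 53 thick / 102 thin filaments (≈5,000 crowns,
sub-second), spectra over 30 repeats, Monte-Carlo link samples of n = 200,
and 500-record duplicate-removal comparisons.  These sizes make every
oracle comparison exact or statistically well-powered while keeping the
whole suite in seconds.

## Known limitations

* The Euler convention, landmark atom choice and link-angle fold are
  documented conventions, not community standards; comparing numbers across
  tools requires matching them explicitly.
* Sinuosity on real models depends on the traced span (S2 only versus the
  full tail) — the per-crown SCP pipeline exposes `tail_start` for this
  reason, and automatic heavy-chain pairing assumes an even number of
  long chains.
* The cylinder model is straight; strongly curved filaments should be
  analysed per segment via trace tangent frames.
* `scene_census` reports raw counts and the raw thin:thick quotient to three
  significant figures; it does not attempt to reproduce rounded ratios
  quoted elsewhere.
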