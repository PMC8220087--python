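# Methods

`discqmri` re-creates, as a tested pipeline on synthetic data, a
quantitative-MRI workflow for characterizing nucleus pulposus mechanics in
an intervertebral disc under sagittal bending, with and without an anterior
radial fissure of the annulus fibrosus.  The stages are: digital disc
phantom → simulated MR acquisitions → pixel-wise T1/T2 mapping →
threshold segmentation → kinematic metrics → simplified 2D finite-element
stress analysis.

## Signal models and relaxometry

T1 maps come from an inversion-recovery (IR) series and T2 maps from a
multi-echo spin-echo (ME) series, fitted pixel-wise after normalizing each
time course by its maximum absolute intensity:

    S_IR(t) = a · (1 − 2 · e^(−t/T1))        (perfect inversion, 2 parameters)
    S_ME(t) = b · e^(−t/T2)

The default schedules emulate the protocol the phantom stands in for:
eight inversion times 30, 60, 130, 300, 600, 1300, 3000, 5800 ms, and a
32-echo train starting at 30 ms with 30 ms spacing, at 0.52 mm in-plane
resolution.  Fits use bounded trust-region least squares
(`scipy.optimize.curve_fit`); T2 is initialized by a log-linear regression
of the early echoes, T1 at TI_min-signal / ln 2.  Bounds default to
[1, 5000] ms (T1) and [1, 1000] ms (T2).  For magnitude IR data the
polarity lost by the magnitude operation is restored by negating the
samples before each candidate null index (the magnitude minimum and its
neighbour) and keeping the lowest-residual fit.  Pixels whose raw peak
intensity is below 15 % of the image maximum (air/background) are not
fitted; non-convergent pixels are flagged invalid, never silently zeroed.
Normalization makes the fitted relaxation times exactly invariant to any
global intensity scale, and on noise-free series the fits recover the
generating parameters to better than 1e−6 relative (verified against a
profiled 1-ms grid-search oracle on noisy data).

## Phantom

The phantom is a 2D axial section: an elliptical disc (annulus, default
semiaxes 11 × 14 mm) containing an elliptical nucleus (5.5 × 7 mm), and a
circular spinal canal (radius 4 mm) disjoint from the disc.  Default
tissue values — nucleus (T1 1200 ms, T2 120 ms), annulus (500, 50), canal
(1400, 200) — put the nucleus on the long-T1/long-T2 side of the
segmentation signature (T1 > 800 ms, T2 > 80 ms) with realistic contrast.
Noise is Rician on magnitude data (magnitude of a complex Gaussian
perturbation) and Gaussian on signed IR data; the default sigma of 2 % of
the maximum proton density corresponds to SNR 50.  All randomness is
seeded; identical spec + seed is bit-reproducible.

A radial fissure is a wedge of the annulus (default 18° wide, centred on
the anterior midline) relabelled as nucleus-valued tissue from the inner
annulus boundary out to `radial_depth_fraction × infiltration_fraction`
of the local annulus thickness, so the imposed migration ground truth is
the product of those fractions × 100.  The induced tear's through-plane
size (54 % of disc height) and in-plane depth (27 % of the transverse
diameter) are carried as metadata and consumed by the finite-element
geometry; they are not rasterised in the axial plane.

Mechanical states rigidly translate the nucleus along the
anteroposterior axis by analytic re-rasterization (sub-pixel exact in the
geometry) and re-set the fissure fill.  Convention, used everywhere:
anterior = decreasing row index, anterior displacement positive, so an
extension state that drives the nucleus anteriorly yields positive
displacement.

Partial volume: by default truth maps are piecewise constant so
truth-recovery tests are exact.  With `partial_volume=True` the truth
T1/T2/PD are blended at compartment boundaries by 8×8-supersampled area
fractions, emulating the boundary mixing that makes sub-pixel centroid
tracking physically possible.

What the phantom does not emulate: B1/coil inhomogeneity, slice profile,
multi-compartment relaxation within a pixel, through-plane geometry, disc
deformation other than rigid nucleus translation plus fissure fill, and
tissue heterogeneity.  Passing tests therefore demonstrate correctness of
the measurement chain under the stated signal models, not performance on
scanner data.

## Segmentation and morphometry

Nucleus-like tissue is `T1 ≥ 800 ms AND T2 ≥ 80 ms` within fitted, valid
pixels (either map can be used alone via options).  The disc is the
largest connected tissue component; the canal is the largest nucleus-like
component disjoint from it.  Infiltration is separated from the nucleus
body by a morphological opening (disk radius 4 px): sizable narrow
protrusions (≥ 5 px) become infiltration, anything smaller is kept as
nucleus, which makes the intact noiseless segmentation exactly equal to
the generating ellipse.  Cleanup order is fixed: remove components < 5 px,
fill holes.

Morphometry (mm, pixel centre = (index + 0.5) × spacing):

* centroids of nucleus and canal; optionally an intensity-weighted
  sub-pixel nucleus centroid that rescales T1 between the annulus and
  nucleus medians as a membership weight (≤ 0.01 px error on
  partial-volume phantoms; identical to the binary centroid on
  piecewise-constant maps);
* anterior/posterior nucleus boundaries on a 3-pixel midsagittal band
  (averaged per column), extent `w` = posterior − anterior;
* migration: along the ray from the nucleus centroid through the
  infiltration centroid, `100 × (infiltration tip − nucleus boundary) /
  (outer boundary − nucleus boundary)`.  The nucleus boundary radius on
  that ray comes from the moment-fitted nucleus ellipse (semiaxes = 2 ×
  moment standard deviations), which is insensitive to the part of the
  infiltration base absorbed into the nucleus label;
* Dallas-like grade: 0 (no infiltration), I (< 50 %), II (≥ 50 %).  The
  label is "Dallas-like" deliberately: true Dallas grading scores
  discographic contrast spread, which is out of scope.

## Kinematics

Bending angle: angle of the upper-stick marker pair versus horizontal;
reported as α − α0 (reference = loaded neutral state, step 1; negative =
flexion).  Axial strain: 100·(h − h0)/h0 with h the stick-tip distance.
Nucleus metrics: boundary displacement w − w0, sagittal strain
100·(w − w0)/w0, and global displacement d − d0 where d is the signed A-P
distance from the canal centroid (fixed anchor) to the nucleus centroid.
State deltas support two comparison modes: plain signed differences, and
magnitude differences (|b| − |a|) for comparisons where a reported
decrease refers to the size of a displacement; the bundled reproduction
table pins which mode each reference delta uses.  All metrics referenced
to step 1, including axial strain (the bench experiment referenced strain
to the unloaded state; a single reference keeps the table self-consistent
and only shifts the imposed phantom strains by a constant).

## Finite-element model

The midsagittal section is a rectangle: width = A-P disc extent from the
axial segmentation, height = disc height (config parameter, default
10 mm — not a measured value); a nucleus band spans the segmented nucleus
A-P extent; the fissured variant carves an anterior notch of depth 0.27 ×
anterior annulus width and height 0.54 × disc height.  Materials are
linear isotropic (nucleus E = 1 MPa, ν = 0.499; annulus E = 8.4 MPa,
ν = 0.45) under plane strain; 6-node quadratic triangles are used
specifically to avoid volumetric locking at ν = 0.499.  The mesh is
structured with grid lines snapped to the band and notch boundaries, so
material interfaces are conforming by construction.

Loading mirrors the bench conditions: inferior plate fully fixed;
superior plate carries a linearly varying normal traction statically
equivalent to a pure couple (moment / out-of-plane width, the lateral
disc extent from segmentation) plus uniform axial compression.  Positive
moment (extension) gives tensile axial stress anteriorly.  Stresses are
evaluated per element at centroids via plane-strain Hooke's law;
maximal-shear intensity is the in-plane (σ1 − σ2)/2; σ_zz = ν(σxx + σyy)
is stored but not headline.  Verification: exact patch test, slender-beam
rotation and surface stress within 2 % of Euler–Bernoulli theory, global
equilibrium < 1e−6 relative, exact linearity in load.  The fissure tip is
a re-entrant corner, hence singular: its pointwise maximum grows with
refinement (flagged in the comparison output) while the probe-region mean
is mesh-stable within 10 %; comparisons between intact and fissured
models therefore use a fixed probe box just beyond the notch tip.

## End-to-end study and numerical tolerances

`run-all` simulates six mechanical states (reference neutral, intact
flexion/extension, fissured extension/flexion/neutral) with per-state
imposed angles (the bench-measured specimen angles), axial strains,
anterior-positive nucleus shifts of −1.5…+2.5 mm and fissure fills of
0 / 0.21 / 1.0, then recovers every metric through the full chain at
SNR 50 on a 100 × 96 grid (problem sizes chosen to keep the whole study
around a minute per run).  Recovery tolerances are quantization-driven,
not fitted: marker angles and strains are exact to < 0.1° / 0.1 %;
canal-anchored centroid displacement is within 0.1 mm for intact states
and 0.25 mm for fissured states (the infiltration base absorbed into the
binary nucleus mask biases its centroid slightly anteriorly); boundary
extents and migration are within ~1.5 map pixels of the imposed truth.
The fissured-extension state shows positive nucleus strain and full
migration versus the intact extension state — the qualitative signature
the pipeline is built to detect.

## Known limitations

Single 2D slice; mono-exponential signal models only; rigid nucleus
translation rather than a deformation field; the sagittal FE section is a
strong idealization of a 3D disc (plane assumption, element size, and the
3D→2D moment conversion are all config-exposed choices); the Dallas-like
grade is a migration-fraction proxy; anterior fissures only by default
(angular position is configurable).
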