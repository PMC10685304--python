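# Methods

## Scope and coordinate conventions

`filmqa` analyses 2D film-plane dose only. The frame is phantom-attached
and voxel-center based, in mm: `crossline` (film short axis, 60 mm),
`inline` (film long axis along the bore, 165 mm), `depth` (normal to the
coronal film plane). The film frame has its origin at the lower-left
pin-defined corner. The long axis is taken as inline because the reported
profiles span the target along the bore. Oblique film planes, 3D gamma and
structure sets are out of scope.

The post-processing grid is 61×166 voxels at 1×1 mm²; one voxel is trimmed
from every border before analysis to remove film edge effects, leaving the
59×164 mm analysis grid. All interpolation is bilinear (2D) or trilinear
(3D); samples outside an interpolation support are marked invalid in a
boolean mask and excluded from every downstream statistic (never
extrapolated). Excluded-voxel counts are carried on the result objects.

## Film dosimetry model

Net response (already base-subtracted) decreases strictly with dose. The
batch calibration fits the rational form `d(x) = (a+bx)/(1+cx)` — the
standard choice for radiochromic film — by linear least squares on the
rearranged relation `d(1+cx) = a+bx`, refined by Levenberg–Marquardt on the
dose residuals; a monotone PCHIP interpolant is available via
`form="pchip"`. Fits are rejected if the point set is not strictly
monotone or the fitted curve loses monotonicity on its range.

Daily correction: a single multiplicative factor `s` minimizing
`Σ (D_i − s·f(x_i))²` over the 3–5 daily films (closed form). Whether the
physical drift acts on the dose or the response axis is not observable from
a single scan session; the dose-axis correction is the default and a
response-axis variant (`mode="response"`) is provided. Conversion flags
pixels outside the calibrated response range (±2 % of the response span)
invalid and aborts if more than 5 % of pixels are out of range.

Landmark registration is a rigid 2D Procrustes fit (SVD, no scaling) of the
three detected pin positions onto their nominal film-frame locations;
landmark *detection* is manual in practice, so landmarks enter as scan
metadata and the simulator writes ground-truth positions plus Gaussian
jitter (default SD 0.3 mm) to mimic manual selection.

## Comparison metrics

Measured film = reference; calculated dose = evaluated/searched
distribution (QA convention). Both planes are normalized by the median
dose within 10 mm of the center of the high-dose region, located as the
centroid of the largest connected component of voxels ≥ 90 % of the plane
maximum (the centroid rule is this package's construction; the notion
"center of the high dose region" is otherwise underdetermined). Threshold
doses (10 %, 90 %) are fractions of D_max of the *calculated* relative
plane by default (`dmax_source` switches to the measured plane).

* **Shift search**: the objective (not standardized anywhere) is the mean
  squared relative dose difference over voxels ≥ 10 % of D_max; exhaustive
  grid search over ±1.5 mm at 0.1 mm pitch, bilinear shifting, ties broken
  toward the smallest |shift|, no subgrid refinement.
* **Gamma**: global dose tolerance 2 % of the normalization dose, 2 mm DTA
  tolerance. The evaluated plane is bilinearly upsampled onto a lattice
  whose pitch is the requested sub-sample (default 0.2 mm) rounded to an
  integer divisor of the grid spacing, so every displacement candidate
  lands on a lattice node. Displacements are enumerated by increasing
  distance within a 6 mm (3× DTA tolerance) search disk with an early exit
  once the distance term alone exceeds every current best value — this is
  exact, verified voxel-by-voxel against an exhaustive full-disk oracle.
* **Dose deviation**: `100·(D_m − D_c)` in % of the normalization dose
  (global), mean ± SD above each threshold; profile differences are
  likewise reported in percentage points to avoid inflating relative
  errors in the low-dose region. Only the DTA tolerance is local.
* **DTA**: radial search (same sub-sampled lattice, 10 mm cap) for the
  smallest displacement with dose agreement within 0.5 % of the *local*
  reference dose. Voxels with no solution — typically noise spikes above
  the local maximum of the calculated plane in flat regions — carry the
  cap value and a saturation flag and are included in the band statistics.
  SDs are population SDs (ddof 0).
* **Chamber**: calculated value is the mean over voxel centers of a 0.5 mm
  trilinear sub-lattice restricted to the 3 mm averaging sphere; the
  discrete sphere mean differs from the continuum value by ≈1.5 % of the
  curvature term, well below chamber measurement uncertainty.

## The synthetic experiment

The simulator stands in for the physical phantom measurement; it is
first-class, tested code, not a fixture. The phantom is an elliptical
water cylinder (semi-axes 140×100 mm, length 300 mm) with a coronal film
cassette on the mid-plane, an air cylinder representing lung, and a
chamber/ball-bearing point at the body center. The plan has 13 beams
spread over a 260° arc (sparing one side), each contributing a 32 mm square
field with an error-function penumbra (σ = 3 mm; 20–80 % width
`2·√2·erfinv(0.6)·σ ≈ 1.683 σ`) and exponential attenuation
(μ = 0.004 mm⁻¹) along its upstream path through the body ellipse.
Contributions are summed and rescaled so the prescription point — on the
≈70 % isodose of the inline profile, giving the prescribed
D_max/fraction-dose ratio of ≈1.43 (1.73 Gy at 1.2 Gy/fraction) — receives
exactly 1.2 Gy per fraction. This parametric model reproduces the features
the QA chain is sensitive to (field edges, penumbra widths, attenuation
gradients, fraction summation); it is not a transport calculation and
carries no scatter, no magnetic-field effects and no heterogeneity
corrections (the lung cylinder is geometric decoration).

Adaptive replanning is emulated in the phantom-attached frame: a variation
rigidly transforms the *machine* (beam directions) by the inverse
transform; body modifications rescale the body ellipse (±5 % default) and
attenuation. A consequence of rigid replanning is exact for translations:
the per-fraction dose in the phantom frame is unchanged, so translation
fractions differ from the original plan only through the noise channels —
consistent with translation rows behaving like the original plan. Exact
physical variation magnitudes for the real phantom are not public;
defaults (translations ≤ 10 mm, rotations ≤ 5°, body scale ± 5 %) are
declared, not claimed to match any specific experiment.

Measurement-chain noise model (defaults): 0.3 % multiplicative film
response noise per pixel, 0.3 mm landmark jitter, per-dataset daily
calibration drift (SD 2 %), scanner rotation SD 1° and translation SD 1 mm,
16-bit TIFF quantization, 0.2 % chamber reading noise, optional per-fraction
delivery dose-scale and residual-shift errors (default zero). The film
encodes `dose/drift` through the inverse calibration curve; daily films are
generated with the same drift so the analysis can correct it. Every
injected perturbation is recorded in `ledger.json`; one seeded generator
drives all randomness, and regeneration under the same seed is
byte-identical.

The paper-style layout emits 14 datasets: the unadapted original plan, a
five-fraction total plus all five singles for translations, a total plus
fractions 1/3/5 for rotations, and a total plus fractions 1/5 for body
modifications; chamber readings accompany the original plan and the five
translation singles. What passing the end-to-end tests shows is that the
*analysis chain* is correct and unbiased under a realistic noise budget —
not that any physical delivery system is accurate: real film artefacts,
lateral scanner response, irradiation-to-scan kinetics and magnetic-field
effects on film are deliberately not modeled.

"Totals indistinguishable from singles" is operationalised as: each
total-dose γ pass rate (10 % threshold) and mean DTA lies within the range
of the single-fraction values or within 2 SD of their mean.

## Numerical choices and problem sizes

* Calculated grids: 2 mm pitch, 61×96×51 voxels — comfortably finer than
  the dose variations of the beam model, and matching common clinical
  recalculation pitch.
* Oracle-equivalence tests run both the optimized path and the exhaustive
  brute-force search at 0.05 mm evaluation pitch on 15×15 planes (50
  seeds); production defaults use 0.2 mm on the 59×164 grid.
* Degenerate inputs raise typed errors: collinear landmarks, non-monotone
  calibration sets, empty high-dose regions, planes outside the grid
  extent, saturating film doses, fraction-count mismatches.
* Ties in the shift search are broken deterministically (smallest |shift|,
  then lexicographic order); improvements below 1e-15 are ignored so
  floating-point noise cannot flip the argmin.

## Known limitations

* The beam model is parametric; absolute dosimetry beyond the prescription
  rescale is not meaningful, which is why the analysis (like the physical
  workflow it models) is relative with a separate chamber point check.
* DTA saturation at the 10 mm cap inflates band means when measured noise
  exceeds the local dose range of the calculated plane; the saturation
  count is reported so users can judge.
* Daily drift correction assumes a single multiplicative factor; dose- and
  response-axis variants bracket the truth but film response nonlinearity
  under large drifts is not modeled.
* RTDOSE I/O writes minimal, non-clinical metadata (no frame-of-reference
  management); it round-trips this package's own grids and reads
  dose-grid-scaled RTDOSE files, nothing more.
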