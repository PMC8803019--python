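# Methods

This note documents the models, conventions, numerical choices and
limitations behind `rnfbtrace`. It states no empirical result beyond
what the test suite and `scripts/acceptance.py` compute themselves.

## Axial-angle algebra

Fiber orientation is a line direction: defined modulo 180°, with no
forward/backward distinction. All averaging, interpolation and distance
computation therefore happens on doubled angles. For angles φᵢ with
weights wᵢ the mean is ½·atan2(Σwᵢ sin 2φᵢ, Σwᵢ cos 2φᵢ), folded to
[0, π); the distance between two orientations is the Euclidean distance
of their doubled-angle unit vectors, d = 2|sin(a−b)| ∈ [0, 2]. A zero
resultant (e.g. perpendicular inputs of equal weight) has no defined
mean and raises rather than returning an arbitrary angle. Geometric
resampling (rotation, bilinear sampling, streamline interpolation) is
always performed on the (sin 2φ, cos 2φ) components — interpolating raw
angles breaks at the wraparound. Rotating an orientation *field* by α
both moves the grid and adds α to every value. Invalid pixels are mask
bits, never sentinel values, and windowed operations are mask-aware: a
masked pixel contributes nothing, so arbitrary values underneath (e.g.
under vessels) cannot influence any output.

Angles are measured counterclockwise from the +x image axis in the
*physical* (micrometre) frame, so orientations and step geometry remain
correct under anisotropic pixel spacing (the instrument grid is
8.2 × 25.2 µm).

## Trajectory model

The average bundle path is φ(φ₀, r) = φ₀ + b·(r − r₀)^c in polar
coordinates around the ONH center, r in degrees, r₀ = 4° (the ONH entry
circle; configurable). The canonical frame puts the fovea at the origin
and the ONH at (+15°, 0); the polar angle is measured from the *nasal*
horizontal (+x), counterclockwise, so the fovea sits at φ = 180° and
the temporal raphe along φ = ±180°. This is the only convention under
which the published coefficient signs (b > 0 superior, b < 0 inferior;
hemifields φ₀ ∈ (0°, 180°) and (−180°, 0°)) drive both hemifields
toward the raphe. The tanh arguments of the ln b formulas are negated
relative to those of c — the reading that places each inflection inside
its hemifield's φ₀ range.

Per-eye fitting uses a similarity transform only: translation matches
the fovea, then rotation and scale about the fixed fovea match the ONH
center. The nonlinear fovea-centered coordinate modification described
for the original model is deliberately not implemented; consequences
are confined to the raphe neighborhood (below). Left eyes are mirrored
into the right-eye frame before fitting and angles mirrored back
(θ → π − θ), since the coefficients are right-eye parameterized.

Rasterization generates trajectories at 1 per degree of φ₀ (default),
samples them every 0.25°, clips them where |φ| crosses 180°, and
scatters the analytic tangent dP/dr (reduced mod π) onto the pixel grid
by inverse-distance weighting of the doubled components within 1 model
degree (k ≤ 12 nearest samples, KD-tree). Pixels farther than that from
every trace sample stay invalid; a deep nasal wedge at large
eccentricity is genuinely outside the model's reach.

The inverse query — which trajectory passes through a given point —
scans φ₀ on a 0.25° grid for a sign change of φ(φ₀, r_s) − φ_s and
refines it with Brent's method; it is used to compare traced entry
angles with the analytic model.

## Polarization extraction

Below the RNFL the tissue preserves polarization, so every depth sample
between the RNFL/GCL and OPL/ONL boundaries measures the same
cumulative RNFL state. Per A-scan the normalized Stokes vector
(cos 2δ, sin 2δ·cos(π−2θ), sin 2δ·sin(π−2θ)) is averaged over that band
(z ∈ [B_NG, B_OO), i.e. B_OO − B_NG samples), re-normalized to unit
length, and inverted: δ_P = arccos(Q_R)/2, φ_P = ½·atan2(V_R, −U_R)
folded to [0, π). The two-argument arctangent preserves the printed
ratio −V/U while keeping quadrant information; with this sign choice a
depth-constant volume of axis θ returns exactly θ, which makes the
synthetic round trip exact and the later offset calibration recover the
generator's offset with the expected sign. Pixels are invalid when the
band is empty, the averaged norm falls below 0.1 (depolarization or
depth-inconsistent states; configurable), or the in-plane amplitude
hypot(U, V) vanishes (δ ≈ 0 ⇒ the axis is undefined).

## Intensity-ridge orientation

The projection is the per-pixel mean of the band of
BE = min(B_NG − B_ILM, MaxLen) voxels immediately above the RNFL/GCL
boundary, MaxLen = 15 (the band never crosses the ILM; empty bands are
invalid). Normalization subtracts a sliding-mean background (145 px
window on the instrument grid, vessel-excluded) and rescales on the
1st–99th percentiles, clipping to [0, 1] — percentiles rather than
min/max so vessel shadows cannot compress the usable range. A constant
image is flagged degenerate and set to 0.5.

Gradients are 3×3 Sobel operators (the standard choice in the
fingerprint literature this follows), divided by the pixel pitch per
axis so the tensor lives in the physical frame. Pixels whose Sobel
stencil touches a vessel or invalid pixel contribute zero to the
windowed tensor sums Gxx, Gyy, Gxy (half-window N = 7 on the instrument
grid). The dominant gradient direction is ½·atan2(2Gxy, Gxx − Gyy);
ridges run perpendicular to it, and the implementation returns the
ridge orientation directly — validated against rendered gratings of
known orientation rather than against any particular printed arctan
form. Zero-energy windows are invalid.

Two consistency measures gate the smoothing: DSTm, the doubled-angle
distance to the model map, and DSTn, the distance between a pixel's
doubled components and their windowed means (a locally parallel field
gives exactly 0 — the product-of-squares variant that does not vanish
for parallel fields was rejected as inconsistent with its purpose).
Both are sliding-window averaged (15 px) and combined into
W = clamp(1 − ½·√(DSTm̄² + DSTn̄²), 0, 1). The final map φ_F is the
W-weighted axial mean over windows of half-size up to 30 px, shrunk
near the fovea so no window covers the fovea position (bundles converge
there from all directions; pixels within 1 px of it use only
themselves). Box sums use integral images so the per-pixel variable
window is O(1).

Two estimator parameters beyond the printed ones:

* **Window scaling.** The printed window sizes are pixel counts on the
  8.2 µm instrument grid. `scaled_parameters()` converts them to other
  grids by physical extent (with floors keeping each window usable);
  the pipeline applies this by default, so a 75 µm phantom grid uses
  tensor half-window 2, background window 17, etc.
* **ONH exclusion (default 6°).** Close to the nerve head, bundles are
  packed more tightly than the pixel pitch and leave no usable
  gradient; intensity estimates there are systematically biased. φ_F
  is masked within this radius and the fusion lets the polarization
  and model sources carry the region.

## Fusion

The polarization axis is relative (it derives from the phase difference
of the detection channels), so a global offset is estimated first:
φ_P + ofs is compared with φ_F on an annulus of 5°–10° eccentricity
around the ONH (outside the entry circle, inside high-retardation
territory; configurable) by the sum of squared doubled-component
differences over jointly valid pixels, for integer offsets −90°…+90°.
The returned value is the *correction applied to φ_P*. Fewer than 100
jointly valid band pixels is an error, not a silent guess.

Per-source weights W = clamp(1 − d(φ, φ_M)/2, 0, 1) measure agreement
with the model map; they are smoothed with a 15 px sliding average
(confined to each source's own validity) and the sources merged as a
weighted axial mean. Where exactly one source is valid it passes
through unchanged; where none is — or the weighted resultant vanishes,
as for perpendicular sources of equal weight — the model fills in,
blended over a 10 px linear ramp on the doubled components from the
nearest fused value to pure φ_M to avoid orientation seams. The
model-filled mask is reported.

## Tracing

From position (x, y) the axial direction OM(x, y) (sampled bilinearly
on the doubled components; a sample is valid only if all four
contributing pixels are) yields two antipodal candidates at distance r.
The first step picks by the distance rule (minimum distance to the ONH
center for inward traces, maximum for outward); every later step
continues the previous heading (positive dot product), which prevents
180° oscillation where the two candidates are nearly equidistant (the
raphe). A midpoint refinement re-samples the direction halfway along
the chosen displacement and steps along that; the step length stays
exactly r in the physical frame and the first-order curvature bias of
plain Euler integration drops out — halving r then changes phantom
entry angles by well under 0.5°. Positions are kept in micrometres so
steps are isotropic under anisotropic pixel spacing; r defaults to 1 px
of the fast axis (≈ 8.2 µm on instrument data) with max 20 000 steps.
Inward traces terminate on entering the ONH circle, leaving the valid
region, or exhausting steps; the reason is recorded. A trace through a
point of interest concatenates the reversed outward sub-trace with the
inward one (seed appearing once, points ordered periphery → ONH).

Tracing inward is the robust mode: bundle paths converge on the ONH, so
orientation errors contract; outward traces diverge. The suite verifies
this directly (endpoint spread of inward vs outward traces under
2° orientation noise, 100 matched seed pairs, paired Wilcoxon).

## Evaluation

Traces are resampled in ONH-centered polar coordinates (fixed radial
grid from r = 4° outward, 0.1° steps; angles unwrapped along the trace;
strictly increasing radius enforced by a running maximum). The entry
angle is the angular position at the 4° circle, reported with 0° at the
temporal horizontal increasing superiorly (right-eye convention) — the
reference direction affects reported EAs but none of the agreement
statistics, which are all differences. Traces that never reach the
circle have no EA; fixed-radius arcs are flagged degenerate.

Per trace group: EA range = maximum pairwise circular distance; EA
offset = mean circular distance to the circular mean (undefined means
raise). Trace RMSE converts the wraparound-minimal angular difference
at each shared radial sample to arc length (Δφ_rad · r · µm-per-degree
— arc, not chord; indistinguishable at few-degree differences), takes
the root mean square per trace and averages over traces; at least 1° of
shared radial support is required. ICC(A,k) is computed from explicit
two-way ANOVA mean squares, (MSR − MSE)/(MSR + (MSC − MSE)/n), after
wraparound compensation: each trace's EAs are unwrapped to within ±180°
of the trace's circular mean, and trace means aligned to a common
branch. Zero between-trace variance raises (the ICC is undefined there).
Sector grouping follows the six-sector ONH scheme (T, ST, IT, SN, IN,
N); the 52-point 24-2 grid with sector labels ships as a versioned CSV
reconstructed from the published mapping figure and is user-editable.
Sector standard deviations are computed over traces and labelled as
such. Visual-field seed points map to the image through the model fit
with the vertical axis inverted (superior field → inferior retina); the
blind-spot column lands on the ONH, which anchors the horizontal
convention.

## Synthetic phantoms

The generator defines the test conditions; every output is a pure
function of (spec, seed).

* **Truth field**: the rasterized fitted model, nearest-neighbor filled
  to full density. Default frame: isotropic 75 µm grid (4 px/degree) at
  300 µm/degree, 184 × 204 px covering x ∈ [−28°, +23°] and
  y ∈ [−23°, +23°] around the fovea — the full 24-2 grid plus the ONH
  circle. (At a 4×-downsampled instrument grid the vertical ridge
  period would fall below 3 px and alias; the isotropic grid keeps the
  texture resolvable while anisotropic behavior is unit-tested
  separately.)
* **Projection**: streamlines of the truth field are seeded with even
  spacing (farthest-point/occupancy seeding, ≈ one ridge period apart,
  default 5 px ≈ 375 µm) and stroked with Gaussian profiles
  (σ = period/4). Stroke accumulation fades where bundles spread, so
  ridge amplitude is equalized against a smoothed local maximum
  envelope (amplification capped ×4): real bundles keep their
  reflectivity while their spacing varies. Contrast 0.8 on a 0.2
  background by default; optional dark vessel Béziers from the ONH with
  a recorded (dilated) mask; optional additive noise.
* **PS-OCT stack**: depth-constant axis = truth − offset (the spec'd
  offset is the *correction* the calibration should recover), constant
  retardation 0.4 rad (mid-range for a healthy RNFL), optional
  per-voxel angular noise; smooth random boundaries with RNFL thickness
  5–40 voxels over a 56-voxel depth; the intensity volume's RNFL band
  carries the projection texture so both estimation branches run from
  one stack.
* **Degradation**: additive Gaussian noise calibrated to a target SNR
  in dB (20·log₁₀ of signal-SD over noise-SD; for orientation maps the
  noise is added to the doubled components and re-normalized), and
  smooth-blob validity dropout hitting the requested fraction exactly
  (quantile threshold on a filtered noise field).

What passing phantom tests does *not* show: real OCT speckle
statistics, segmentation errors in the layer boundaries, imperfect
vessel masks, mosaicking seams between scan regions, or pathological
RNFL thinning beyond what SNR/dropout emulate. The generator's ridges
are also geometrically cleaner than real bundle texture, so phantom
accuracy figures are an upper bound on real-data performance.

## Known limitations

* The similarity-only model fit leaves the raphe region of φ_M
  unrealistic: with the printed coefficients, trajectories cross the
  temporal horizontal steeply rather than asymptotically, and the
  doubled-angle average of the two hemifields on the midline itself is
  near-vertical. Tracing across the raphe relies on the heading rule
  and can still pick the wrong hemifield for seeds essentially on the
  line — the known failure mode of this class of methods.
* The nasal far periphery lies outside the model's trace coverage;
  φ_M is invalid there and fusion output relies on the measured
  sources.
* ICC wraparound compensation assumes each trace's EAs span well under
  a half-circle; raters disagreeing by ≈ 180° on one trace would be
  aliased rather than flagged.
* The pipeline processes one already-mosaicked wide field; per-region
  stitching and registration are out of scope, as are layer
  segmentation and corneal birefringence compensation (their outputs
  are inputs here).
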