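# rnfbtrace

Automatic tracing of retinal nerve fiber bundles (RNFBs) from wide-field
en-face imaging of the retinal nerve fiber layer (RNFL).

Glaucoma damages the RNFL along the trajectories of individual fiber
bundles, so linking a retinal location to the position where its bundle
enters the optic nerve head (ONH) is central to structure–function
analysis. Manual tracing on fundus images is slow and poorly
reproducible; this package reconstructs bundle trajectories
automatically from three complementary orientation sources and
quantifies the agreement of trace sets with circular statistics. It is
aimed at researchers working with polarization-sensitive OCT (PS-OCT)
or en-face RNFL imagery, and at anyone who needs a fully synthetic,
ground-truthed test bed for orientation-field estimation and streamline
tracing on the retina.

## What it computes

Every stage works on *axial* orientations (directions modulo 180°),
handled throughout as doubled-angle unit vectors (sin 2φ, cos 2φ).

1. **Trajectory model (φ_M)** — the parametric average bundle path in
   ONH-centered polar coordinates,

       φ(φ₀, r) = φ₀ + b(φ₀) · (r − r₀)^{c(φ₀)},   r₀ = 4°,

   with tanh-shaped coefficients per hemifield (superior: c = 1.9 +
   1.4·tanh((φ₀−121)/14), ln b = −1.9 + 3.9·tanh(−(φ₀−121)/14);
   inferior: c = 1.0 + 0.5·tanh((−φ₀−90)/25), ln(−b) = 0.7 +
   1.5·tanh(−(−φ₀−90)/25)). The model is fitted to each eye by a
   similarity transform (fovea by translation, ONH by rotation and
   scale) and rasterized from 1-per-degree traces.
2. **Polarization (φ_P)** — per-pixel Stokes vectors averaged over the
   polarization-preserving band below the RNFL, re-normalized, and
   inverted for RNFL retardation δ_P and axis orientation φ_P. The axis
   is relative; its global offset is calibrated later.
3. **Intensity ridges (φ_F)** — an RNFL projection (mean intensity of
   ≤ 15 voxels above the RNFL/GCL boundary) is background-normalized
   and processed with fingerprint-style structure-tensor orientation
   estimation, followed by model/neighborhood-consistency weighting and
   a large weighted axial-mean smoothing. Vessel pixels are excluded.
4. **Fusion (OM)** — the φ_P axis offset is found by exhaustive search
   (−90°…+90°, 1° steps) against φ_F on an annulus around the ONH; the
   sources are merged by a weighted axial mean with per-source weights
   measuring agreement with φ_M, which also fills regions where neither
   source is usable.
5. **Tracing** — streamline integration of OM with step length r
   (default 1 px): two antipodal candidates per step, inward tracing
   (toward the ONH, the convergent and therefore robust direction),
   outward tracing, and bidirectional traces through a point.
6. **Evaluation** — traces in ONH-centered polar coordinates; entry
   angle (EA) at the 4° circle; per-Garway-Heath-sector circular EA
   range and offset, trace RMSE in µm, and ICC(A,k) with wraparound
   compensation. The 24-2 visual-field grid with sector labels ships as
   an editable CSV.

A synthetic-phantom generator (`rnfbtrace.synthetic`) produces every
input the pipeline consumes — ridge-textured projections rendered by
stroking streamlines of a known truth field, depth-constant PS-OCT
stacks with a known axis offset, layer boundaries, vessel masks, and
calibrated SNR/dropout degradation — so the whole chain is testable
without instrument data.

## Worked example

`examples/04_fuse_and_trace.py` runs the full chain on a default
phantom (wide field covering the 24-2 grid, 300 µm/degree, 75 µm
pixels) with the projection degraded to 20 dB SNR:

```
axis offset: recovered +30 deg (generator used +30)
fused orientation map OM: 0 model-filled pixels
entry angles from 52 VF seeds: median |error| vs analytic model = 1.87 deg
below ~2 deg means traced bundles enter the ONH where the model says.
```

The recovered +30° is the polarization channel's global axis offset,
found blind by the calibration search. The last line is the end-to-end
figure of merit: bundles traced through the fused map from all 52
visual-field seed points enter the ONH within a median of 1.87° of the
analytic model trajectories that generated the phantom.

The other examples exercise one capability each: `01` the trajectory
model, `02` Stokes-averaging recovery, `03` ridge-orientation
estimation under noise and vessels, `05` the sector-wise agreement
report (EA range/offset, RMSE, ICC) for repeated tracings.

A thin CLI mirrors the stages:

```bash
rnfbtrace simulate --seed 5 --out phantom/
rnfbtrace run --config run.yaml
rnfbtrace {fit-model, orient-polarization, orient-intensity, fuse, trace, evaluate} ...
```

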