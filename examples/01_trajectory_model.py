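"""Evaluate the average nerve-fiber trajectory model for one eye.

Builds the parametric trajectory phi(phi0, r) = phi0 + b (r - r0)^c,
fits it to an eye's fovea/ONH landmarks by similarity transform, and
rasterizes the orientation map phi_M.
"""

import numpy as np

from rnfbtrace import jansonius
from rnfbtrace.synthetic import default_geometry

geometry = default_geometry()  # fovea-centered frame, ONH 15 deg nasal

print("model coefficients b, c by starting angle phi0 (deg):")
for phi0 in (30.0, 121.0, 160.0, -45.0, -90.0, -150.0):
    hemi = "superior" if phi0 > 0 else "inferior"
    b, c = jansonius.model_constants(phi0, hemi)
    print(f"  phi0={phi0:+7.1f} ({hemi[:3]}):  b={b:+.4f}  c={c:.3f}")
# b > 0 superior / b < 0 inferior: both hemifields curve toward the raphe.

p = jansonius.TrajectoryParams.from_phi0(121.0)
print("\nangular position along the phi0=121 trajectory:")
for r in (4.0, 8.0, 12.0, 16.0):
    print(f"  r={r:4.1f} deg -> phi={jansonius.trajectory(p, r):7.2f} deg")
# phi grows with eccentricity: the bundle arcs toward the temporal raphe.

fit = jansonius.fit_to_eye(geometry.fovea_xy, geometry.onh_xy, geometry)
phi_m = jansonius.rasterize_model(fit, (184, 204), traces_per_degree=1.0)
print(f"\nrasterized phi_M: shape {phi_m.shape}, "
      f"{100 * phi_m.valid.mean():.1f}% of pixels reached by a model trace")
a, _ = phi_m.sample(geometry.fovea_xy[0] + 40, geometry.fovea_xy[1])
print(f"orientation on the papillomacular midline: {np.degrees(a):.1f} deg "
      "(mod 180; ~0/180 = horizontal, as the bundle runs fovea -> ONH)")
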