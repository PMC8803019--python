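"""Estimate fiber orientation from a ridge-textured RNFL projection.

Renders a projection whose ridge orientation equals a known truth field,
degrades it to 20 dB SNR, and runs the fingerprint-style chain:
normalize -> structure tensor (phi_FI) -> model/neighbor consistency
weights -> weighted axial smoothing (phi_F).
"""

import numpy as np

from rnfbtrace import intensity
from rnfbtrace.core import axial_distance
from rnfbtrace.synthetic import PhantomSpec, degrade, make_truth_field, render_projection

spec = PhantomSpec(rng_seed=1, vessel_count=5)
truth = make_truth_field(spec)
proj = degrade(render_projection(truth, spec), snr_db=20, seed=3)
g = spec.geometry

win = intensity.scaled_parameters(g.spacing_x)  # instrument windows -> this grid
res = intensity.estimate_intensity_orientation(
    proj, truth, fovea_xy=g.fovea_xy, geometry=g, **win
)

for name in ("phi_fi", "phi_f"):
    m = res[name]
    err = np.degrees(np.arcsin(np.clip(axial_distance(m.values, truth.values) / 2, 0, 1)))
    print(f"{name}: median axial error {np.median(err[m.valid]):.2f} deg "
          f"on {100 * m.valid.mean():.0f}% valid pixels")
print("smoothing with consistency weights reduces the raw tensor error;")
print("vessel pixels and the crowded zone near the ONH are excluded by mask.")
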