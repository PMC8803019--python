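"""Shared fixtures: one default phantom reused across the suite.

The phantom (seed 7) represents the study conditions — wide field
covering the 24-2 grid, 300 um/degree, ONH 15 degrees nasal of the
fovea — and is generated once per session; tests must not mutate it.
"""

import numpy as np
import pytest

from rnfbtrace import evaluation, jansonius, synthetic, tracing


@pytest.fixture(scope="session")
def phantom_spec():
    return synthetic.PhantomSpec(rng_seed=7)


@pytest.fixture(scope="session")
def geometry(phantom_spec):
    return phantom_spec.geometry


@pytest.fixture(scope="session")
def fit(phantom_spec):
    return phantom_spec.fit()


@pytest.fixture(scope="session")
def truth(phantom_spec):
    return synthetic.make_truth_field(phantom_spec)


@pytest.fixture(scope="session")
def clean_projection(truth, phantom_spec):
    return synthetic.render_projection(truth, phantom_spec)


@pytest.fixture(scope="session")
def vf_grid():
    return evaluation.load_vf_grid()


@pytest.fixture(scope="session")
def analytic_entry_angles(fit, geometry, vf_grid):
    """Entry angle of the analytic model trajectory through each VF seed,
    in the same polar convention the evaluation module uses."""
    seeds = vf_grid.seed_points_px(fit)
    out = {}
    for (x, y), pid in zip(seeds, vf_grid.points["id"]):
        phi0 = jansonius.find_phi0(fit, (x, y))
        if phi0 is None:
            continue
        pts, _, _ = jansonius.trajectory_polyline_px(fit, phi0, r_max=40, dr=0.1)
        trace = tracing.Trace(
            points=pts[::-1], step_px=1.0, seed=(x, y), direction_mode="inward",
            termination="onh_reached",
        )
        out[pid] = evaluation.to_polar(trace, geometry).angle_deg[0] % 360.0
    return out


@pytest.fixture(scope="session")
def fovea_raphe_mask(phantom_spec, geometry):
    """Pixels at least 2 degrees from the fovea and from the raphe line."""
    h, w = phantom_spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    ppd = geometry.um_per_deg / geometry.spacing_x
    fx, fy = geometry.fovea_xy
    far_fovea = np.hypot(xx - fx, yy - fy) / ppd >= 2.0
    near_raphe = (xx < fx) & (np.abs(yy - fy) < 2.0 * ppd)
    return far_fovea & ~near_raphe


@pytest.fixture(scope="session")
def divergence_spreads(truth, geometry):
    """Endpoint spreads of inward vs outward traces under 2-degree noise.

    100 matched seed pairs, 4 seeded noise realizations each; computed
    once per session and shared between the tracing property test and
    the acceptance check.
    """
    rng = np.random.default_rng(42)
    h, w = truth.shape
    seeds = []
    while len(seeds) < 100:
        x, y = rng.uniform(5, w - 6), rng.uniform(5, h - 6)
        if 12 <= geometry.eccentricity_deg(x, y) <= 20:
            seeds.append((x, y))
    spread_in, spread_out = [], []
    for i, (x, y) in enumerate(seeds):
        clean = tracing.trace_inward((x, y), truth, geometry, r_px=1.0)
        if clean.termination != "onh_reached" or len(clean) < 10:
            continue
        start_out = tuple(clean.points[-1])
        ends_i, ends_o = [], []
        for k in range(4):
            noisy = synthetic.perturb_orientation(truth, 2.0, seed=1000 * i + k)
            ti = tracing.trace_inward((x, y), noisy, geometry, r_px=1.0)
            if ti.termination == "onh_reached":
                ends_i.append(ti.points[-1])
            to = tracing.trace_outward(start_out, noisy, geometry, r_px=1.0,
                                       max_steps=len(clean))
            ends_o.append(to.points[-1])
        if len(ends_i) < 4:
            continue
        for ends, acc in ((ends_i, spread_in), (ends_o, spread_out)):
            e = np.asarray(ends)
            c = e.mean(axis=0)
            acc.append(float(np.mean(np.hypot(*(e - c).T))))
    return np.asarray(spread_in), np.asarray(spread_out)


def axial_error_deg(a, b):
    """Per-pixel axial error in degrees between two angle arrays."""
    d = np.abs(((np.asarray(a) - np.asarray(b)) + np.pi / 2) % np.pi - np.pi / 2)
    return np.degrees(d)


@pytest.fixture(scope="session")
def axial_err():
    return axial_error_deg
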