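"""Synthetic phantom generation: every pipeline input from a known truth.

A phantom starts from a ground-truth orientation field — the rasterized
average-trajectory model for the phantom's eye geometry — and emulates
the measured inputs:

* a ridge-textured en-face projection whose local orientation equals the
  truth (rendered by *stroking* evenly spaced streamlines of the truth
  field with Gaussian profiles — reusing the tracer guarantees
  orientation fidelity and reproduces the natural spreading of bundles
  away from the ONH, including the sparse raphe region),
* a PS-OCT stack with depth-constant polarization (axis = truth + a
  known global offset, constant retardation) plus per-voxel angular
  noise, smooth layer boundaries and an intensity volume whose RNFL band
  carries the projection texture,
* vessel masks (dark curves stamped into the projection),
* calibrated degradation (additive noise at a target SNR, smooth-blob
  validity dropout).

Every output is a pure function of (spec, seed): identical spec and seed
give bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .core import AxialAngleMap, RetinalGeometry, components_to_angle, fold_axial
from .intensity import ProjectionImage
from .jansonius import ModelFit, fit_to_eye, rasterize_model
from .polarization import LayerBoundaries, PSOCTStack
from .tracing import trace_through_point

__all__ = [
    "PhantomSpec",
    "default_geometry",
    "make_truth_field",
    "render_projection",
    "render_psoct",
    "degrade",
    "perturb_orientation",
]


def default_geometry(pixels_per_deg=4.0, um_per_deg=300.0) -> RetinalGeometry:
    """Geometry of the default phantom frame.

    A wide field covering the full 24-2 grid and the ONH entry circle:
    x spans roughly -28..+23 degrees around the fovea (nasal positive),
    y about +-23 degrees, on an isotropic grid.
    """
    spacing = um_per_deg / pixels_per_deg
    fovea = (28.0 * pixels_per_deg, 23.0 * pixels_per_deg)
    onh = (fovea[0] + 15.0 * pixels_per_deg, fovea[1])
    return RetinalGeometry(
        fovea_xy=fovea,
        onh_xy=onh,
        onh_radius_deg=4.0,
        um_per_deg=um_per_deg,
        spacing_x=spacing,
        spacing_y=spacing,
    )


def _default_shape(pixels_per_deg=4.0):
    return (int(round(46 * pixels_per_deg)), int(round(51 * pixels_per_deg)))


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom.

    Defaults emulate the study conditions at a reduced isotropic grid:
    300 um per degree, 4 px per degree (75 um pixels), ridge period
    about 375 um, RNFL retardation 0.4 rad with a 30-degree axis offset
    between the polarization channel frame and the en-face frame.
    """

    shape: tuple = None
    geometry: RetinalGeometry = None
    ridge_period_px: float = 5.0
    ridge_contrast: float = 0.8
    noise_sigma: float = 0.0
    vessel_count: int = 0
    axis_offset_true_deg: float = 30.0
    retardation_true: float = 0.4
    axis_noise_sigma: float = 0.0
    depth: int = 56  # >= ILM + max RNFL thickness + sub-RNFL band
    rng_seed: int = 0

    def __post_init__(self):
        if self.geometry is None:
            self.geometry = default_geometry()
        if self.shape is None:
            self.shape = _default_shape()
        self.shape = (int(self.shape[0]), int(self.shape[1]))

    def rng(self, salt=0):
        return np.random.default_rng(np.random.SeedSequence([self.rng_seed, salt]))

    def fit(self) -> ModelFit:
        return fit_to_eye(self.geometry.fovea_xy, self.geometry.onh_xy, self.geometry)


def make_truth_field(spec: PhantomSpec, traces_per_degree=2.0) -> AxialAngleMap:
    """Dense ground-truth orientation field over the phantom extent.

    The fitted trajectory model is rasterized; the few pixels beyond the
    reach of any model trace (deep nasal wedges) are filled from their
    nearest rasterized neighbor so the truth is defined everywhere.
    """
    fit = spec.fit()
    phi_m = rasterize_model(fit, spec.shape, traces_per_degree=traces_per_degree)
    if not phi_m.valid.all():
        _, (iy, ix) = ndimage.distance_transform_edt(~phi_m.valid, return_indices=True)
        phi_m.values = phi_m.values[iy, ix]
        phi_m.valid = np.ones_like(phi_m.valid)
    return phi_m


def _stroke_streamlines(truth: AxialAngleMap, geometry, period_px, rng, step_px=1.0):
    """Evenly spaced streamlines of the truth field (Jobard–Léfer style).

    Candidate seeds are visited in random order; a bidirectional
    streamline is started wherever the canvas is still unoccupied within
    half a ridge period, and its points stamp the occupancy raster.
    Returns a list of (N, 2) pixel polylines.
    """
    h, w = truth.shape
    half = max(int(round(period_px / 2.0)), 1)
    occupied = np.zeros((h, w), dtype=bool)
    # stamp footprint: disk of radius ~ half the spacing
    rr = np.arange(-half, half + 1)
    dy, dx = np.meshgrid(rr, rr, indexing="ij")
    disk = dy**2 + dx**2 <= half**2
    dy, dx = dy[disk], dx[disk]

    margin = 2
    ys, xs = np.mgrid[margin : h - margin : 2, margin : w - margin : 2]
    seeds = np.stack([xs.ravel(), ys.ravel()], axis=1)
    order = rng.permutation(len(seeds))

    polylines = []
    for i in order:
        sx, sy = seeds[i]
        if occupied[sy, sx]:
            continue
        tr = trace_through_point((float(sx), float(sy)), truth, geometry, r_px=step_px)
        if len(tr) < 3:
            continue
        polylines.append(tr.points)
        px = np.clip(np.round(tr.points[:, 0]).astype(int), 0, w - 1)
        py = np.clip(np.round(tr.points[:, 1]).astype(int), 0, h - 1)
        yy = np.clip(py[:, None] + dy[None, :], 0, h - 1).ravel()
        xx = np.clip(px[:, None] + dx[None, :], 0, w - 1).ravel()
        occupied[yy, xx] = True
    return polylines


def _splat_polyline(canvas, points, sigma_px, kernel_half=None):
    if kernel_half is None:
        kernel_half = max(int(np.ceil(3 * sigma_px)), 1)
    h, w = canvas.shape
    rr = np.arange(-kernel_half, kernel_half + 1)
    ky, kx = np.meshgrid(rr, rr, indexing="ij")
    for x, y in points:
        ix, iy = int(round(x)), int(round(y))
        gx = ix + kx
        gy = iy + ky
        ok = (gx >= 0) & (gx < w) & (gy >= 0) & (gy < h)
        weight = np.exp(-(((gx - x) ** 2 + (gy - y) ** 2) / (2 * sigma_px**2)))
        np.add.at(canvas, (gy[ok], gx[ok]), weight[ok])


def _vessel_curves(spec: PhantomSpec, rng):
    """Smooth dark vessel arcs leaving the ONH, as quadratic Beziers."""
    h, w = spec.shape
    onh = np.array(spec.geometry.onh_xy)
    curves = []
    for _ in range(spec.vessel_count):
        ang = rng.uniform(0, 2 * np.pi)
        end = np.array(
            [
                rng.uniform(0.05, 0.95) * (w - 1),
                rng.choice([rng.uniform(0, 0.15), rng.uniform(0.85, 1.0)]) * (h - 1),
            ]
        )
        ctrl = onh + rng.uniform(15, 40) * np.array([np.cos(ang), np.sin(ang)])
        t = np.linspace(0, 1, 200)[:, None]
        pts = (1 - t) ** 2 * onh + 2 * (1 - t) * t * ctrl + t**2 * end
        curves.append(pts)
    return curves


def render_projection(truth: AxialAngleMap, spec: PhantomSpec):
    """Render a ridge-textured projection whose orientation equals ``truth``.

    Returns a :class:`ProjectionImage` (values in [0, 1], ``normalized``
    left False so the analysis pipeline applies its own normalization)
    with the vessel mask filled in.
    """
    rng = spec.rng(salt=1)
    h, w = spec.shape
    canvas = np.zeros((h, w))
    if spec.ridge_contrast > 0:
        polylines = _stroke_streamlines(
            truth, spec.geometry, spec.ridge_period_px, rng
        )
        sigma = max(spec.ridge_period_px / 4.0, 0.8)
        for pts in polylines:
            _splat_polyline(canvas, pts, sigma)
        # Equalize ridge amplitude against the local envelope: bundles keep
        # a similar reflectivity everywhere while their spacing varies, so
        # the stroke accumulation (which fades where streamlines spread)
        # is divided by a smoothed local maximum, with the amplification
        # capped so empty regions stay empty.
        peak = np.percentile(canvas, 99.0)
        if peak > 0:
            envelope = ndimage.maximum_filter(canvas, size=int(2.5 * spec.ridge_period_px))
            envelope = ndimage.gaussian_filter(envelope, spec.ridge_period_px)
            canvas = canvas / np.maximum(envelope, 0.25 * peak)
            canvas = np.clip(canvas / np.percentile(canvas, 99.0), 0.0, 1.2)
    values = 0.2 + 0.6 * spec.ridge_contrast * canvas

    vessel_mask = np.zeros((h, w), dtype=bool)
    if spec.vessel_count > 0:
        stamp = np.zeros((h, w))
        for pts in _vessel_curves(spec, rng):
            _splat_polyline(stamp, pts, sigma_px=1.2)
        core = stamp > 0.35
        values = np.where(core, 0.08, values)
        vessel_mask = ndimage.binary_dilation(core, iterations=1)

    if spec.noise_sigma > 0:
        values = values + rng.normal(0.0, spec.noise_sigma, size=values.shape)
    return ProjectionImage(
        values=np.clip(values, 0.0, 2.0),
        vessel_mask=vessel_mask,
        max_len=15,
        spacing_x=truth.spacing_x,
        spacing_y=truth.spacing_y,
    )


def _smooth_field(rng, shape, sigma, lo, hi):
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma)
    f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
    return lo + (hi - lo) * f


def render_psoct(truth: AxialAngleMap, spec: PhantomSpec, projection: ProjectionImage = None) -> PSOCTStack:
    """Emulate a PS-OCT stack from the truth field.

    Axis orientation is depth-constant and shifted against the truth by
    the phantom's global axis offset — ``axis_offset_true_deg`` is the
    *correction* the fusion calibration should recover — plus optional
    per-voxel Gaussian angular noise; retardation is constant at
    ``retardation_true``.  Layer boundaries are smooth, with
    RNFL thickness varying between 5 and 40 voxels; the intensity
    volume's RNFL band carries the projection texture so the intensity
    pipeline can run on the same stack.
    """
    rng = spec.rng(salt=2)
    h, w = spec.shape
    depth = spec.depth
    ilm = np.round(_smooth_field(rng, (h, w), sigma=15, lo=2, hi=5)).astype(int)
    thickness = np.round(_smooth_field(rng, (h, w), sigma=20, lo=5, hi=40)).astype(int)
    bng = ilm + thickness
    boo = bng + np.round(_smooth_field(rng, (h, w), sigma=20, lo=4, hi=7)).astype(int)
    boo = np.minimum(boo, depth - 1)
    bng = np.minimum(bng, boo)
    ilm = np.minimum(ilm, bng)

    # the recorded channel axis is shifted by -offset, so that the
    # calibration (which returns the correction to apply) recovers
    # +axis_offset_true
    theta0 = fold_axial(truth.values - np.deg2rad(spec.axis_offset_true_deg))
    axis = np.broadcast_to(theta0[:, :, None], (h, w, depth)).copy()
    ret = np.full((h, w, depth), float(spec.retardation_true))
    if spec.axis_noise_sigma > 0:
        axis = fold_axial(axis + rng.normal(0.0, spec.axis_noise_sigma, size=axis.shape))

    intensity = np.full((h, w, depth), 0.1)
    if projection is not None:
        z = np.arange(depth)
        band = (z[None, None, :] >= ilm[:, :, None]) & (z[None, None, :] < bng[:, :, None])
        intensity = np.where(band, projection.values[:, :, None], intensity)
    return PSOCTStack(
        intensity=intensity,
        retardation=ret,
        axis=axis,
        boundaries=LayerBoundaries(ilm=ilm, rnfl_gcl=bng, opl_onl=boo),
    )


def _dropout_mask(rng, shape, fraction):
    """Smooth-blob invalidity mask covering ~``fraction`` of the image."""
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma=4)
    thr = np.quantile(f, 1.0 - fraction)
    return f > thr


def degrade(data, snr_db=np.inf, dropout_fraction=0.0, seed=0):
    """Calibrated degradation of an image, volume or orientation map.

    For arrays, additive Gaussian noise scaled so that the ratio of the
    signal's standard deviation to the noise standard deviation matches
    ``snr_db`` (20*log10).  For :class:`AxialAngleMap`, the noise is
    applied to the doubled-angle components (then re-normalized) and
    ``dropout_fraction`` of the pixels — in smooth blobs, as real signal
    loss appears — is marked invalid.  Deterministic per seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 99]))
    if isinstance(data, AxialAngleMap):
        out = data.copy()
        if np.isfinite(snr_db):
            s, c = out.components()
            amp = 1.0 / (10.0 ** (snr_db / 20.0))
            s = s + rng.normal(0.0, amp, size=s.shape)
            c = c + rng.normal(0.0, amp, size=c.shape)
            out.values = np.where(out.valid, components_to_angle(s, c), 0.0)
        drop = _dropout_mask(rng, out.shape, dropout_fraction)
        out.valid = out.valid & ~drop
        out.values = np.where(out.valid, out.values, 0.0)
        return out
    if isinstance(data, ProjectionImage):
        vals = np.asarray(data.values, dtype=float).copy()
        if np.isfinite(snr_db):
            sd = float(np.std(vals[data.usable])) if data.usable.any() else float(np.std(vals))
            vals = vals + rng.normal(0.0, sd / (10.0 ** (snr_db / 20.0)), size=vals.shape)
        drop = _dropout_mask(rng, vals.shape, dropout_fraction)
        return replace(data, values=vals, valid=data.valid & ~drop)
    arr = np.asarray(data, dtype=float).copy()
    if np.isfinite(snr_db):
        sd = float(np.std(arr))
        arr = arr + rng.normal(0.0, sd / (10.0 ** (snr_db / 20.0)), size=arr.shape)
    if dropout_fraction > 0:
        drop = _dropout_mask(rng, arr.shape[:2], dropout_fraction)
        arr[drop] = 0.0
    return arr


def perturb_orientation(field: AxialAngleMap, sigma_deg, seed=0) -> AxialAngleMap:
    """Add independent Gaussian angular noise (degrees) to a field."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    out = field.copy()
    noise = rng.normal(0.0, np.deg2rad(sigma_deg), size=out.shape)
    out.values = np.where(out.valid, fold_axial(out.values + noise), 0.0)
    return out
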