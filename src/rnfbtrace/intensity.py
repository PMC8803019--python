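"""Ridge-orientation estimation from RNFL intensity projections.

Nerve fiber bundles reflect more strongly than the tissue between them,
so a projection of the OCT intensity just above the RNFL/GCL boundary
shows them as a pattern of ridges and grooves, much like a fingerprint.
This module builds that projection, normalizes it, and estimates the
local ridge orientation with the classic gradient structure-tensor
approach from fingerprint analysis, followed by model- and
neighborhood-consistency weighting and a large weighted axial-mean
smoothing that produces the intensity orientation map ``phi_F``.

All windowed operations are mask-aware: retinal vessel pixels (and any
otherwise invalid pixels) contribute nothing, so arbitrary values under
the vessel mask cannot influence the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    AxialAngleMap,
    WeightMap,
    axial_distance,
    components_to_angle,
    fold_axial,
    masked_window_mean,
)

__all__ = [
    "scaled_parameters",
    "ProjectionImage",
    "GradientTensors",
    "project_rnfl",
    "normalize_projection",
    "initial_orientation",
    "model_distance_map",
    "neighbor_distance_map",
    "estimation_weights",
    "smooth_orientation",
    "estimate_intensity_orientation",
]


#: Pixel pitch (micrometres, fast axis) at which the default window sizes
#: are calibrated — the instrument grid of the study data.
REFERENCE_SPACING_UM = 8.2


def scaled_parameters(spacing_x_um, reference=REFERENCE_SPACING_UM):
    """Window sizes rescaled from the reference pixel grid to another.

    The window defaults (structure-tensor half-size 7, background window
    145, weight window 15, smoothing half-size 30 — all in pixels) are
    physical neighborhood choices on the instrument's 8.2 um grid.  On a
    coarser grid (e.g. a downsampled phantom) the same physical extents
    correspond to fewer pixels; this helper converts them, with floors
    that keep every window usable.
    """
    f = reference / float(spacing_x_um)

    def _odd(v, lo):
        v = max(int(round(v)), lo)
        return v if v % 2 == 1 else v + 1

    return {
        "tensor_halfsize": max(int(round(7 * f)), 2),
        "neighbor_halfsize": max(int(round(7 * f)), 2),
        "weight_window": _odd(15 * f, 3),
        "smooth_halfsize": max(int(round(30 * f)), 3),
        "bg_window": _odd(145 * f, 9),
    }


@dataclass
class ProjectionImage:
    """En-face RNFL intensity projection with exclusion masks.

    ``values`` is the per-pixel mean intensity of the band above the
    RNFL/GCL boundary (normalized to [0, 1] after
    :func:`normalize_projection`).  ``vessel_mask`` is True on retinal
    vessels (excluded from all estimation); ``valid`` is False where the
    projection band was empty.  ``max_len`` records the band-height cap.
    """

    values: np.ndarray
    vessel_mask: np.ndarray = None
    valid: np.ndarray = None
    max_len: int = 15
    spacing_x: float = 1.0
    spacing_y: float = 1.0
    normalized: bool = False
    degenerate: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.vessel_mask is None:
            self.vessel_mask = np.zeros(self.values.shape, dtype=bool)
        self.vessel_mask = np.asarray(self.vessel_mask, dtype=bool)
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.values.shape == self.vessel_mask.shape == self.valid.shape):
            raise ValueError("projection values and masks must share a shape")

    @property
    def usable(self):
        """Pixels that may contribute to orientation estimation."""
        return self.valid & ~self.vessel_mask

    @property
    def shape(self):
        return self.values.shape


@dataclass
class GradientTensors:
    """Windowed gradient-product sums ``Gxx, Gyy, Gxy`` (structure tensor)."""

    gxx: np.ndarray
    gyy: np.ndarray
    gxy: np.ndarray
    window_halfsize: int = 7


def project_rnfl(volume, boundaries, max_len=15, vessel_mask=None, spacing_x=1.0, spacing_y=1.0) -> ProjectionImage:
    """Mean-intensity projection of the band above the RNFL/GCL boundary.

    Per pixel the band extent is ``BE = min(BNG - BILM, max_len)`` voxels
    (never crossing the inner limiting membrane) and the projection is
    the mean of ``V[x, y, BNG - i]`` for ``i = 1..BE``.  Pixels with a
    zero-height band are invalid.
    """
    volume = np.asarray(volume, dtype=float)
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    bng = boundaries.rnfl_gcl
    be = np.minimum(bng - boundaries.ilm, int(max_len))
    depth = volume.shape[2]
    z = np.arange(depth)
    # band covers z in [BNG - BE, BNG - 1]
    in_band = (z[None, None, :] >= (bng - be)[:, :, None]) & (
        z[None, None, :] < bng[:, :, None]
    )
    n = in_band.sum(axis=2)
    vals = np.sum(np.where(in_band, volume, 0.0), axis=2) / np.maximum(n, 1)
    return ProjectionImage(
        values=np.where(n > 0, vals, 0.0),
        vessel_mask=vessel_mask,
        valid=n > 0,
        max_len=int(max_len),
        spacing_x=spacing_x,
        spacing_y=spacing_y,
    )


def normalize_projection(img: ProjectionImage, window=145) -> ProjectionImage:
    """Background-subtract and rescale a projection to [0, 1].

    The background is the sliding mean over a ``window`` x ``window``
    neighborhood computed from usable pixels only; after subtraction the
    image is rescaled on its 1st..99th percentile range (robust to the
    few extreme pixels vessel shadows leave behind) and clipped.  A
    constant input has no contrast to rescale: the output is flat 0.5
    and the image is flagged ``degenerate``.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    usable = img.usable
    background, _ = masked_window_mean(img.values, usable, window)
    flat = img.values - background
    ref = flat[usable]
    if ref.size == 0:
        raise ValueError("no usable pixels to normalize")
    lo, hi = np.percentile(ref, [1.0, 99.0])
    degenerate = hi - lo < 1e-12
    if degenerate:
        out = np.full(img.shape, 0.5)
    else:
        out = np.clip((flat - lo) / (hi - lo), 0.0, 1.0)
    return ProjectionImage(
        values=out,
        vessel_mask=img.vessel_mask,
        valid=img.valid,
        max_len=img.max_len,
        spacing_x=img.spacing_x,
        spacing_y=img.spacing_y,
        normalized=True,
        degenerate=degenerate,
    )


def _structure_tensor(img: ProjectionImage, halfsize) -> GradientTensors:
    usable = img.usable
    # Any constant under excluded pixels must not leak into gradients:
    # zero them out and afterwards drop every pixel whose 3x3 Sobel
    # stencil touched an excluded pixel.
    vals = np.where(usable, img.values, 0.0)
    gx = ndimage.sobel(vals, axis=1, mode="constant")
    gy = ndimage.sobel(vals, axis=0, mode="constant")
    clean = ndimage.binary_erosion(usable, structure=np.ones((3, 3)), border_value=0)
    gx = np.where(clean, gx, 0.0)
    gy = np.where(clean, gy, 0.0)
    size = 2 * halfsize + 1
    norm = 1.0 / size**2
    gxx = ndimage.uniform_filter(gx * gx, size=size, mode="constant")
    gyy = ndimage.uniform_filter(gy * gy, size=size, mode="constant")
    gxy = ndimage.uniform_filter(gx * gy, size=size, mode="constant")
    return GradientTensors(gxx=gxx, gyy=gyy, gxy=gxy, window_halfsize=halfsize)


def initial_orientation(img: ProjectionImage, halfsize=7, energy_threshold=1e-9) -> AxialAngleMap:
    """First ridge-orientation estimate ``phi_FI`` from the structure tensor.

    The dominant gradient direction is the half-angle of
    ``atan2(2*Gxy, Gxx - Gyy)``; ridges run perpendicular to it, so a
    quarter turn is added.  Pixels whose window carries no gradient
    energy (or that are vessels / were never projected) are invalid.
    """
    if not img.normalized:
        raise ValueError("initial_orientation expects a normalized projection")
    t = _structure_tensor(img, halfsize)
    energy = t.gxx + t.gyy
    grad_angle = 0.5 * np.arctan2(2.0 * t.gxy, t.gxx - t.gyy)
    ridge = fold_axial(grad_angle + 0.5 * np.pi)
    valid = (energy > energy_threshold) & img.usable
    return AxialAngleMap(
        values=np.where(valid, ridge, 0.0),
        valid=valid,
        spacing_x=img.spacing_x,
        spacing_y=img.spacing_y,
    )


def model_distance_map(phi_fi: AxialAngleMap, phi_m: AxialAngleMap):
    """Doubled-angle distance ``DSTm`` between the initial estimate and the
    model map, in [0, 2]; zero where either map is invalid."""
    if phi_fi.shape != phi_m.shape:
        raise ValueError("maps must share a shape")
    both = phi_fi.valid & phi_m.valid
    d = axial_distance(phi_fi.values, phi_m.values)
    return np.where(both, d, 0.0)


def neighbor_distance_map(phi_fi: AxialAngleMap, halfsize=7):
    """Doubled-angle distance ``DSTn`` of each pixel to its windowed
    neighborhood mean orientation; zero for locally parallel fields."""
    if halfsize < 1:
        raise ValueError("halfsize must be >= 1")
    s, c = phi_fi.components()
    size = 2 * halfsize + 1
    sbar, _ = masked_window_mean(s, phi_fi.valid, size)
    cbar, _ = masked_window_mean(c, phi_fi.valid, size)
    d = np.hypot(s - sbar, c - cbar)
    return np.where(phi_fi.valid, d, 0.0)


def estimation_weights(dst_m, dst_n, valid=None, avg_window=15) -> WeightMap:
    """Combine the model and neighborhood distances into weights.

    ``W = 1 - sqrt(DSTm_bar**2 + DSTn_bar**2) / 2`` with both distances
    sliding-window averaged first; clamped to [0, 1].
    """
    dst_m = np.asarray(dst_m, dtype=float)
    dst_n = np.asarray(dst_n, dtype=float)
    if dst_m.shape != dst_n.shape:
        raise ValueError("distance maps must share a shape")
    if valid is None:
        valid = np.ones(dst_m.shape, dtype=bool)
    mbar, _ = masked_window_mean(dst_m, valid, avg_window)
    nbar, _ = masked_window_mean(dst_n, valid, avg_window)
    w = 1.0 - 0.5 * np.sqrt(mbar**2 + nbar**2)
    return WeightMap(values=np.clip(w, 0.0, 1.0))


def _integral(a):
    p = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=p[1:, 1:])
    return p


def _box_sum(p, y0, y1, x0, x1):
    # inclusive box sums from a padded integral image; bounds are arrays
    return p[y1 + 1, x1 + 1] - p[y0, x1 + 1] - p[y1 + 1, x0] + p[y0, x0]


def smooth_orientation(
    phi_fi: AxialAngleMap,
    weights: WeightMap,
    n_max=30,
    fovea_xy=None,
    min_weight=1e-9,
) -> AxialAngleMap:
    """Large weighted axial-mean smoothing producing ``phi_F``.

    Per pixel the doubled-angle components of ``phi_FI`` are averaged
    over a square window of half-size up to ``n_max`` with the
    consistency weights; invalid pixels carry zero weight.  Near the
    fovea, where bundles converge from all directions, the window
    half-size shrinks so that it never covers the fovea position (except
    for pixels within 1 px of it, which use only themselves).
    """
    if phi_fi.shape != weights.shape:
        raise ValueError("phi_FI and weights must share a shape")
    h, w = phi_fi.shape
    s, c = phi_fi.components()
    wgt = np.where(phi_fi.valid, weights.values, 0.0)
    ps = _integral(wgt * s)
    pc = _integral(wgt * c)
    pw = _integral(wgt)

    yy, xx = np.mgrid[0:h, 0:w]
    n = np.full((h, w), int(n_max), dtype=int)
    if fovea_xy is not None:
        fx, fy = float(fovea_xy[0]), float(fovea_xy[1])
        cheb = np.maximum(np.abs(xx - fx), np.abs(yy - fy))
        n = np.minimum(n, np.maximum(0, np.ceil(cheb).astype(int) - 1))
    y0 = np.clip(yy - n, 0, h - 1)
    y1 = np.clip(yy + n, 0, h - 1)
    x0 = np.clip(xx - n, 0, w - 1)
    x1 = np.clip(xx + n, 0, w - 1)
    rs = _box_sum(ps, y0, y1, x0, x1)
    rc = _box_sum(pc, y0, y1, x0, x1)
    rw = _box_sum(pw, y0, y1, x0, x1)
    resultant = np.hypot(rs, rc)
    valid = (rw > min_weight) & (resultant > min_weight * 1e-3)
    return AxialAngleMap(
        values=np.where(valid, components_to_angle(rs, rc), 0.0),
        valid=valid,
        spacing_x=phi_fi.spacing_x,
        spacing_y=phi_fi.spacing_y,
    )


def estimate_intensity_orientation(
    projection: ProjectionImage,
    phi_m: AxialAngleMap,
    fovea_xy=None,
    tensor_halfsize=7,
    neighbor_halfsize=7,
    weight_window=15,
    smooth_halfsize=30,
    bg_window=145,
    geometry=None,
    onh_exclusion_deg=6.0,
):
    """Run the full intensity-orientation chain on a projection image.

    Normalizes (if needed), estimates ``phi_FI``, computes the model and
    neighborhood distances, the combined weights, and the smoothed map
    ``phi_F``.  Returns a dict with keys ``projection``, ``phi_fi``,
    ``dst_m``, ``dst_n``, ``weights`` and ``phi_f``.

    When ``geometry`` is given, pixels within ``onh_exclusion_deg`` of
    the ONH center are excluded from the intensity estimate: close to
    the nerve head the bundles are packed too tightly for usable
    intensity gradients, so orientation there is left to the
    polarization and model sources during fusion.
    """
    if not projection.normalized:
        projection = normalize_projection(projection, window=bg_window)
    phi_fi = initial_orientation(projection, halfsize=tensor_halfsize)
    if geometry is not None and onh_exclusion_deg > 0:
        h, w = phi_fi.shape
        yy, xx = np.mgrid[0:h, 0:w]
        near_onh = geometry.eccentricity_deg(xx, yy) < onh_exclusion_deg
        phi_fi.valid = phi_fi.valid & ~near_onh
        phi_fi.values = np.where(phi_fi.valid, phi_fi.values, 0.0)
    dst_m = model_distance_map(phi_fi, phi_m)
    dst_n = neighbor_distance_map(phi_fi, halfsize=neighbor_halfsize)
    weights = estimation_weights(dst_m, dst_n, valid=phi_fi.valid, avg_window=weight_window)
    phi_f = smooth_orientation(phi_fi, weights, n_max=smooth_halfsize, fovea_xy=fovea_xy)
    return {
        "projection": projection,
        "phi_fi": phi_fi,
        "dst_m": dst_m,
        "dst_n": dst_n,
        "weights": weights,
        "phi_f": phi_f,
    }
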